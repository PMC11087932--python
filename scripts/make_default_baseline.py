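"""Regenerate the shipped CDKN2A/B deletion baseline artifact.

The artifact is fitted on a synthetic, noiseless admixture series (normal x
homozygous-deletion tumor on the hg38 grid at high depth), so it encodes
the ideal copy(t) = 2 - 2t relation up to rounding. It is a synthetic
stand-in calibrator; users with matched normal/tumor count files should
refit with `gliocnv fit-baseline`.

Usage: python scripts/make_default_baseline.py
"""

from pathlib import Path

from gliocnv.deletion_baseline import fit_baseline
from gliocnv.genome_model import (GenomeBuild, MarkerCatalog, build_bin_grid,
                                  exclusion_mask, locate_marker_bins)
from gliocnv.simulate import simulate_admixture_series

OUT = (Path(__file__).resolve().parent.parent / "src" / "gliocnv" / "data"
       / "default_deletion_baseline.synthetic.json")


def main() -> None:
    build = GenomeBuild.load("hg38")
    grid = build_bin_grid(build)
    mask = exclusion_mask(grid)
    marker_bins = locate_marker_bins(MarkerCatalog.default(build), grid, "CDKN2AB")
    fractions = [round(0.1 * k, 1) for k in range(1, 10)]
    admix, _ = simulate_admixture_series(
        grid, fractions, seed=20240500, depth_lambda=10_000.0, noiseless=True)
    baseline = fit_baseline(
        admix, mask, marker_bins,
        provenance="synthetic noiseless admixture series (hg38 grid, "
                   "depth 10000, fractions 0.1..0.9)")
    baseline.to_json(str(OUT))
    print(f"slope={baseline.slope:.5f} intercept={baseline.intercept:.5f} "
          f"residual_sd={baseline.residual_sd:.2g} -> {OUT}")


if __name__ == "__main__":
    main()
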