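"""Synthetic bin-count profiles with known truth, for testing every stage.

The generator works at the bin-count level (no read-level simulation of
nanopore error profiles): for tumor fraction t and per-bin tumor copy c_b,
the expected count is

    mu_b = depth_lambda * gc_bias(gc_b) * (t*c_b + 2*(1-t)) / 2

and counts are drawn negative-binomially around mu_b with a dispersion
(size) parameter, default 20 — low-pass nanopore depth is overdispersed
relative to Poisson. ``noiseless=True`` returns the exact expectations,
which the admixture-algebra tests rely on. The GC fraction track is a fixed
smooth deterministic function of genomic position (the same for every
sample on a grid, as it would be for a real genome), and gc_bias is an
arbitrary polynomial in GC, default flat.

Defaults mirror the intended use case: 500-kb bins over hg38
(~6200 bins), mean depth 100 reads/bin — roughly the 0.5x low-pass regime
the pipeline targets.

A tiny SAM emitter (``write_test_sam``) exists solely to exercise the
alignment-counting path on hand-scripted reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .deletion_baseline import AdmixtureSet, make_admixture
from .errors import InvalidParameterError, MarkerLookupError
from .genome_model import (BinGrid, GenomeBuild, MarkerCatalog, build_bin_grid,
                           locate_marker_bins)
from .readcount_io import BinCounts

DEFAULT_DEPTH = 100.0
DEFAULT_DISPERSION = 20.0


@dataclass
class Event:
    """A planted alteration: either a catalog marker or an explicit region."""

    tumor_copy: int
    marker_id: str | None = None
    region: tuple[str, int, int] | None = None

    def __post_init__(self):
        if self.tumor_copy < 0:
            raise InvalidParameterError("tumor_copy must be >= 0")
        if (self.marker_id is None) == (self.region is None):
            raise InvalidParameterError("give exactly one of marker_id / region")


@dataclass
class SimulationSpec:
    grid: BinGrid
    seed: int
    tumor_fraction: float = 1.0
    depth_lambda: float = DEFAULT_DEPTH
    dispersion: float = DEFAULT_DISPERSION
    events: tuple[Event, ...] = ()
    gc_bias: tuple[float, ...] | None = None   # polynomial coeffs in GC (high->low)
    noiseless: bool = False
    sample_id: str = "sim"
    catalog: MarkerCatalog | None = None

    def __post_init__(self):
        if self.depth_lambda <= 0:
            raise InvalidParameterError("depth_lambda must be positive")
        if not 0 < self.tumor_fraction <= 1:
            raise InvalidParameterError("tumor_fraction must lie in (0, 1]")
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")


@dataclass
class Truth:
    tumor_fraction: float
    copy: np.ndarray                 # true tumor copy number per bin
    marker_status: dict = field(default_factory=dict)


@dataclass
class SimulatedSample:
    counts: BinCounts
    truth: Truth


def smooth_gc_track(grid: BinGrid) -> np.ndarray:
    """Deterministic smooth GC fraction per bin in roughly [0.33, 0.53].

    A fixed function of bin ordinal, shared by every sample on the grid —
    GC content is a property of the genome, not of the sample.
    """
    i = np.arange(grid.n_bins, dtype=float)
    gc = (0.43 + 0.06 * np.sin(2 * np.pi * i / 97.0)
          + 0.04 * np.sin(2 * np.pi * i / 1003.0 + 1.0))
    return np.clip(gc, 0.0, 1.0)


def _truth_copy(spec: SimulationSpec) -> np.ndarray:
    grid = spec.grid
    copy = np.full(grid.n_bins, 2, dtype=np.int64)
    for event in spec.events:
        if event.marker_id is not None:
            catalog = spec.catalog or MarkerCatalog.default(grid.build)
            bins = locate_marker_bins(catalog, grid, event.marker_id)
        else:
            chrom, start, end = event.region
            sl = grid.chrom_slices.get(chrom)
            if sl is None:
                raise MarkerLookupError(f"event region on unknown chromosome {chrom}")
            hit = (grid.start[sl] < end) & (grid.end[sl] > start)
            bins = np.nonzero(hit)[0] + sl.start
            if bins.size == 0:
                raise MarkerLookupError(f"event region {chrom}:{start}-{end} off grid")
        copy[bins] = event.tumor_copy
    return copy


def simulate_bin_counts(spec: SimulationSpec) -> SimulatedSample:
    """Draw one sample according to ``spec`` (reproducible from the seed)."""
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    gc = smooth_gc_track(grid)
    copy = _truth_copy(spec)
    t = spec.tumor_fraction
    mixture = (t * copy + 2.0 * (1.0 - t)) / 2.0
    bias = np.polyval(spec.gc_bias, gc) if spec.gc_bias is not None else 1.0
    mu = spec.depth_lambda * bias * mixture
    mu = np.maximum(mu, 0.0)
    if spec.noiseless:
        counts = mu
    else:
        r = spec.dispersion
        p = r / (r + np.maximum(mu, 1e-12))
        counts = np.where(mu > 0, rng.negative_binomial(r, p), 0).astype(float)
    bc = BinCounts(grid=grid, counts=counts, gc=gc,
                   mappability=np.ones(grid.n_bins),
                   total_reads=int(np.round(counts.sum())),
                   sample_id=spec.sample_id)
    status = {e.marker_id: e.tumor_copy for e in spec.events if e.marker_id}
    return SimulatedSample(counts=bc, truth=Truth(
        tumor_fraction=t, copy=copy, marker_status=status))


def simulate_admixture_series(grid: BinGrid, fractions: Sequence[float],
                              seed: int, depth_lambda: float = DEFAULT_DEPTH,
                              dispersion: float = DEFAULT_DISPERSION,
                              noiseless: bool = False,
                              tumor_events: Sequence[Event] | None = None,
                              catalog: MarkerCatalog | None = None
                              ) -> tuple[AdmixtureSet, dict]:
    """Generate a normal and a homozygous-deletion tumor, then mix them.

    The tumor is pure (t = 1) with CDKN2A/B at copy 0 unless other events
    are given. Returns the admixture set plus the truth record of each
    mixture fraction.
    """
    events = tuple(tumor_events) if tumor_events is not None else (
        Event(marker_id="CDKN2AB", tumor_copy=0),
    )
    normal = simulate_bin_counts(SimulationSpec(
        grid=grid, seed=seed, tumor_fraction=1.0, depth_lambda=depth_lambda,
        dispersion=dispersion, noiseless=noiseless, sample_id="sim_normal",
        catalog=catalog))
    tumor = simulate_bin_counts(SimulationSpec(
        grid=grid, seed=seed + 1, tumor_fraction=1.0,
        depth_lambda=depth_lambda, dispersion=dispersion, events=events,
        noiseless=noiseless, sample_id="sim_tumor_homdel", catalog=catalog))
    admix = make_admixture(normal.counts, tumor.counts, fractions, seed=seed)
    truth = {"fractions": sorted(float(t) for t in fractions),
             "tumor_events": [(e.marker_id or e.region, e.tumor_copy)
                              for e in events]}
    return admix, truth


def scenario_library() -> dict:
    """Named scenario presets, as (name -> event tuple).

    Instantiate with :func:`scenario_spec`. Intended end-to-end readings:
    ``neutral`` → unclassified_by_cnv; ``oligodendroglioma-like`` →
    oligodendroglioma; ``gbm-like`` → glioblastoma (molecular);
    ``astro-grade4-like`` → astrocytoma with grade-4 support.
    """
    return {
        "neutral": (),
        "oligodendroglioma-like": (
            Event(marker_id="ARM_1P", tumor_copy=1),
            Event(marker_id="ARM_19Q", tumor_copy=1),
        ),
        "gbm-like": (
            Event(marker_id="CHR7", tumor_copy=3),
            Event(marker_id="CHR10", tumor_copy=1),
            Event(marker_id="EGFR", tumor_copy=8),
        ),
        "astro-grade4-like": (
            Event(marker_id="CDKN2AB", tumor_copy=0),
        ),
    }


#: scenario-preset sequencing conditions: a well-covered run of 500-kb bins
#: with the mild overdispersion seen at this bin size, giving per-bin log2
#: noise near 0.09 — the ~0.1 log2-unit regime the segmentation model is
#: designed for, and enough to resolve a 2-bin focal deletion. The heavily
#: overdispersed generator default (dispersion 20, log2 noise floor ~0.32)
#: can never resolve one, regardless of depth.
SCENARIO_DEPTH = 1000.0
SCENARIO_DISPERSION = 400.0


def scenario_spec(name: str, grid: BinGrid, tumor_fraction: float, seed: int,
                  depth_lambda: float = SCENARIO_DEPTH,
                  dispersion: float = SCENARIO_DISPERSION) -> SimulationSpec:
    """A SimulationSpec for one library scenario at the given t and seed."""
    library = scenario_library()
    if name not in library:
        raise MarkerLookupError(f"unknown scenario {name!r}; "
                                f"choose from {sorted(library)}")
    return SimulationSpec(grid=grid, seed=seed, tumor_fraction=tumor_fraction,
                          depth_lambda=depth_lambda, dispersion=dispersion,
                          events=library[name], sample_id=f"{name}_t{tumor_fraction}")


def simulate_log2_profile(grid: BinGrid, tumor_fraction: float,
                          events: Sequence[Event], sd: float, seed: int,
                          valid: np.ndarray | None = None,
                          catalog: MarkerCatalog | None = None):
    """A CorrectedProfile drawn directly in log2 space: expected ratios at
    the given tumor fraction plus Gaussian noise of standard deviation
    ``sd``. This isolates the segmentation model from count-level noise
    (which at the generator's default overdispersion is far above the 0.1
    log2 units these studies assume). Returns (profile, truth)."""
    from .cnv_hmm import expected_log2_ratio, LOG2_FLOOR
    from .normalization import CorrectedProfile

    rng = np.random.default_rng(seed)
    spec = SimulationSpec(grid=grid, seed=seed, tumor_fraction=tumor_fraction,
                          events=tuple(events), catalog=catalog)
    copy = _truth_copy(spec)
    centers = np.maximum(
        expected_log2_ratio(copy.astype(float), tumor_fraction), LOG2_FLOOR)
    log2 = centers + rng.normal(0.0, sd, size=grid.n_bins)
    if valid is None:
        valid = np.ones(grid.n_bins, dtype=bool)
    profile = CorrectedProfile(
        grid=grid, log2_ratio=np.where(valid, log2, np.nan),
        valid=np.asarray(valid, dtype=bool),
        metadata={"synthetic": True, "sd": sd},
        sample_id=f"log2sim_t{tumor_fraction}")
    return profile, Truth(tumor_fraction=tumor_fraction, copy=copy)


def write_test_sam(path: str, chrom_lengths: dict,
                   reads: Sequence[tuple[str, int, int, int]]) -> None:
    """Write a minimal coordinate-sorted SAM for counting tests.

    ``reads`` are (chrom, pos0, mapq, flag) tuples; each becomes a 50 bp
    perfect-match record. Records are sorted by (chromosome order, position).
    """
    order = {c: i for i, c in enumerate(chrom_lengths)}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        ordered = sorted(enumerate(reads),
                         key=lambda kv: (order.get(kv[1][0], 1 << 30), kv[1][1]))
        for i, (chrom, pos0, mapq, flag) in ordered:
            seq = "A" * 50
            if flag & 4 or chrom == "*":
                fh.write(f"read{i}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
            else:
                fh.write(f"read{i}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t50M\t"
                         f"*\t0\t0\t{seq}\t*\n")
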