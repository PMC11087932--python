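"""Bias correction of binned counts and conversion to log2 copy ratios.

The correction is two-stage. Stage 1 removes GC bias with a non-parametric
fit of count versus GC fraction (binned medians smoothed with a moving
window spanning 30% of the observed GC range), dividing each count by its
fitted value. Stage 2 divides by per-bin mappability where available and
drops bins below the mappability threshold. The corrected values are then
expressed as log2 ratios against the median over valid autosomal bins —
sex chromosomes are excluded from centering so that sample sex cannot shift
the diploid baseline.

Optionally, a panel of normals is subtracted (per-bin median of the panel's
log2 ratios) to remove recurrent technical artifacts.

Because the GC fit, the mappability division, and the median centering are
all scale-equivariant, the resulting log2 ratio is invariant to overall
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GridConsistencyError, InsufficientDataError
from .genome_model import BinGrid
from .readcount_io import BinCounts

DEFAULT_MAPPABILITY_THRESHOLD = 0.75
GC_FIT_SPAN = 0.3          # smoothing window, as a fraction of the GC range
GC_FIT_CENTERS = 51        # number of GC knots for the binned-median fit
MIN_VALID_BINS = 50
MIN_GC_COVERAGE = 0.8      # required GC annotation rate over non-excluded bins


@dataclass
class CorrectedProfile:
    """Per-bin log2 copy ratios with a validity mask and correction metadata."""

    grid: BinGrid
    log2_ratio: np.ndarray   # NaN where invalid
    valid: np.ndarray        # bool per bin
    metadata: dict = field(default_factory=dict)
    sample_id: str = "sample"

    def __post_init__(self):
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.log2_ratio.size != self.grid.n_bins or self.valid.size != self.grid.n_bins:
            raise GridConsistencyError("profile arrays do not match the grid")
        if np.any(~np.isfinite(self.log2_ratio[self.valid])):
            raise GridConsistencyError("valid bins must have finite log2 ratios")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.grid.chrom,
            "start": self.grid.start,
            "end": self.grid.end,
            "log2_ratio": self.log2_ratio,
            "valid": self.valid,
        })

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _fit_gc_curve(gc: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Binned-median curve of count vs GC, smoothed with a moving window of
    width ``GC_FIT_SPAN`` times the GC range. Returns (knots, fitted)."""
    lo, hi = gc.min(), gc.max()
    knots = np.linspace(lo, hi, GC_FIT_CENTERS)
    medians = np.full(GC_FIT_CENTERS, np.nan)
    assignment = np.clip(
        np.round((gc - lo) / (hi - lo) * (GC_FIT_CENTERS - 1)).astype(int),
        0, GC_FIT_CENTERS - 1,
    )
    for k in range(GC_FIT_CENTERS):
        sel = counts[assignment == k]
        if sel.size:
            medians[k] = np.median(sel)
    half_span = GC_FIT_SPAN * (hi - lo) / 2
    smoothed = np.full(GC_FIT_CENTERS, np.nan)
    for k in range(GC_FIT_CENTERS):
        window = np.abs(knots - knots[k]) <= half_span
        vals = medians[window]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            smoothed[k] = vals.mean()
    ok = np.isfinite(smoothed)
    return knots[ok], smoothed[ok]


def correct_bias(counts: BinCounts, mask: np.ndarray,
                 mappability_threshold: float = DEFAULT_MAPPABILITY_THRESHOLD,
                 skip_gc: bool = False) -> CorrectedProfile:
    """GC/mappability-correct ``counts`` and return centered log2 ratios.

    ``mask`` is the centromere exclusion mask (True = excluded); masked bins,
    zero-count bins and bins with missing GC are invalid in the output.
    """
    grid = counts.grid
    mask = np.asarray(mask, dtype=bool)
    if mask.size != grid.n_bins:
        raise GridConsistencyError("exclusion mask does not match the grid")

    raw = counts.counts
    dropped = {}
    valid = ~mask
    dropped["excluded_region"] = int(mask.sum())

    missing = ~np.isfinite(raw)
    dropped["missing_count"] = int((valid & missing).sum())
    valid &= ~missing

    zero = np.isfinite(raw) & (raw <= 0)
    dropped["zero_count"] = int((valid & zero).sum())
    valid &= ~zero

    gc_known = np.isfinite(counts.gc)
    if not skip_gc:
        non_excluded = ~mask & ~missing
        coverage = gc_known[non_excluded].mean() if non_excluded.any() else 0.0
        if coverage < MIN_GC_COVERAGE:
            raise InsufficientDataError(
                f"GC annotated for only {coverage:.0%} of non-excluded bins "
                f"(need >= {MIN_GC_COVERAGE:.0%}); supply a GC track or skip_gc"
            )
        dropped["missing_gc"] = int((valid & ~gc_known).sum())
        valid &= gc_known

    if valid.sum() < MIN_VALID_BINS:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid bins (< {MIN_VALID_BINS})"
        )

    corrected = raw.astype(float).copy()
    gc_fit_summary: dict = {"applied": False}
    if not skip_gc:
        gc = counts.gc
        gc_range = float(gc[valid].max() - gc[valid].min())
        if gc_range < 1e-6:
            gc_fit_summary = {"applied": False,
                              "warning": "degenerate GC range; stage 1 skipped"}
        else:
            knots, fitted = _fit_gc_curve(gc[valid], raw[valid])
            expected = np.interp(gc, knots, fitted)
            bad_fit = valid & (expected <= 0)
            dropped["nonpositive_gc_fit"] = int(bad_fit.sum())
            valid &= expected > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                corrected = np.where(expected > 0, raw / expected, np.nan)
            gc_fit_summary = {"applied": True, "knots": len(knots),
                              "gc_range": gc_range}

    mp = counts.mappability
    mp_known = np.isfinite(mp)
    low_map = mp_known & (mp < mappability_threshold)
    dropped["low_mappability"] = int((valid & low_map).sum())
    valid &= ~low_map
    divisor = np.where(mp_known & (mp > 0), mp, 1.0)
    corrected = corrected / divisor

    if valid.sum() < MIN_VALID_BINS:
        raise InsufficientDataError(
            f"only {int(valid.sum())} valid bins after correction"
        )

    autosomal = grid.autosomal_mask()
    center_pool = valid & autosomal
    center = np.median(corrected[center_pool if center_pool.any() else valid])
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.where(valid, np.log2(corrected / center), np.nan)

    return CorrectedProfile(
        grid=grid,
        log2_ratio=log2_ratio,
        valid=valid,
        metadata={
            "gc_fit_summary": gc_fit_summary,
            "mappability_threshold": mappability_threshold,
            "bins_dropped_by_reason": dropped,
        },
        sample_id=counts.sample_id,
    )


def normalize_against_panel(profile: CorrectedProfile,
                            panel: Sequence[CorrectedProfile]
                            ) -> CorrectedProfile:
    """Subtract the panel-of-normals median log2 ratio per bin.

    Bins invalid in >= 50% of panel members become invalid; the result is
    re-centered on the autosomal median. An empty panel returns the profile
    unchanged (with a warning recorded in metadata).
    """
    panel = list(panel)
    if not panel:
        meta = dict(profile.metadata)
        meta["panel"] = {"size": 0, "warning": "empty panel; identity fallback"}
        return CorrectedProfile(grid=profile.grid,
                                log2_ratio=profile.log2_ratio.copy(),
                                valid=profile.valid.copy(),
                                metadata=meta, sample_id=profile.sample_id)
    for member in panel:
        if member.grid.n_bins != profile.grid.n_bins or \
                member.grid.build.name != profile.grid.build.name:
            raise GridConsistencyError("panel member grid does not match the profile")

    stack = np.vstack([m.log2_ratio for m in panel])
    valid_stack = np.vstack([m.valid for m in panel])
    n_invalid = (~valid_stack).sum(axis=0)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-invalid columns
        panel_median = np.nanmedian(np.where(valid_stack, stack, np.nan), axis=0)
    panel_ok = n_invalid * 2 < len(panel)  # invalid in >= 50% of members -> drop

    valid = profile.valid & panel_ok & np.isfinite(panel_median)
    log2 = np.where(valid, profile.log2_ratio - panel_median, np.nan)

    autosomal = profile.grid.autosomal_mask()
    pool = valid & autosomal
    if pool.any():
        log2 = np.where(valid, log2 - np.median(log2[pool]), np.nan)

    meta = dict(profile.metadata)
    meta["panel"] = {"size": len(panel),
                     "bins_invalidated": int((profile.valid & ~valid).sum())}
    return CorrectedProfile(grid=profile.grid, log2_ratio=log2, valid=valid,
                            metadata=meta, sample_id=profile.sample_id)
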