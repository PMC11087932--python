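"""Per-marker status calls and the composite marker table.

Focal markers (CDKN2A/B, EGFR) are called from the bins overlapping the
gene: CDKN2A/B through the tumor-fraction-aware deletion baseline (so that
homozygous and hemizygous losses separate), EGFR from the modal copy state
(amplification at the capped top state, gain at 3-4). Arm and
whole-chromosome markers (1p, 19q, chr7, chr10) are called from the
fraction of valid bins in an altered state: a loss/gain is only called when
at least ``arm_call_threshold`` (default 0.8) of the arm is altered —
echoing the diagnostic requirement that the 1p/19q codeletion be complete —
while substantial partial alterations are surfaced in the evidence note
rather than called.

Composites: codeletion_1p19q requires losses on BOTH arms; plus7_minus10
requires chr7 gain/amplification AND a chr10 loss. Indeterminate inputs
propagate to indeterminate composites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cnv_hmm import SegmentationResult
from .deletion_baseline import (DeletionBaseline, HEMIZYGOUS, HOMOZYGOUS,
                                classify_deletion, copy_value_at)
from .errors import GridConsistencyError
from .genome_model import BinGrid, MarkerCatalog, locate_marker_bins
from .normalization import CorrectedProfile

AMPLIFICATION = "amplification"
GAIN = "gain"
NEUTRAL = "neutral"
HEMIZYGOUS_LOSS = "hemizygous_loss"
HOMOZYGOUS_LOSS = "homozygous_loss"
INDETERMINATE = "indeterminate"

STATUSES = (AMPLIFICATION, GAIN, NEUTRAL, HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS,
            INDETERMINATE)
LOSSES = (HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS)

DEFAULT_ARM_CALL_THRESHOLD = 0.8
PARTIAL_NOTE_FLOOR = 0.2
MIN_ARM_BINS = 5
DEFAULT_AMPLIFICATION_STATE = 5


@dataclass
class MarkerCall:
    marker_id: str
    status: str
    mean_copy: float
    fraction_of_bins_altered: float
    bins_used: int
    evidence_note: str = ""


@dataclass
class MarkerTable:
    """One call per catalog marker plus the two composite flags
    (True / False / None-for-indeterminate)."""

    calls: dict
    codeletion_1p19q: bool | None
    plus7_minus10: bool | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.calls.values()])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4g")

    def to_dict(self) -> dict:
        return {
            "markers": {mid: asdict(c) for mid, c in self.calls.items()},
            "codeletion_1p19q": self.codeletion_1p19q,
            "plus7_minus10": self.plus7_minus10,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
            fh.write("\n")


def call_focal_marker(seg: SegmentationResult, profile: CorrectedProfile,
                      marker_bins: np.ndarray, marker_id: str,
                      baseline: DeletionBaseline,
                      amplification_state: int = DEFAULT_AMPLIFICATION_STATE
                      ) -> MarkerCall:
    """Call a focal gene marker from its overlapping bins."""
    marker_bins = np.asarray(marker_bins, dtype=np.int64)
    valid = marker_bins[profile.valid[marker_bins]]
    if valid.size == 0:
        return MarkerCall(marker_id, INDETERMINATE, float("nan"), 0.0, 0,
                          "no valid bins over the marker")
    mean_copy = copy_value_at(profile, valid)
    states = seg.copy_state[valid]
    altered = float(np.mean(states != 2))

    if marker_id == "CDKN2AB":
        # The HMM decides whether a loss is present (so a non-informative
        # tumor-fraction estimate cannot conjure one); the admixture baseline
        # then decides its zygosity.
        modal = int(np.bincount(states).argmax())
        if modal >= 2 or not seg.tf_informative:
            status = NEUTRAL
            note = f"modal copy state {modal}; no deletion called"
        else:
            zygosity = classify_deletion(mean_copy, seg.tumor_fraction, baseline)
            status = {HOMOZYGOUS: HOMOZYGOUS_LOSS,
                      HEMIZYGOUS: HEMIZYGOUS_LOSS}.get(zygosity, HEMIZYGOUS_LOSS)
            note = (f"copy {mean_copy:.2f} at t={seg.tumor_fraction:.2f} vs "
                    f"homozygous expectation "
                    f"{baseline.predict(seg.tumor_fraction):.2f}, "
                    f"hemizygous {2 - seg.tumor_fraction:.2f}")
    else:
        modal = int(np.bincount(states).argmax())
        if modal >= amplification_state:
            status = AMPLIFICATION
        elif modal in (3, 4):
            status = GAIN
        elif modal == 2:
            status = NEUTRAL
        elif modal == 1:
            status = HEMIZYGOUS_LOSS
        else:
            status = HOMOZYGOUS_LOSS
        note = f"modal copy state {modal}"
    return MarkerCall(marker_id, status, mean_copy, altered, int(valid.size), note)


def call_arm_marker(seg: SegmentationResult, profile: CorrectedProfile,
                    marker_bins: np.ndarray, marker_id: str,
                    arm_call_threshold: float = DEFAULT_ARM_CALL_THRESHOLD
                    ) -> MarkerCall:
    """Call an arm or whole-chromosome marker from its altered-bin fractions."""
    marker_bins = np.asarray(marker_bins, dtype=np.int64)
    valid = marker_bins[profile.valid[marker_bins]]
    if valid.size < MIN_ARM_BINS:
        return MarkerCall(marker_id, INDETERMINATE, float("nan"), 0.0,
                          int(valid.size),
                          f"only {valid.size} valid bins (< {MIN_ARM_BINS})")
    states = seg.copy_state[valid]
    loss_frac = float(np.mean(states < 2))
    gain_frac = float(np.mean(states > 2))
    mean_copy = copy_value_at(profile, valid)
    notes = []
    if loss_frac >= arm_call_threshold:
        status, altered = HEMIZYGOUS_LOSS, loss_frac
    elif gain_frac >= arm_call_threshold:
        status, altered = GAIN, gain_frac
    else:
        status, altered = NEUTRAL, max(loss_frac, gain_frac)
        if PARTIAL_NOTE_FLOOR <= loss_frac < arm_call_threshold:
            notes.append(f"partial loss over {loss_frac:.0%} of bins")
        if PARTIAL_NOTE_FLOOR <= gain_frac < arm_call_threshold:
            notes.append(f"partial gain over {gain_frac:.0%} of bins")
    return MarkerCall(marker_id, status, mean_copy, altered, int(valid.size),
                      "; ".join(notes))


def assemble_marker_table(calls: Mapping[str, MarkerCall]) -> MarkerTable:
    """Compute the diagnostic composites from the six per-marker calls."""
    required = ("CDKN2AB", "EGFR", "ARM_1P", "ARM_19Q", "CHR7", "CHR10")
    missing = [m for m in required if m not in calls]
    if missing:
        raise GridConsistencyError(f"missing marker calls: {missing}")

    def composite(a: str, b: str, pred_a, pred_b) -> bool | None:
        sa, sb = calls[a].status, calls[b].status
        if INDETERMINATE in (sa, sb):
            return None
        return pred_a(sa) and pred_b(sb)

    codel = composite("ARM_1P", "ARM_19Q",
                      lambda s: s in LOSSES, lambda s: s in LOSSES)
    plus7_minus10 = composite("CHR7", "CHR10",
                              lambda s: s in (GAIN, AMPLIFICATION),
                              lambda s: s in LOSSES)
    return MarkerTable(calls=dict(calls), codeletion_1p19q=codel,
                       plus7_minus10=plus7_minus10)


def call_all_markers(seg: SegmentationResult, profile: CorrectedProfile,
                     catalog: MarkerCatalog, grid: BinGrid,
                     baseline: DeletionBaseline,
                     arm_call_threshold: float = DEFAULT_ARM_CALL_THRESHOLD,
                     amplification_state: int = DEFAULT_AMPLIFICATION_STATE
                     ) -> MarkerTable:
    """Call every catalog marker and assemble the table."""
    calls: dict[str, MarkerCall] = {}
    for entry in catalog.entries:
        bins = locate_marker_bins(catalog, grid, entry.marker_id)
        if entry.kind == "focal":
            calls[entry.marker_id] = call_focal_marker(
                seg, profile, bins, entry.marker_id, baseline,
                amplification_state=amplification_state)
        else:
            calls[entry.marker_id] = call_arm_marker(
                seg, profile, bins, entry.marker_id,
                arm_call_threshold=arm_call_threshold)
    return assemble_marker_table(calls)
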