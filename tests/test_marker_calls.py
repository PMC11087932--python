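import itertools

import numpy as np
import pytest

from gliocnv.cnv_hmm import SegmentationResult, expected_log2_ratio
from gliocnv.errors import GridConsistencyError
from gliocnv.genome_model import locate_marker_bins
from gliocnv.marker_calls import (AMPLIFICATION, GAIN, HEMIZYGOUS_LOSS,
                                  HOMOZYGOUS_LOSS, INDETERMINATE, MarkerCall,
                                  NEUTRAL, assemble_marker_table,
                                  call_arm_marker, call_focal_marker)

from conftest import make_profile


def make_seg(grid, states, t=0.6, informative=True):
    states = np.asarray(states)
    return SegmentationResult(
        grid=grid, copy_state=states, segments=[], tumor_fraction=t,
        log_likelihood=0.0,
        expected_log2=np.zeros(grid.n_bins), tf_informative=informative)


def profile_for_states(grid, states, t):
    log2 = np.array([expected_log2_ratio(max(int(s), 0), t) if s >= 0 else np.nan
                     for s in states])
    return make_profile(grid, log2, np.asarray(states) >= 0)


@pytest.fixture
def marker_env(hg38_grid, hg38_catalog):
    def build(status_map, t=0.6):
        """states: per-marker planted copy state (others neutral)."""
        states = np.full(hg38_grid.n_bins, 2)
        for marker_id, state in status_map.items():
            bins = locate_marker_bins(hg38_catalog, hg38_grid, marker_id)
            states[bins] = state
        profile = profile_for_states(hg38_grid, states, t)
        return make_seg(hg38_grid, states, t), profile
    return build


class TestFocalCalls:
    def test_all_neutral_marker(self, marker_env, hg38_grid, hg38_catalog,
                                ideal_baseline):
        seg, profile = marker_env({})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "CDKN2AB")
        call = call_focal_marker(seg, profile, bins, "CDKN2AB", ideal_baseline)
        assert call.status == NEUTRAL
        assert call.mean_copy == pytest.approx(2.0)

    def test_homozygous_deletion_with_ideal_baseline(self, marker_env,
                                                     hg38_grid, hg38_catalog,
                                                     ideal_baseline):
        seg, profile = marker_env({"CDKN2AB": 0}, t=0.5)
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "CDKN2AB")
        call = call_focal_marker(seg, profile, bins, "CDKN2AB", ideal_baseline)
        assert call.status == HOMOZYGOUS_LOSS
        assert call.mean_copy == pytest.approx(1.0)  # 2 - 2*0.5

    def test_hemizygous_deletion(self, marker_env, hg38_grid, hg38_catalog,
                                 ideal_baseline):
        seg, profile = marker_env({"CDKN2AB": 1}, t=0.6)
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "CDKN2AB")
        call = call_focal_marker(seg, profile, bins, "CDKN2AB", ideal_baseline)
        assert call.status == HEMIZYGOUS_LOSS

    def test_non_informative_tf_blocks_deletion_call(self, marker_env,
                                                     hg38_grid, hg38_catalog,
                                                     ideal_baseline):
        seg, profile = marker_env({"CDKN2AB": 1}, t=0.6)
        seg.tf_informative = False
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "CDKN2AB")
        call = call_focal_marker(seg, profile, bins, "CDKN2AB", ideal_baseline)
        assert call.status == NEUTRAL

    @pytest.mark.parametrize("state,expected", [
        (5, AMPLIFICATION), (4, GAIN), (3, GAIN), (2, NEUTRAL),
        (1, HEMIZYGOUS_LOSS), (0, HOMOZYGOUS_LOSS)])
    def test_egfr_status_by_modal_state(self, marker_env, hg38_grid,
                                        hg38_catalog, ideal_baseline, state,
                                        expected):
        seg, profile = marker_env({"EGFR": state}, t=0.8)
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "EGFR")
        call = call_focal_marker(seg, profile, bins, "EGFR", ideal_baseline)
        assert call.status == expected

    def test_no_valid_bins_indeterminate(self, marker_env, hg38_grid,
                                         hg38_catalog, ideal_baseline):
        seg, profile = marker_env({})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "EGFR")
        profile.valid[bins] = False
        call = call_focal_marker(seg, profile, bins, "EGFR", ideal_baseline)
        assert call.status == INDETERMINATE
        assert call.bins_used == 0


class TestArmCalls:
    def test_complete_loss(self, marker_env, hg38_grid, hg38_catalog):
        seg, profile = marker_env({"ARM_1P": 1})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "ARM_1P")
        call = call_arm_marker(seg, profile, bins, "ARM_1P")
        assert call.status == HEMIZYGOUS_LOSS
        assert call.fraction_of_bins_altered == pytest.approx(1.0)

    def test_partial_loss_noted_not_called(self, marker_env, hg38_grid,
                                           hg38_catalog):
        seg, profile = marker_env({})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "ARM_1P")
        half = bins[: bins.size // 2]
        seg.copy_state[half] = 1
        call = call_arm_marker(seg, profile, bins, "ARM_1P")
        assert call.status == NEUTRAL
        assert "partial loss" in call.evidence_note

    def test_complete_gain(self, marker_env, hg38_grid, hg38_catalog):
        seg, profile = marker_env({"CHR7": 3})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "CHR7")
        call = call_arm_marker(seg, profile, bins, "CHR7")
        assert call.status == GAIN

    def test_coverage_floor(self, marker_env, hg38_grid, hg38_catalog):
        seg, profile = marker_env({})
        bins = locate_marker_bins(hg38_catalog, hg38_grid, "ARM_19Q")
        profile.valid[bins[4:]] = False
        call = call_arm_marker(seg, profile, bins, "ARM_19Q")
        assert call.status == INDETERMINATE

    def test_loss_call_monotone_in_deletion_depth(self, marker_env, hg38_grid,
                                                  hg38_catalog):
        """Deepening a called loss (state 1 -> 0) can never flip it to
        neutral."""
        for state in (1, 0):
            seg, profile = marker_env({"CHR10": state})
            bins = locate_marker_bins(hg38_catalog, hg38_grid, "CHR10")
            call = call_arm_marker(seg, profile, bins, "CHR10")
            assert call.status == HEMIZYGOUS_LOSS


def mk_call(marker_id, status):
    return MarkerCall(marker_id=marker_id, status=status, mean_copy=2.0,
                      fraction_of_bins_altered=0.0, bins_used=10)


def table_from(statuses):
    defaults = {m: NEUTRAL for m in
                ("CDKN2AB", "EGFR", "ARM_1P", "ARM_19Q", "CHR7", "CHR10")}
    defaults.update(statuses)
    return assemble_marker_table(
        {m: mk_call(m, s) for m, s in defaults.items()})


class TestComposites:
    ARM_STATUSES = (NEUTRAL, HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS, INDETERMINATE)

    def test_codeletion_truth_table(self):
        for s1p, s19q in itertools.product(self.ARM_STATUSES, repeat=2):
            table = table_from({"ARM_1P": s1p, "ARM_19Q": s19q})
            if INDETERMINATE in (s1p, s19q):
                assert table.codeletion_1p19q is None
            else:
                expected = (s1p in (HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS) and
                            s19q in (HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS))
                assert table.codeletion_1p19q is expected

    def test_plus7_minus10_truth_table(self):
        chr7_statuses = (NEUTRAL, GAIN, AMPLIFICATION, INDETERMINATE)
        for s7, s10 in itertools.product(chr7_statuses, self.ARM_STATUSES):
            table = table_from({"CHR7": s7, "CHR10": s10})
            if INDETERMINATE in (s7, s10):
                assert table.plus7_minus10 is None
            else:
                expected = (s7 in (GAIN, AMPLIFICATION) and
                            s10 in (HEMIZYGOUS_LOSS, HOMOZYGOUS_LOSS))
                assert table.plus7_minus10 is expected

    def test_one_sided_loss_is_not_codeletion(self):
        table = table_from({"ARM_1P": HEMIZYGOUS_LOSS})
        assert table.codeletion_1p19q is False

    def test_missing_marker_raises(self):
        calls = {m: mk_call(m, NEUTRAL) for m in ("CDKN2AB", "EGFR")}
        with pytest.raises(GridConsistencyError):
            assemble_marker_table(calls)

    def test_json_export_round_trips_values(self, tmp_path):
        import json
        table = table_from({"ARM_1P": HEMIZYGOUS_LOSS,
                            "ARM_19Q": HEMIZYGOUS_LOSS})
        path = tmp_path / "markers.json"
        table.to_json(str(path))
        data = json.loads(path.read_text())
        assert data["codeletion_1p19q"] is True
        assert data["markers"]["ARM_1P"]["status"] == HEMIZYGOUS_LOSS
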