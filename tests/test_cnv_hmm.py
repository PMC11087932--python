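import itertools
import math

import numpy as np
import pytest

from gliocnv.cnv_hmm import (HMMConfig, LOG2_FLOOR, estimate_emission_sd,
                             estimate_tumor_fraction, expected_log2_ratio,
                             merge_segments, path_score, viterbi_segment)
from gliocnv.errors import InsufficientDataError, InvalidParameterError
from gliocnv.genome_model import GenomeBuild, build_bin_grid
from gliocnv.simulate import Event, simulate_log2_profile

from conftest import make_profile


def single_chrom_grid(n_bins):
    build = GenomeBuild(name="toy", chrom_lengths={"chrA": n_bins * 500_000},
                        arm_boundaries={})
    return build_bin_grid(build, 500_000)


def brute_force_best_path(obs, tumor_fraction, config, sd):
    """Independent oracle: enumerate every state path over one chromosome and
    score it from the model definition with plain Python arithmetic."""
    states = config.copy_states
    K = len(states)
    best = (-math.inf, None)
    for path in itertools.product(range(K), repeat=len(obs)):
        total = math.log(1.0 / K)
        prev = None
        for x, s in zip(obs, path):
            if prev is not None:
                total += math.log1p(-config.switch_prob) if s == prev \
                    else math.log(config.switch_prob / (K - 1))
            c = states[s]
            mix = tumor_fraction * c + 2 * (1 - tumor_fraction)
            center = max(math.log2(mix / 2) if mix > 0 else -math.inf,
                         LOG2_FLOOR)
            total += (-math.log(sd * math.sqrt(2 * math.pi))
                      - 0.5 * ((x - center) / sd) ** 2)
            total += -config.neutral_state_bias * abs(c - config.normal_copy)
            prev = s
        if total > best[0]:
            best = (total, path)
    return best


class TestExpectedLog2:
    @pytest.mark.parametrize("t", [0.05, 0.3, 0.7, 1.0])
    def test_neutral_copy_is_zero_for_any_t(self, t):
        assert expected_log2_ratio(2, t) == 0.0

    def test_closed_forms(self):
        assert expected_log2_ratio(4, 1.0) == pytest.approx(1.0)
        assert expected_log2_ratio(0, 0.5) == pytest.approx(-1.0)
        assert expected_log2_ratio(0, 1.0) == -np.inf

    def test_strictly_increasing_in_copy(self):
        for t in (0.2, 0.6, 1.0):
            vals = [expected_log2_ratio(c, t) for c in range(6)]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            expected_log2_ratio(-1, 0.5)
        with pytest.raises(InvalidParameterError):
            expected_log2_ratio(2, 0.0)


class TestViterbi:
    def test_flat_profile_is_all_neutral(self):
        grid = single_chrom_grid(30)
        rng = np.random.default_rng(0)
        profile = make_profile(grid, rng.normal(0, 0.05, 30))
        states, _ = viterbi_segment(profile, 0.5, HMMConfig())
        assert (states == 2).all()

    def test_exact_emission_match_recovers_arm_loss(self):
        grid = single_chrom_grid(20)
        log2 = np.zeros(20)
        log2[:8] = -1.0  # exactly expected_log2(0, 0.5)
        profile = make_profile(grid, log2)
        states, _ = viterbi_segment(profile, 0.5,
                                    HMMConfig(emission_sd=0.05))
        assert (states[:8] == 0).all() and (states[8:] == 2).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        config = HMMConfig(copy_states=(0, 1, 2, 3), switch_prob=0.05,
                           emission_sd=1.0)
        sd = 0.25
        t = float(rng.choice([0.3, 0.5, 0.8, 1.0]))
        grid = single_chrom_grid(n)
        obs = rng.uniform(-2.5, 1.2, n)
        profile = make_profile(grid, obs)
        states, loglik = viterbi_segment(profile, t, config, sd=sd)
        best_score, best_path = brute_force_best_path(obs, t, config, sd)
        assert loglik == pytest.approx(best_score, abs=1e-9)
        assert tuple(states) == tuple(config.copy_states[s] for s in best_path)

    def test_invalid_bins_bridged_by_single_transition(self):
        rng = np.random.default_rng(4)
        n = 7
        config = HMMConfig(copy_states=(0, 1, 2, 3), switch_prob=0.05,
                           emission_sd=1.0)
        grid = single_chrom_grid(n)
        obs = rng.uniform(-2, 1, n)
        valid = np.ones(n, dtype=bool)
        valid[[2, 5]] = False
        profile = make_profile(grid, obs, valid)
        states, loglik = viterbi_segment(profile, 0.5, config, sd=0.3)
        # oracle over valid bins only; the bridge is one ordinary transition
        best_score, best_path = brute_force_best_path(obs[valid], 0.5, config, 0.3)
        assert loglik == pytest.approx(best_score, abs=1e-9)
        assert (states[~valid] == -1).all()

    def test_reported_score_equals_path_score(self):
        grid = single_chrom_grid(25)
        rng = np.random.default_rng(8)
        log2 = np.where(np.arange(25) < 10, -0.4, 0.0) + rng.normal(0, 0.1, 25)
        profile = make_profile(grid, log2)
        config = HMMConfig(emission_sd=0.1)
        states, loglik = viterbi_segment(profile, 0.5, config)
        assert loglik == pytest.approx(
            path_score(profile, states, 0.5, config, 0.1), rel=1e-12)

    def test_no_valid_bins_raises(self):
        grid = single_chrom_grid(5)
        profile = make_profile(grid, np.full(5, np.nan),
                               np.zeros(5, dtype=bool))
        with pytest.raises(InsufficientDataError):
            viterbi_segment(profile, 0.5, HMMConfig(emission_sd=0.1))


class TestMergeSegments:
    def test_single_state_two_chromosomes(self, toy_grid):
        n = toy_grid.n_bins
        profile = make_profile(toy_grid, np.zeros(n))
        segments = merge_segments(np.full(n, 2), toy_grid, profile)
        assert len(segments) == 2
        assert {s.chrom for s in segments} == {"chr1", "chr2"}

    def test_three_runs(self):
        grid = single_chrom_grid(5)
        profile = make_profile(grid, np.zeros(5))
        segments = merge_segments(np.array([2, 2, 0, 0, 2]), grid, profile)
        assert [(s.copy_state, s.n_bins) for s in segments] == \
            [(2, 2), (0, 2), (2, 1)]
        assert segments[0].start == 0 and segments[-1].end == grid.end[-1]

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzz_bin_conservation(self, seed, toy_grid):
        rng = np.random.default_rng(seed)
        n = toy_grid.n_bins
        valid = rng.random(n) > 0.2
        profile = make_profile(toy_grid, np.where(valid, 0.0, np.nan), valid)
        states = np.where(valid, rng.integers(0, 6, n), -1)
        segments = merge_segments(states, toy_grid, profile)
        assert sum(s.n_bins for s in segments) == valid.sum()
        # adjacent segments on one chromosome differ in state
        by_chrom = {}
        for s in segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for runs in by_chrom.values():
            assert all(a.copy_state != b.copy_state
                       for a, b in zip(runs, runs[1:]))


class TestTumorFraction:
    def test_noiseless_profile_recovers_exact_grid_point(self):
        grid = single_chrom_grid(150)
        t_true = 0.40
        log2 = np.zeros(150)
        log2[:60] = expected_log2_ratio(1, t_true)   # planted loss
        log2[100:130] = expected_log2_ratio(3, t_true)
        profile = make_profile(grid, log2)
        config = HMMConfig(emission_sd=0.05, min_valid_bins=50)
        seg = estimate_tumor_fraction(profile, config)
        assert seg.tumor_fraction == t_true
        assert seg.tf_informative

    def test_pure_normal_flags_non_informative(self):
        grid = single_chrom_grid(200)
        rng = np.random.default_rng(5)
        profile = make_profile(grid, rng.normal(0, 0.08, 200))
        seg = estimate_tumor_fraction(profile, HMMConfig())
        assert (seg.copy_state[profile.valid] == 2).all()
        assert not seg.tf_informative
        assert seg.tumor_fraction == pytest.approx(0.05)  # smallest grid t

    def test_simulated_events_recovered(self, hg38_grid):
        events = (Event(marker_id="CHR10", tumor_copy=1),
                  Event(marker_id="CHR7", tumor_copy=3))
        profile, truth = simulate_log2_profile(hg38_grid, 0.6, events, 0.1,
                                               seed=7)
        seg = estimate_tumor_fraction(profile, HMMConfig())
        assert abs(seg.tumor_fraction - 0.6) <= 0.05
        acc = np.mean(seg.copy_state[profile.valid] ==
                      np.clip(truth.copy[profile.valid], 0, 5))
        assert acc >= 0.95

    def test_reported_likelihood_matches_path_score(self, hg38_grid):
        events = (Event(marker_id="CHR10", tumor_copy=1),)
        profile, _ = simulate_log2_profile(hg38_grid, 0.5, events, 0.1, seed=3)
        config = HMMConfig()
        seg = estimate_tumor_fraction(profile, config)
        recomputed = path_score(profile, seg.copy_state, seg.tumor_fraction,
                                config, seg.emission_sd)
        assert seg.log_likelihood == pytest.approx(recomputed, rel=1e-10)

    def test_determinism(self, hg38_grid):
        events = (Event(marker_id="CHR10", tumor_copy=1),)
        profile, _ = simulate_log2_profile(hg38_grid, 0.5, events, 0.1, seed=3)
        a = estimate_tumor_fraction(profile, HMMConfig())
        b = estimate_tumor_fraction(profile, HMMConfig())
        assert a.tumor_fraction == b.tumor_fraction
        assert np.array_equal(a.copy_state, b.copy_state)
        assert a.log_likelihood == b.log_likelihood

    def test_min_bin_floor(self):
        grid = single_chrom_grid(20)
        profile = make_profile(grid, np.zeros(20))
        with pytest.raises(InsufficientDataError):
            estimate_tumor_fraction(profile, HMMConfig(min_valid_bins=100))

    def test_emission_sd_estimator_tracks_truth(self):
        grid = single_chrom_grid(500)
        rng = np.random.default_rng(0)
        profile = make_profile(grid, rng.normal(0, 0.12, 500))
        assert estimate_emission_sd(profile) == pytest.approx(0.12, rel=0.2)
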