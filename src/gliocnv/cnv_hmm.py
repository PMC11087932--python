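"""Copy-number segmentation and tumor-fraction estimation.

The model is a hidden Markov model over integer copy states 0..5 (5 meaning
">=5"). For tumor fraction t, a bin with tumor copy number c has expected
log2 ratio

    mu(c, t) = log2((t*c + 2*(1 - t)) / 2)

i.e. the bulk sample is a mixture of tumor cells at copy c and diploid
normal cells; at c = 2 the expectation is 0 for every t. Emissions are
Gaussian around mu(c, t) with a shared standard deviation (estimated from
the data by default), plus a per-bin log-prior -alpha*|c - 2| that favors
the copy-neutral state. The prior is what makes tumor fraction
identifiable: without it, any profile whose aberrant copies c all satisfy
2c - 2 in {0..5} has an exactly likelihood-tied "halved purity"
interpretation (t/2 with every deviation doubled) — the classic
purity/ploidy ambiguity. The prior deterministically resolves the tie
toward the least-aberrant genome, which is the interpretation at the true
tumor fraction.

Transitions keep the current state with probability 1 - switch_prob and
move to each other state with probability switch_prob/(K-1); chromosomes
are segmented independently, and invalid bins are bridged by a single
transition without emitting.

Tumor fraction is estimated by running Viterbi at every t on a grid
(default 0.05..1.00, step 0.01) and keeping the t with the highest path
score; exact ties break toward smaller t. If the best path is entirely
copy-neutral the profile carries no information about t and the result is
flagged non-informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .genome_model import BinGrid
from .normalization import CorrectedProfile

LOG2_FLOOR = -8.0  # clamp for the c=0, t→1 center (copy value ~0.008)


def default_tf_grid() -> np.ndarray:
    """0.05 .. 1.00 in steps of 0.01."""
    return np.arange(5, 101) / 100.0


@dataclass
class HMMConfig:
    """Parameters of the segmentation model.

    ``emission_sd=None`` means "estimate from the data" via the median
    absolute deviation of first differences of valid log2 ratios
    (sd = 1.4826 * MAD / sqrt(2)), a robust noise estimate that ignores
    segment structure. ``neutral_state_bias`` is the per-bin log-prior
    penalty per copy step away from diploid (see module docstring).
    """

    copy_states: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    normal_copy: int = 2
    switch_prob: float = 1e-4
    emission_sd: float | None = None
    tf_grid: np.ndarray = field(default_factory=default_tf_grid)
    neutral_state_bias: float = 0.1
    min_valid_bins: int = 100
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.switch_prob < 0.5):
            raise InvalidParameterError("switch_prob must lie in (0, 0.5)")
        self.tf_grid = np.asarray(self.tf_grid, dtype=float)
        if np.any((self.tf_grid <= 0) | (self.tf_grid > 1)):
            raise InvalidParameterError("tf_grid values must lie in (0, 1]")
        if self.normal_copy not in self.copy_states:
            raise InvalidParameterError("copy_states must include normal_copy")
        if self.emission_sd is not None and self.emission_sd <= 0:
            raise InvalidParameterError("emission_sd must be positive")


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    copy_state: int
    mean_log2: float
    n_bins: int


@dataclass
class SegmentationResult:
    """Viterbi segmentation at the selected tumor fraction."""

    grid: BinGrid
    copy_state: np.ndarray          # int per bin, -1 where invalid
    segments: list[Segment]
    tumor_fraction: float
    log_likelihood: float
    expected_log2: np.ndarray       # NaN where invalid
    tf_informative: bool = True
    tf_loglik: dict = field(default_factory=dict)   # t -> best path score
    emission_sd: float = float("nan")
    sample_id: str = "sample"

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "sample": self.sample_id, "chrom": s.chrom, "start": s.start,
            "end": s.end, "n_bins": s.n_bins, "mean_log2": s.mean_log2,
            "copy_state": s.copy_state,
        } for s in self.segments])

    def to_seg(self, path: str) -> None:
        self.segments_frame().to_csv(path, sep="\t", index=False,
                                     float_format="%.6g")

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for s in self.segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t"
                         f"CN{s.copy_state}\t{s.mean_log2:.4g}\n")


def expected_log2_ratio(copy_state, tumor_fraction):
    """Expected log2 ratio of copy state c at tumor fraction t.

    Vectorized over either argument. Returns -inf when the mixture copy
    value is 0 (c = 0, t = 1); callers clamp for emission scoring.
    """
    c = np.asarray(copy_state, dtype=float)
    t = np.asarray(tumor_fraction, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("copy_state must be >= 0")
    if np.any((t <= 0) | (t > 1)):
        raise InvalidParameterError("tumor_fraction must lie in (0, 1]")
    mix = t * c + 2.0 * (1.0 - t)
    with np.errstate(divide="ignore"):
        out = np.log2(mix / 2.0)
    if out.ndim == 0:
        return float(out)
    return out


def estimate_emission_sd(profile: CorrectedProfile, floor: float = 0.01) -> float:
    """Robust per-bin noise estimate from within-chromosome first differences."""
    diffs = []
    for chrom, sl in profile.grid.chrom_slices.items():
        vals = profile.log2_ratio[sl][profile.valid[sl]]
        if vals.size >= 2:
            diffs.append(np.diff(vals))
    if not diffs:
        return floor
    d = np.concatenate(diffs)
    mad = np.median(np.abs(d - np.median(d)))
    return max(float(1.4826 * mad / math.sqrt(2.0)), floor)


def _state_centers(config: HMMConfig, tf: np.ndarray) -> np.ndarray:
    """(T, K) emission centers, clamped at LOG2_FLOOR."""
    states = np.asarray(config.copy_states, dtype=float)
    centers = expected_log2_ratio(states[None, :], np.asarray(tf)[:, None])
    return np.maximum(centers, LOG2_FLOOR)


def _viterbi_chrom_batch(obs: np.ndarray, centers: np.ndarray, sd: float,
                         config: HMMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Viterbi over one chromosome's valid bins, batched over tumor fractions.

    obs: (n,) observed log2 ratios; centers: (T, K).
    Returns (states (T, n), score (T,)).
    """
    n = obs.size
    T, K = centers.shape
    prior = -config.neutral_state_bias * np.abs(
        np.asarray(config.copy_states, dtype=float) - config.normal_copy
    )
    log_norm = -math.log(sd * math.sqrt(2.0 * math.pi))
    # (n, T, K) emission + prior scores
    z = (obs[:, None, None] - centers[None, :, :]) / sd
    emis = log_norm - 0.5 * z * z + prior[None, None, :]

    A = np.full((K, K), math.log(config.switch_prob / (K - 1)))
    np.fill_diagonal(A, math.log1p(-config.switch_prob))

    delta = -math.log(K) + emis[0]                    # uniform initial distribution
    back = np.zeros((n, T, K), dtype=np.int8)
    for i in range(1, n):
        cand = delta[:, :, None] + A[None, :, :]      # (T, K_prev, K_next)
        back[i] = np.argmax(cand, axis=1)
        delta = np.take_along_axis(cand, back[i][:, None, :], axis=1)[:, 0, :] \
            + emis[i]
    last = np.argmax(delta, axis=1)                   # (T,)
    score = delta[np.arange(T), last]
    states = np.empty((T, n), dtype=np.int64)
    states[:, n - 1] = last
    rows = np.arange(T)
    for i in range(n - 2, -1, -1):
        states[:, i] = back[i + 1][rows, states[:, i + 1]]
    return states, score


def viterbi_segment(profile: CorrectedProfile, tumor_fraction: float,
                    config: HMMConfig | None = None,
                    sd: float | None = None
                    ) -> tuple[np.ndarray, float]:
    """Maximum-score state path at a fixed tumor fraction.

    Returns (per-bin copy states with -1 at invalid bins, path score). The
    score is the joint log-probability of the path and the observations
    under the model (including the neutral-state prior).
    """
    config = config or HMMConfig()
    if sd is None:
        sd = config.emission_sd or estimate_emission_sd(profile)
    if sd <= 0:
        raise InvalidParameterError("emission sd must be positive")
    if not profile.valid.any():
        raise InsufficientDataError("profile has no valid bins")
    centers = _state_centers(config, np.asarray([tumor_fraction]))
    states_out = np.full(profile.grid.n_bins, -1, dtype=np.int64)
    total = 0.0
    copy_states = np.asarray(config.copy_states)
    for chrom, sl in profile.grid.chrom_slices.items():
        vmask = profile.valid[sl]
        if not vmask.any():
            continue
        obs = profile.log2_ratio[sl][vmask]
        states, score = _viterbi_chrom_batch(obs, centers, sd, config)
        idx = np.nonzero(vmask)[0] + sl.start
        states_out[idx] = copy_states[states[0]]
        total += float(score[0])
    return states_out, total


def merge_segments(states: np.ndarray, grid: BinGrid,
                   profile: CorrectedProfile) -> list[Segment]:
    """Maximal runs of identical copy state per chromosome (valid bins only).

    Segment coordinates span from the first to the last valid bin of the
    run; ``n_bins`` counts valid bins and ``mean_log2`` averages over them.
    """
    segments: list[Segment] = []
    for chrom, sl in grid.chrom_slices.items():
        idx = np.nonzero(profile.valid[sl])[0] + sl.start
        if idx.size == 0:
            continue
        run_start = 0
        st = states[idx]
        for i in range(1, idx.size + 1):
            if i == idx.size or st[i] != st[run_start]:
                members = idx[run_start:i]
                segments.append(Segment(
                    chrom=chrom,
                    start=int(grid.start[members[0]]),
                    end=int(grid.end[members[-1]]),
                    copy_state=int(st[run_start]),
                    mean_log2=float(np.mean(profile.log2_ratio[members])),
                    n_bins=int(members.size),
                ))
                run_start = i
    return segments


def estimate_tumor_fraction(profile: CorrectedProfile,
                            config: HMMConfig | None = None
                            ) -> SegmentationResult:
    """Grid-scan tumor fraction, segmenting at each candidate t.

    Returns the segmentation with the highest path score; exact ties break
    toward the smaller t (the grid is scanned in ascending order). When the
    winning path is entirely copy-neutral, the data carry no information
    about t and ``tf_informative`` is False.
    """
    config = config or HMMConfig()
    n_valid = int(profile.valid.sum())
    if n_valid == 0:
        raise InsufficientDataError("profile has no valid bins")
    if n_valid < config.min_valid_bins:
        raise InsufficientDataError(
            f"{n_valid} valid bins < floor of {config.min_valid_bins}"
        )
    sd = config.emission_sd or estimate_emission_sd(profile)
    tf = config.tf_grid
    centers = _state_centers(config, tf)
    T = tf.size
    copy_states = np.asarray(config.copy_states)

    total_scores = np.zeros(T)
    per_chrom_states: list[tuple[np.ndarray, np.ndarray]] = []
    for chrom, sl in profile.grid.chrom_slices.items():
        vmask = profile.valid[sl]
        if not vmask.any():
            continue
        obs = profile.log2_ratio[sl][vmask]
        states, scores = _viterbi_chrom_batch(obs, centers, sd, config)
        idx = np.nonzero(vmask)[0] + sl.start
        per_chrom_states.append((idx, states))
        total_scores += scores

    best = int(np.argmax(total_scores))  # first maximum -> smallest t on ties
    t_hat = float(tf[best])
    states_out = np.full(profile.grid.n_bins, -1, dtype=np.int64)
    for idx, states in per_chrom_states:
        states_out[idx] = copy_states[states[best]]

    valid = profile.valid
    informative = bool(np.any(states_out[valid] != config.normal_copy))
    expected = np.full(profile.grid.n_bins, np.nan)
    expected[valid] = np.maximum(
        expected_log2_ratio(states_out[valid].astype(float), t_hat), LOG2_FLOOR
    )
    return SegmentationResult(
        grid=profile.grid,
        copy_state=states_out,
        segments=merge_segments(states_out, profile.grid, profile),
        tumor_fraction=t_hat,
        log_likelihood=float(total_scores[best]),
        expected_log2=expected,
        tf_informative=informative,
        tf_loglik={float(t): float(s) for t, s in zip(tf, total_scores)},
        emission_sd=float(sd),
        sample_id=profile.sample_id,
    )


def path_score(profile: CorrectedProfile, states: np.ndarray,
               tumor_fraction: float, config: HMMConfig, sd: float) -> float:
    """Joint log-probability of an explicit state path — the quantity Viterbi
    maximizes. Used to verify reported likelihoods and by the brute-force
    test oracle."""
    copy_states = list(config.copy_states)
    K = len(copy_states)
    centers = _state_centers(config, np.asarray([tumor_fraction]))[0]
    prior = -config.neutral_state_bias * np.abs(
        np.asarray(copy_states, dtype=float) - config.normal_copy
    )
    log_stay = math.log1p(-config.switch_prob)
    log_switch = math.log(config.switch_prob / (K - 1))
    log_norm = -math.log(sd * math.sqrt(2.0 * math.pi))
    total = 0.0
    for chrom, sl in profile.grid.chrom_slices.items():
        idx = np.nonzero(profile.valid[sl])[0] + sl.start
        if idx.size == 0:
            continue
        total += -math.log(K)
        prev = None
        for i in idx:
            s = copy_states.index(int(states[i]))
            if prev is not None:
                total += log_stay if s == prev else log_switch
            z = (profile.log2_ratio[i] - centers[s]) / sd
            total += log_norm - 0.5 * z * z + prior[s]
            prev = s
    return total
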