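"""Per-electrode randomisation tests and Fisher combination.

First level: for each electrode, a Monte-Carlo randomisation test of the
Probe-vs-Irrelevant peak-to-peak difference. Under the null hypothesis
the two conditions' trials are exchangeable, so B random relabellings of
a matched pool of 2m trials into two m-sized surrogate conditions yield
a null distribution of the statistic. A trial is a *triple* (one segment
per electrode) and the relabelling is shared across electrodes, so the
null matrix preserves the within-trial cross-electrode correlations.

Second level: the three per-electrode p-values are combined with
Fisher's product method, −2·Σ ln p. Instead of referring the score to a
χ² distribution (which would require independence across electrodes),
each of the B resamples is itself converted to a triple of p-values
within the null matrix and Fisher-scored, giving an empirical null for
the combined score that inherits the electrode correlations.

The resolution of every p-value is 1/B; a reported 0 means "larger than
all B resamples" and is displayed as <1/B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .epochs_io import DetectionReport, EpochSet
from .peaks import P3A, P3B, PeakParams, peak_to_peak_batch
from .preprocess import BaselineWindow, baseline_correct, reject_amplitude

__all__ = [
    "FirstLevelConfig",
    "FirstLevelResult",
    "CombinedResult",
    "DetectConfig",
    "first_level",
    "per_resample_pvalues",
    "fisher_score",
    "combined_p",
    "detect_subject",
]

DEFAULT_PARAMS: dict[str, PeakParams] = {"Fz": P3A, "Cz": P3A, "Pz": P3B}


@dataclass(frozen=True)
class FirstLevelConfig:
    """Resampling configuration for the per-electrode tests."""

    B: int = 1000
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    params_per_channel: Mapping[str, PeakParams] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")
        if not self.channels:
            raise ValueError("need at least one channel")
        missing = [ch for ch in self.channels if ch not in self.params_per_channel]
        if missing:
            raise ValueError(f"no peak parameters for channel(s) {missing}")


@dataclass
class FirstLevelResult:
    """Observed statistics, the B × n_channels null matrix, and p-values."""

    m: int
    channels: tuple[str, ...]
    observed: dict[str, float]
    null_matrix: np.ndarray  # (B, n_channels)
    p_per_channel: dict[str, float]

    @property
    def B(self) -> int:
        return self.null_matrix.shape[0]


@dataclass
class CombinedResult:
    fisher_observed: float
    fisher_null: np.ndarray  # (B,)
    fisher_p: float


@dataclass(frozen=True)
class DetectConfig:
    """End-to-end configuration for a single-subject detection run."""

    B: int = 1000
    alpha: float = 0.05
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    params_per_channel: Mapping[str, PeakParams] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS)
    )
    probe_condition: str = "Probe"
    irrelevant_condition: str = "Irrelevant1"
    baseline: BaselineWindow = field(default_factory=BaselineWindow)
    reject_threshold: float = 50.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.B < 2:
            raise ValueError("B must be >= 2")

    def first_level_config(self) -> FirstLevelConfig:
        return FirstLevelConfig(
            B=self.B,
            channels=self.channels,
            params_per_channel=self.params_per_channel,
            seed=self.seed,
        )


def first_level(
    probe: EpochSet,
    irrelevant: EpochSet,
    cfg: FirstLevelConfig,
    rng: np.random.Generator | None = None,
) -> FirstLevelResult:
    """Per-electrode randomisation test of Probe against Irrelevant.

    The observed statistic uses *all* valid trials of each condition
    (the subject's true ERPs); the null matches the conditions to the
    smaller valid-trial count m by random sub-selection, then reshuffles
    the 2m pooled trials B times. The same relabelling is applied at
    every electrode. p = #(null > observed) / B, strictly greater, so
    ties count toward significance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not np.allclose(probe.times, irrelevant.times):
        raise ValueError("probe and irrelevant epochs on different time grids")
    ch_idx_p = [probe.channel_index(ch) for ch in cfg.channels]
    ch_idx_i = [irrelevant.channel_index(ch) for ch in cfg.channels]

    Xp = probe.stack()[:, ch_idx_p, :]
    Xi = irrelevant.stack()[:, ch_idx_i, :]
    n_p, n_i = Xp.shape[0], Xi.shape[0]
    if n_p < 2 or n_i < 2:
        raise ValueError(
            f"need >=2 valid trials per condition, have probe={n_p}, irrelevant={n_i}"
        )
    m = min(n_p, n_i)
    times = probe.times
    n_ch, n_s = len(cfg.channels), len(times)

    # observed: full valid-trial ERP difference, per channel
    d_obs = Xp.mean(axis=0) - Xi.mean(axis=0)  # (C, S)

    # matched pool of 2m trials (random without-replacement sub-selection)
    pool = np.concatenate(
        [Xp[rng.choice(n_p, m, replace=False)], Xi[rng.choice(n_i, m, replace=False)]]
    ).reshape(2 * m, n_ch * n_s)

    # B shared relabellings: first m rows of each permutation play Probe
    perm = np.argsort(rng.random((cfg.B, 2 * m)), axis=1)
    weights = np.full((cfg.B, 2 * m), -1.0 / m)
    np.put_along_axis(weights, perm[:, :m], 1.0 / m, axis=1)
    null_waves = (weights @ pool).reshape(cfg.B, n_ch, n_s)

    observed: dict[str, float] = {}
    null_matrix = np.empty((cfg.B, n_ch))
    p_per_channel: dict[str, float] = {}
    for c, ch in enumerate(cfg.channels):
        params = cfg.params_per_channel[ch]
        null_matrix[:, c] = peak_to_peak_batch(null_waves[:, c, :], times, params)[0]
        obs_c = float(peak_to_peak_batch(d_obs[c][None, :], times, params)[0][0])
        observed[ch] = obs_c
        # tie guard: the observed and null statistics travel different
        # floating-point paths (plain mean vs weight matmul), so genuine
        # ties — e.g. the relabelling that reproduces the true labels —
        # can come out an ulp apart; ties must count toward significance
        tol = 1e-9 * (1.0 + abs(obs_c))
        p_per_channel[ch] = float(np.sum(null_matrix[:, c] > obs_c + tol) / cfg.B)

    return FirstLevelResult(
        m=m,
        channels=tuple(cfg.channels),
        observed=observed,
        null_matrix=null_matrix,
        p_per_channel=p_per_channel,
    )


def per_resample_pvalues(null_matrix: np.ndarray) -> np.ndarray:
    """p-value of each resample within its own column's null distribution.

    p[i, c] = #(null[:, c] > null[i, c]) / B. A value is never strictly
    greater than itself, so attainable p's are {0, 1/B, …, (B−1)/B}.
    """
    null_matrix = np.atleast_2d(np.asarray(null_matrix, dtype=float))
    B = null_matrix.shape[0]
    if B < 2:
        raise ValueError("need B >= 2 resamples")
    out = np.empty_like(null_matrix)
    for c in range(null_matrix.shape[1]):
        col = null_matrix[:, c]
        order = np.sort(col)
        out[:, c] = (B - np.searchsorted(order, col, side="right")) / B
    return out


def fisher_score(p: np.ndarray, B: int = 1000) -> np.ndarray | float:
    """Fisher combined score −2·Σ ln p over the last axis.

    Zero p-values (the statistic beat all B resamples) are replaced by
    the smallest resolvable p-value 1/B before taking logs, since the
    underlying probability is merely below that floor, not zero.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.where(p == 0.0, 1.0 / B, p)
    score = -2.0 * np.sum(np.log(q), axis=-1)
    return float(score) if score.ndim == 0 else score


def combined_p(fl: FirstLevelResult, B: int | None = None) -> CombinedResult:
    """Fisher-combine the per-electrode tests against their resampled null.

    Each null-matrix row is converted to per-electrode p-values within
    the null columns, Fisher-scored, and the observed Fisher score is
    referred to those B scores: fisher_p = #(null scores > observed)/B.
    """
    if B is None:
        B = fl.B
    null_p = per_resample_pvalues(fl.null_matrix)
    fisher_null = fisher_score(null_p, B)
    obs_p = np.array([fl.p_per_channel[ch] for ch in fl.channels])
    fisher_observed = float(fisher_score(obs_p, B))
    fisher_p = float(np.sum(fisher_null > fisher_observed) / B)
    return CombinedResult(
        fisher_observed=fisher_observed, fisher_null=fisher_null, fisher_p=fisher_p
    )


def detect_subject(
    es: EpochSet,
    cfg: DetectConfig = DetectConfig(),
    rng: np.random.Generator | None = None,
) -> DetectionReport:
    """Full single-subject pipeline: preprocess → first level → Fisher.

    Baseline-corrects, applies ±threshold rejection, runs the
    per-electrode randomisation of Probe against Irrelevant1, combines
    with Fisher's method, and packages a report whose decision is
    fisher_p < alpha.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    es = baseline_correct(es, cfg.baseline)
    es = reject_amplitude(es, cfg.reject_threshold, channels=tuple(cfg.channels))
    probe = es.subset(cfg.probe_condition, valid_only=True)
    irrelevant = es.subset(cfg.irrelevant_condition, valid_only=True)
    fl = first_level(probe, irrelevant, cfg.first_level_config(), rng=rng)
    comb = combined_p(fl)
    return DetectionReport(
        subject_id=es.subject_id,
        observed=fl.observed,
        p_per_channel=fl.p_per_channel,
        fisher_p=comb.fisher_p,
        alpha=cfg.alpha,
        B=cfg.B,
        seed=cfg.seed,
        m=fl.m,
    )
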