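"""Group-level tests: paired t-tests, the early–late habituation
control, and the fixed-effects latency-difference randomisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .epochs_io import EpochSet, Waveform
from .erp import average_erp, difference_wave, pooled_average
from .peaks import (
    LatencyParams,
    PeakParams,
    latency_batch,
    peak_to_peak,
)
from .preprocess import split_half_chronological, split_parity
from .randtest import DEFAULT_PARAMS

__all__ = [
    "PairedTestResult",
    "LatencyTestResult",
    "paired_t",
    "early_late_analysis",
    "probe_vs_irrelevant2",
    "latency_difference_test",
    "latency_difference_from_epochs",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test with a 95% CI on the mean difference.

    ``degenerate`` flags zero-variance differences, where the t
    statistic is not finite: all-zero differences give t=0, p=1; a
    constant non-zero difference gives p=0 with ±inf t.
    """

    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    mean_diff: float
    degenerate: bool = False


@dataclass
class LatencyTestResult:
    """Fixed-effects latency-difference randomisation outcome (ms)."""

    observed_diff: float  # Fake latency − Probe latency
    null_diffs: np.ndarray  # (B,)
    p: float
    m: int


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test of per-subject values a against b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, n - 1, 1.0, (0.0, 0.0), 0.0, degenerate=True)
        t = float(np.inf if mean > 0 else -np.inf)
        return PairedTestResult(t, n - 1, 0.0, (mean, mean), mean, degenerate=True)
    res = stats.ttest_rel(a, b)
    lo, hi = res.confidence_interval(0.95)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        ci95=(float(lo), float(hi)),
        mean_diff=mean,
    )


def early_late_analysis(
    subjects: Iterable[EpochSet],
    params_per_channel: Mapping[str, PeakParams] | None = None,
    channels: Sequence[str] = ("Fz", "Cz", "Pz"),
    test_condition: str = "Irrelevant2",
    baseline_condition: str = "Irrelevant1",
) -> dict[str, PairedTestResult]:
    """Does repeated exposure change the response to an irrelevant item?

    Per subject and channel, the peak-to-peak of the (Late − Early)
    difference wave of ``test_condition`` trials is compared against the
    peak-to-peak of the (Even − Odd) difference wave of
    ``baseline_condition`` trials — a split in which no temporal effect
    can exist, giving a proper null baseline for the inherently
    positive-biased peak-to-peak measure. A paired t-test across
    subjects is run per channel.
    """
    if params_per_channel is None:
        params_per_channel = DEFAULT_PARAMS
    late_early: dict[str, list[float]] = {ch: [] for ch in channels}
    even_odd: dict[str, list[float]] = {ch: [] for ch in channels}
    for es in subjects:
        early, late = split_half_chronological(es, test_condition)
        odd, even = split_parity(es, baseline_condition)
        for ch in channels:
            params = params_per_channel[ch]
            d_time = difference_wave(
                average_erp(late, test_condition, ch),
                average_erp(early, test_condition, ch),
            )
            d_null = difference_wave(
                average_erp(even, baseline_condition, ch),
                average_erp(odd, baseline_condition, ch),
            )
            late_early[ch].append(peak_to_peak(d_time, params).p2p)
            even_odd[ch].append(peak_to_peak(d_null, params).p2p)
    return {ch: paired_t(late_early[ch], even_odd[ch]) for ch in channels}


def probe_vs_irrelevant2(
    subjects: Iterable[EpochSet],
    params_per_channel: Mapping[str, PeakParams] | None = None,
    channels: Sequence[str] = ("Fz", "Cz", "Pz"),
    baseline_condition: str = "Irrelevant1",
) -> dict[str, PairedTestResult]:
    """Group contrast of Probe vs Irrelevant2 peak-to-peak values.

    Both conditions are referenced to the Irrelevant1 ERP; the
    Irrelevant2 value provides the no-effect baseline that the
    positively biased peak-to-peak statistic requires.
    """
    if params_per_channel is None:
        params_per_channel = DEFAULT_PARAMS
    probe_vals: dict[str, list[float]] = {ch: [] for ch in channels}
    irr2_vals: dict[str, list[float]] = {ch: [] for ch in channels}
    for es in subjects:
        for ch in channels:
            params = params_per_channel[ch]
            base = average_erp(es, baseline_condition, ch)
            d_probe = difference_wave(average_erp(es, "Probe", ch), base)
            d_irr2 = difference_wave(average_erp(es, "Irrelevant2", ch), base)
            probe_vals[ch].append(peak_to_peak(d_probe, params).p2p)
            irr2_vals[ch].append(peak_to_peak(d_irr2, params).p2p)
    return {ch: paired_t(probe_vals[ch], irr2_vals[ch]) for ch in channels}


def latency_difference_test(
    fake: np.ndarray,
    probe: np.ndarray,
    times: np.ndarray,
    lp: LatencyParams,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> LatencyTestResult:
    """Fixed-effects randomisation test of a Fake − Probe latency shift.

    ``fake`` and ``probe`` are (n_trials, n_samples) pools of all
    subjects' trials at one electrode. The observed value is the latency
    of the fake pool's grand average minus that of the probe pool's.
    For the null, the pools are merged and two disjoint m-sized sets
    (m = the smaller pool) are drawn without replacement B times; each
    pair of surrogate grand averages yields one null latency difference.
    p = #(null > observed)/B.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fake = np.atleast_2d(np.asarray(fake, dtype=float))
    probe = np.atleast_2d(np.asarray(probe, dtype=float))
    if fake.shape[0] == 0 or probe.shape[0] == 0:
        raise ValueError("both trial pools must be non-empty")
    merged = np.concatenate([fake, probe], axis=0)
    total = merged.shape[0]
    m = min(fake.shape[0], probe.shape[0])
    if 2 * m > total:
        m = total // 2
        warnings.warn(
            f"pools too small for two disjoint sets of the matched size; using m={m}",
            stacklevel=2,
        )
    if m < 1:
        raise ValueError("merged pool admits no disjoint surrogate sets")

    observed = float(
        latency_batch(fake.mean(axis=0)[None, :], times, lp)[0]
        - latency_batch(probe.mean(axis=0)[None, :], times, lp)[0]
    )

    perm = np.argsort(rng.random((B, total)), axis=1)
    w_fake = np.zeros((B, total))
    np.put_along_axis(w_fake, perm[:, :m], 1.0 / m, axis=1)
    w_probe = np.zeros((B, total))
    np.put_along_axis(w_probe, perm[:, m : 2 * m], 1.0 / m, axis=1)
    lat_fake = latency_batch(w_fake @ merged, times, lp)
    lat_probe = latency_batch(w_probe @ merged, times, lp)
    null_diffs = lat_fake - lat_probe
    p = float(np.sum(null_diffs > observed) / B)
    return LatencyTestResult(observed_diff=observed, null_diffs=null_diffs, p=p, m=m)


def latency_difference_from_epochs(
    subjects: Iterable[EpochSet],
    channel: str,
    lp: LatencyParams,
    fake_condition: str = "Fake",
    probe_condition: str = "Probe",
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> LatencyTestResult:
    """Pool all subjects' valid trials at one electrode and run the test."""
    fakes, probes, times = [], [], None
    for es in subjects:
        if times is None:
            times = es.times
        ci = es.channel_index(channel)
        fakes.append(es.stack(fake_condition)[:, ci, :])
        probes.append(es.stack(probe_condition)[:, ci, :])
    if times is None:
        raise ValueError("no subjects supplied")
    return latency_difference_test(
        np.concatenate(fakes), np.concatenate(probes), times, lp, B=B, rng=rng
    )
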