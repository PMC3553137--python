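"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorised kernels in ``p300cit.peaks`` and
``p300cit.randtest``: window positions are enumerated one by one and
statistics recomputed with plain loops, so agreement is informative.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_TOL = 1e-9


def enumerate_starts(times, inner_ms, lo_ms, hi_ms):
    """All start indices whose inner window [t, t+inner) fits in [lo, hi)."""
    fs = 1000.0 / (times[1] - times[0])
    n_in = int(round(inner_ms * fs / 1000.0))
    out = []
    for k in range(len(times) - n_in + 1):
        if times[k] >= lo_ms - _TOL and times[k] + inner_ms <= hi_ms + _TOL:
            out.append(k)
    return out, n_in


def oracle_peak_to_peak(values, times, p):
    """Exhaustive-scan peak-to-peak: (p2p, high_k, low_k, degenerate)."""
    starts, n_in = enumerate_starts(times, p.inner, p.bound_start, p.bound_end)
    cap = p.bound_end if p.high_limit is None else p.high_limit
    high_candidates = [k for k in starts if times[k] + p.inner <= cap + _TOL]
    high_k, high_v = None, -np.inf
    for k in high_candidates:
        m = values[k : k + n_in].mean()
        if m > high_v:
            high_k, high_v = k, m
    low_candidates = [k for k in starts if k >= high_k + n_in]
    if not low_candidates:
        return 0.0, high_k, None, True
    low_k, low_v = None, np.inf
    for k in low_candidates:
        m = values[k : k + n_in].mean()
        if m < low_v:
            low_k, low_v = k, m
    return high_v - low_v, high_k, low_k, False


def oracle_latency(values, times, p):
    """Exhaustive-scan latency: start time of the maximal-mean window."""
    starts, n_in = enumerate_starts(times, p.inner, p.bound_start, p.bound_end)
    best_k, best_v = None, -np.inf
    for k in starts:
        m = values[k : k + n_in].mean()
        if m > best_v:
            best_k, best_v = k, m
    return times[best_k]


def exact_randomisation_p(probe, irrelevant, times, params):
    """Exact equal-split permutation p for the peak-to-peak statistic.

    ``probe``/``irrelevant`` are (n, S) arrays at one channel with equal
    n. Enumerates every way to relabel the pooled 2n trials into two
    n-sized groups; p = #(relabelled statistic > observed) / n_splits,
    counting each ordered assignment once.
    """
    probe = np.asarray(probe, float)
    irrelevant = np.asarray(irrelevant, float)
    n = probe.shape[0]
    pool = np.concatenate([probe, irrelevant])
    observed = oracle_peak_to_peak(
        probe.mean(axis=0) - irrelevant.mean(axis=0), times, params
    )[0]
    count = total = 0
    for group_a in combinations(range(2 * n), n):
        group_b = [i for i in range(2 * n) if i not in group_a]
        stat = oracle_peak_to_peak(
            pool[list(group_a)].mean(axis=0) - pool[group_b].mean(axis=0),
            times,
            params,
        )[0]
        count += stat > observed
        total += 1
    return count / total, observed
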