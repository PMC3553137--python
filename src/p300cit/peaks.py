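"""Windowed peak statistics on difference waves.

A "peak" is never a single sample: it is the mean amplitude over a short
*inner* window (50–100 ms) slid one sample at a time across a *bounding*
window. Two statistics are built on this primitive:

* **peak-to-peak** — the highest inner-window mean minus the lowest
  inner-window mean found at or after the first non-overlapping position
  following the highest one. For the early fronto-central component
  (P3a) the search for the highest peak is additionally capped: the
  inner window must end by 300 ms, so the later parietal positivity
  (P3b) cannot masquerade as the P3a's positive peak. With such a cap
  the statistic can be negative; without one it is non-negative.

* **latency** — the start time of the inner window with the maximal
  mean, ties broken towards the earliest start.

All window logic is half-open: an inner window starting at sample time t
covers [t, t + inner) ms, and must lie wholly inside the bounding range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs_io import Waveform

__all__ = [
    "PeakParams",
    "LatencyParams",
    "PeakToPeakResult",
    "P3A",
    "P3B",
    "P3A_LATENCY",
    "P3B_LATENCY",
    "PRESETS",
    "sliding_means",
    "peak_to_peak",
    "latency",
    "peak_to_peak_batch",
    "latency_batch",
]

_TOL = 1e-9


@dataclass(frozen=True)
class PeakParams:
    """Peak-to-peak search windows, all in ms.

    ``high_limit``, when set, caps the highest-peak search: the inner
    window must end at or before it.
    """

    bound_start: float
    bound_end: float
    inner: float
    high_limit: float | None = None

    def __post_init__(self) -> None:
        if not self.bound_start < self.bound_end:
            raise ValueError("bound_start must precede bound_end")
        if self.inner <= 0 or self.inner > self.bound_end - self.bound_start:
            raise ValueError("inner window must fit inside the bounding window")
        if self.high_limit is not None and not (
            self.bound_start < self.high_limit <= self.bound_end
        ):
            raise ValueError("high_limit must lie within (bound_start, bound_end]")


@dataclass(frozen=True)
class LatencyParams:
    """Latency search windows, all in ms."""

    bound_start: float
    bound_end: float
    inner: float

    def __post_init__(self) -> None:
        if not self.bound_start < self.bound_end:
            raise ValueError("bound_start must precede bound_end")
        if self.inner <= 0 or self.inner > self.bound_end - self.bound_start:
            raise ValueError("inner window must fit inside the bounding window")


#: Fronto-central component: bounding 150–1000 ms, 100 ms peaks, highest
#: peak constrained to end by 300 ms.
P3A = PeakParams(150.0, 1000.0, 100.0, 300.0)
#: Parietal component: bounding 300–1000 ms, 100 ms peaks, no cap.
P3B = PeakParams(300.0, 1000.0, 100.0, None)
#: Latency presets: the P3a is sharper, hence the narrower windows.
P3A_LATENCY = LatencyParams(150.0, 400.0, 50.0)
P3B_LATENCY = LatencyParams(300.0, 1000.0, 100.0)

PRESETS = {
    "p3a": P3A,
    "p3b": P3B,
    "p3a-latency": P3A_LATENCY,
    "p3b-latency": P3B_LATENCY,
}


@dataclass(frozen=True)
class PeakToPeakResult:
    """Highest and lowest inner-window means and their difference.

    ``degenerate`` marks waves where no full inner window fits after the
    highest peak; the conservative verdict is then p2p = 0 ("no biphasic
    component"), with the low-peak fields unset.
    """

    high_value: float
    high_start: float
    low_value: float | None
    low_start: float | None
    p2p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# sample-index geometry
# ---------------------------------------------------------------------------

def _inner_samples(inner_ms: float, fs: float) -> int:
    n = int(round(inner_ms * fs / 1000.0))
    if n < 1:
        raise ValueError(f"inner window {inner_ms} ms shorter than one sample at {fs} Hz")
    return n


def _start_index_range(
    times: np.ndarray, inner_ms: float, lo_ms: float, hi_ms: float
) -> tuple[int, int, int]:
    """Indices [k0, k1] of window starts with [t_k, t_k+inner) ⊆ [lo, hi).

    Also returns the inner width in samples. k1 < k0 means no window fits.
    """
    fs = 1000.0 / float(times[1] - times[0])
    n_in = _inner_samples(inner_ms, fs)
    ok = (times >= lo_ms - _TOL) & (times + inner_ms <= hi_ms + _TOL)
    # the window's samples must also exist on the grid
    ok[len(times) - n_in + 1 :] = False
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return 0, -1, n_in
    return int(idx[0]), int(idx[-1]), n_in


def _all_window_means(values: np.ndarray, n_in: int) -> np.ndarray:
    """Means of every length-n_in window; shape (..., S - n_in + 1)."""
    cs = np.cumsum(values, axis=-1, dtype=float)
    pad = np.zeros(values.shape[:-1] + (1,))
    cs = np.concatenate([pad, cs], axis=-1)
    return (cs[..., n_in:] - cs[..., :-n_in]) / n_in


def sliding_means(
    w: Waveform, inner: float, window: tuple[float, float]
) -> np.ndarray:
    """All inner-window means inside ``window`` = (start_ms, end_ms).

    Returns an (n, 2) array of (window_start_ms, mean µV), one row per
    sample-aligned start position whose window lies wholly in range.
    """
    lo, hi = window
    k0, k1, n_in = _start_index_range(w.times, inner, lo, hi)
    if k1 < k0:
        raise ValueError(
            f"no full {inner} ms window fits in [{lo}, {hi}) at {w.sampling_rate} Hz"
        )
    means = _all_window_means(w.values, n_in)[k0 : k1 + 1]
    return np.column_stack([w.times[k0 : k1 + 1], means])


# ---------------------------------------------------------------------------
# peak-to-peak
# ---------------------------------------------------------------------------

def peak_to_peak_batch(
    values: np.ndarray, times: np.ndarray, p: PeakParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised peak-to-peak over many waves sharing one time grid.

    ``values`` has shape (N, S). Returns arrays (p2p, high_val, high_k,
    low_val, low_k, degenerate); the k's are start sample indices, with
    low_k = -1 on degenerate rows. Ties in argmax/argmin break towards
    the earliest start, making results storage-order independent.
    """
    values = np.atleast_2d(values)
    hi_cap = p.bound_end if p.high_limit is None else p.high_limit
    h0, h1, n_in = _start_index_range(times, p.inner, p.bound_start, hi_cap)
    if h1 < h0:
        raise ValueError("bounding window admits no full inner window for the high peak")
    b0, b1, _ = _start_index_range(times, p.inner, p.bound_start, p.bound_end)

    means = _all_window_means(values, n_in)  # (N, n_pos)
    high_rel = np.argmax(means[:, h0 : h1 + 1], axis=1)
    high_k = h0 + high_rel
    high_val = np.take_along_axis(means, high_k[:, None], axis=1)[:, 0]

    # low peak: first non-overlapping start after the high peak, up to bound_end
    lo_from = high_k + n_in
    cols = np.arange(means.shape[1])
    allowed = (cols[None, :] >= lo_from[:, None]) & (cols[None, :] <= b1)
    degenerate = ~allowed.any(axis=1)
    masked = np.where(allowed, means, np.inf)
    low_k = np.argmin(masked, axis=1)
    low_val = np.take_along_axis(means, low_k[:, None], axis=1)[:, 0]
    low_val = np.where(degenerate, np.nan, low_val)
    low_k = np.where(degenerate, -1, low_k)
    p2p = np.where(degenerate, 0.0, high_val - low_val)
    return p2p, high_val, high_k, low_val, low_k, degenerate


def peak_to_peak(w: Waveform, p: PeakParams) -> PeakToPeakResult:
    """Peak-to-peak statistic of one difference wave."""
    p2p, hv, hk, lv, lk, deg = peak_to_peak_batch(w.values[None, :], w.times, p)
    degenerate = bool(deg[0])
    return PeakToPeakResult(
        high_value=float(hv[0]),
        high_start=float(w.times[hk[0]]),
        low_value=None if degenerate else float(lv[0]),
        low_start=None if degenerate else float(w.times[lk[0]]),
        p2p=float(p2p[0]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------

def latency_batch(values: np.ndarray, times: np.ndarray, p: LatencyParams) -> np.ndarray:
    """Start time (ms) of the maximal-mean inner window, per wave."""
    values = np.atleast_2d(values)
    k0, k1, n_in = _start_index_range(times, p.inner, p.bound_start, p.bound_end)
    if k1 < k0:
        raise ValueError("bounding window admits no full inner window")
    means = _all_window_means(values, n_in)[:, k0 : k1 + 1]
    return times[k0 + np.argmax(means, axis=1)]


def latency(w: Waveform, p: LatencyParams) -> float:
    """Latency (ms) of one waveform's maximal inner-window mean."""
    return float(latency_batch(w.values[None, :], w.times, p)[0])
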