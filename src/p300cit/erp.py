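"""ERP averaging, difference waves, and pooled fixed-effects averages."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .epochs_io import EpochSet, Waveform

__all__ = ["average_erp", "difference_wave", "pooled_average", "erp_set"]


def average_erp(es: EpochSet, condition: str, channel: str) -> Waveform:
    """Pointwise mean over a condition's valid trials at one channel."""
    data = es.stack(condition)  # (n, C, S), valid only
    if data.shape[0] == 0:
        raise ValueError(f"no valid trials for condition {condition!r}")
    ci = es.channel_index(channel)
    return Waveform(
        channel=channel,
        times=es.times,
        values=data[:, ci, :].mean(axis=0),
        n_trials=data.shape[0],
    )


def erp_set(es: EpochSet, conditions: Sequence[str] | None = None) -> dict[tuple[str, str], Waveform]:
    """All (condition, channel) ERPs with at least one valid trial."""
    out: dict[tuple[str, str], Waveform] = {}
    for cond in conditions if conditions is not None else es.conditions:
        if not es.valid_trials(cond):
            continue
        for ch in es.channels:
            out[(cond, ch)] = average_erp(es, cond, ch)
    return out


def difference_wave(a: Waveform, b: Waveform) -> Waveform:
    """Pointwise a − b on an identical time grid and channel."""
    if a.channel != b.channel:
        raise ValueError(f"channel mismatch: {a.channel!r} vs {b.channel!r}")
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("time grid mismatch between waveforms")
    return Waveform(channel=a.channel, times=a.times, values=a.values - b.values, n_trials=0)


def pooled_average(
    epoch_sets: EpochSet | Iterable[EpochSet], condition: str, channel: str
) -> Waveform:
    """Unweighted mean over all valid trials pooled across subjects.

    Every trial carries equal weight regardless of which subject it came
    from (a fixed-effects grand average), so subjects with more valid
    trials contribute proportionally more.
    """
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    chunks, times = [], None
    for es in epoch_sets:
        data = es.stack(condition)
        if data.shape[0] == 0:
            continue
        if times is None:
            times = es.times
        elif not np.allclose(times, es.times):
            raise ValueError("subjects have incompatible time grids")
        chunks.append(data[:, es.channel_index(channel), :])
    if not chunks:
        raise ValueError(f"empty pool for condition {condition!r}")
    pool = np.concatenate(chunks, axis=0)
    return Waveform(channel=channel, times=times, values=pool.mean(axis=0), n_trials=pool.shape[0])
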