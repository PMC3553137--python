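"""Baseline correction, amplitude-based artifact rejection, trial splits.

Inputs are assumed to be already filtered, re-referenced and free of
ocular artifacts; this module covers only the epoch-level steps of the
analysis: pre-stimulus baseline subtraction, the ±threshold µV rejection
rule, and the chronological / parity splits used by control analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np

from .epochs_io import EpochSet, TrialRecord

__all__ = [
    "BaselineWindow",
    "baseline_correct",
    "reject_amplitude",
    "split_half_chronological",
    "split_parity",
    "valid_counts",
]

#: Channels examined by amplitude rejection when none are given.
DEFAULT_ANALYSIS_CHANNELS = ("Fz", "Cz", "Pz")


@dataclass(frozen=True)
class BaselineWindow:
    """Pre-stimulus window [start, end) in ms whose mean is subtracted."""

    start: float = -100.0
    end: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("baseline start must precede end")


def _window_mask(es: EpochSet, w: BaselineWindow) -> np.ndarray:
    if w.start < es.epoch_start - 1e-9 or w.end > es.epoch_end + 1e-9:
        raise ValueError(
            f"baseline window [{w.start}, {w.end}) outside epoch "
            f"[{es.epoch_start}, {es.epoch_end})"
        )
    t = es.times
    mask = (t >= w.start - 1e-9) & (t < w.end - 1e-9)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return mask


def baseline_correct(es: EpochSet, w: BaselineWindow = BaselineWindow()) -> EpochSet:
    """Subtract, per trial and channel, the mean over the baseline window."""
    mask = _window_mask(es, w)
    trials = [
        replace(tr, data=tr.data - tr.data[:, mask].mean(axis=1, keepdims=True))
        for tr in es.trials
    ]
    return es.with_trials(trials)


def reject_amplitude(
    es: EpochSet,
    threshold: float = 50.0,
    channels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Invalidate trials whose amplitude strictly exceeds ±threshold µV.

    A sample equal to exactly ±threshold is kept. Only the analysed
    channels (default Fz/Cz/Pz, intersected with the set present) are
    examined, and already-invalid trials stay invalid, which makes the
    operation idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if channels is None:
        channels = tuple(ch for ch in DEFAULT_ANALYSIS_CHANNELS if ch in es.channels)
        if not channels:
            channels = es.channels
    idx = [es.channel_index(ch) for ch in channels]
    trials = []
    for tr in es.trials:
        exceeded = bool(np.any(np.abs(tr.data[idx]) > threshold))
        trials.append(replace(tr, valid=tr.valid and not exceeded))
    return es.with_trials(trials)


def valid_counts(es: EpochSet) -> dict[str, int]:
    """Number of valid trials per condition."""
    counts = {c: 0 for c in es.conditions}
    for tr in es.trials:
        if tr.valid:
            counts[tr.condition] += 1
    return counts


def _sorted_valid(es: EpochSet, condition: str) -> list[TrialRecord]:
    pool = sorted(es.valid_trials(condition), key=lambda tr: tr.chrono_index)
    if len(pool) < 2:
        raise ValueError(
            f"need >=2 valid {condition!r} trials to split, have {len(pool)}"
        )
    return pool


def split_half_chronological(es: EpochSet, condition: str) -> tuple[EpochSet, EpochSet]:
    """Split a condition's valid trials into early and late halves.

    Trials are ordered by chronological index; the first ⌈n/2⌉ go to the
    early half (the extra trial on odd counts goes to early).
    """
    pool = _sorted_valid(es, condition)
    k = ceil(len(pool) / 2)
    return es.with_trials(pool[:k]), es.with_trials(pool[k:])


def split_parity(es: EpochSet, condition: str) -> tuple[EpochSet, EpochSet]:
    """Split a condition's valid trials by odd/even chronological rank.

    Rank is 1-based *within the condition* (so gaps in raw chronological
    indices, e.g. from interleaved conditions or rejected trials, do not
    skew the assignment): rank 1 → odd set, rank 2 → even set, ...
    """
    pool = _sorted_valid(es, condition)
    odd = [tr for i, tr in enumerate(pool, start=1) if i % 2 == 1]
    even = [tr for i, tr in enumerate(pool, start=1) if i % 2 == 0]
    return es.with_trials(odd), es.with_trials(even)
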