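"""Core data model and interchange formats for epoched single-trial EEG.

The package operates on *epoch sets*: collections of single-trial EEG
segments, stimulus-locked to a critical item in a rapid serial visual
presentation (RSVP) stream, carrying a condition label (Probe, Fake,
Irrelevant1, Irrelevant2, distractor, ...) and a chronological trial
index. Amplitudes are in microvolts (µV) and times in milliseconds (ms).

The on-disk format is a long-format TSV (one row per sample) with a JSON
sidecar carrying the sampling metadata; see :func:`read_epochs` and
:func:`write_epochs`. Detection results are serialised as JSON via
:func:`write_report`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "TrialRecord",
    "EpochSet",
    "Waveform",
    "DetectionReport",
    "read_epochs",
    "write_epochs",
    "write_report",
    "read_report",
]

_EPOCH_COLUMNS = [
    "subject_id",
    "condition",
    "chrono_index",
    "valid",
    "channel",
    "time_ms",
    "amplitude_uv",
]


class FormatError(ValueError):
    """Raised when an epoch file violates the documented format."""


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-locked trial: a (channels × samples) µV array.

    ``chrono_index`` is the 1-based position of the trial in the
    experiment; ``valid`` is False for trials excluded by artifact
    rejection (such trials never enter an average or a resample).
    """

    chrono_index: int
    condition: str
    valid: bool
    data: np.ndarray  # shape (n_channels, n_samples)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if self.chrono_index < 1:
            raise ValueError(f"chrono_index must be >= 1, got {self.chrono_index}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"trial {self.chrono_index} ({self.condition}): non-finite amplitude"
            )


@dataclass
class EpochSet:
    """A subject's epoched trials on a shared half-open time grid.

    The grid spans ``[epoch_start, epoch_end)`` ms with samples at the
    left edge of each sampling interval, so the sample count is
    ``round((epoch_end - epoch_start) * sampling_rate / 1000)`` for any
    rate.
    """

    subject_id: str
    sampling_rate: float  # Hz
    channels: tuple[str, ...]
    conditions: tuple[str, ...]
    trials: list[TrialRecord] = field(default_factory=list)
    epoch_start: float = -100.0  # ms
    epoch_end: float = 1000.0  # ms, half-open

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.conditions = tuple(self.conditions)
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_end - self.epoch_start) * self.sampling_rate / 1000.0))

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, left edges of the half-open epoch window."""
        step = 1000.0 / self.sampling_rate
        return self.epoch_start + step * np.arange(self.n_samples)

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; have {self.channels}") from None

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.epoch_end <= self.epoch_start:
            raise ValueError("epoch_end must exceed epoch_start")
        n_ch, n_s = len(self.channels), self.n_samples
        seen: set[int] = set()
        for tr in self.trials:
            if tr.data.shape != (n_ch, n_s):
                raise FormatError(
                    f"trial {tr.chrono_index} ({tr.condition}): data shape "
                    f"{tr.data.shape} != ({n_ch}, {n_s})"
                )
            if tr.condition not in self.conditions:
                raise FormatError(
                    f"trial {tr.chrono_index}: condition {tr.condition!r} not in "
                    f"declared set {self.conditions}"
                )
            if tr.chrono_index in seen:
                raise FormatError(f"duplicate chrono_index {tr.chrono_index}")
            seen.add(tr.chrono_index)

    # -- selection helpers -----------------------------------------------
    def valid_trials(self, condition: str | None = None) -> list[TrialRecord]:
        return [
            tr
            for tr in self.trials
            if tr.valid and (condition is None or tr.condition == condition)
        ]

    def stack(self, condition: str | None = None, valid_only: bool = True) -> np.ndarray:
        """Stack trials into an (n_trials, n_channels, n_samples) array."""
        pool = self.valid_trials(condition) if valid_only else [
            tr for tr in self.trials if condition is None or tr.condition == condition
        ]
        if not pool:
            return np.empty((0, len(self.channels), self.n_samples))
        return np.stack([tr.data for tr in pool])

    def subset(self, condition: str, valid_only: bool = False) -> "EpochSet":
        """A copy containing only this condition's trials."""
        trials = [
            tr
            for tr in self.trials
            if tr.condition == condition and (tr.valid or not valid_only)
        ]
        return self.with_trials(trials)

    def with_trials(self, trials: Sequence[TrialRecord]) -> "EpochSet":
        return replace(self, trials=list(trials))


@dataclass
class Waveform:
    """One channel's time series in µV on an ms grid.

    ``n_trials`` records how many trials contributed to an average
    (0 for raw difference waves, whose trial bookkeeping is undefined).
    """

    channel: str
    times: np.ndarray
    values: np.ndarray
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(self.times[1] - self.times[0])


@dataclass
class DetectionReport:
    """Per-subject outcome of the three-electrode randomisation analysis."""

    subject_id: str
    observed: dict[str, float]  # channel -> observed peak-to-peak, µV
    p_per_channel: dict[str, float]
    fisher_p: float
    alpha: float
    B: int
    seed: int | None
    m: int | None = None

    def __post_init__(self) -> None:
        for name, p in {**self.p_per_channel, "fisher": self.fisher_p}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value for {name} outside [0, 1]: {p}")

    @property
    def decision(self) -> bool:
        """True when the Fisher combined p falls below alpha."""
        return self.fisher_p < self.alpha

    def p_display(self, p: float) -> str:
        """Printable p: a p of 0 only means 'below the B-resolution floor'."""
        return f"<{1.0 / self.B:g}" if p == 0.0 else f"{p:g}"


# ---------------------------------------------------------------------------
# epoch TSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(es: EpochSet, path: str | Path) -> None:
    """Write an epoch set as long-format TSV plus JSON sidecar.

    Row order is canonical (trial in chrono order, then channel, then
    time), so equal epoch sets produce byte-identical files.
    """
    path = Path(path)
    es.validate()
    times = es.times
    n_ch, n_s = len(es.channels), es.n_samples
    trials = sorted(es.trials, key=lambda tr: tr.chrono_index)

    rows_per_trial = n_ch * n_s
    n_rows = rows_per_trial * len(trials)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(es.subject_id, n_rows),
            "condition": np.repeat([tr.condition for tr in trials], rows_per_trial),
            "chrono_index": np.repeat([tr.chrono_index for tr in trials], rows_per_trial),
            "valid": np.repeat([tr.valid for tr in trials], rows_per_trial),
            "channel": np.tile(np.repeat(es.channels, n_s), len(trials)),
            "time_ms": np.tile(times, n_ch * len(trials)),
            "amplitude_uv": (
                np.concatenate([tr.data.ravel() for tr in trials])
                if trials
                else np.empty(0)
            ),
        },
        columns=_EPOCH_COLUMNS,
    )
    df["valid"] = df["valid"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    sidecar = {
        "sampling_rate_hz": es.sampling_rate,
        "epoch_start_ms": es.epoch_start,
        "epoch_end_ms": es.epoch_end,
        "channels": list(es.channels),
        "conditions": list(es.conditions),
        "subject_id": es.subject_id,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch TSV (with its JSON sidecar) into an :class:`EpochSet`."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_file}")
    with open(sidecar_file, encoding="utf-8") as fh:
        meta = json.load(fh)

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject_id": str, "condition": str},
        float_precision="round_trip",
    )
    missing = [c for c in _EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    channels = tuple(meta["channels"])
    conditions = tuple(meta["conditions"])
    es = EpochSet(
        subject_id=str(meta.get("subject_id", "")),
        sampling_rate=float(meta["sampling_rate_hz"]),
        channels=channels,
        conditions=conditions,
        epoch_start=float(meta["epoch_start_ms"]),
        epoch_end=float(meta["epoch_end_ms"]),
    )
    n_s = es.n_samples
    ch_pos = {ch: i for i, ch in enumerate(channels)}

    if df.empty:
        return es
    if not es.subject_id:
        es.subject_id = str(df["subject_id"].iloc[0])

    bad_channel = set(df["channel"]) - set(channels)
    if bad_channel:
        row = df.index[df["channel"].isin(bad_channel)][0]
        raise FormatError(f"{path} row {row + 2}: unknown channel {df['channel'][row]!r}")

    trials: list[TrialRecord] = []
    for (chrono, condition), grp in df.groupby(["chrono_index", "condition"], sort=True):
        data = np.full((len(channels), n_s), np.nan)
        for ch, sub in grp.groupby("channel", sort=False):
            if len(sub) != n_s:
                raise FormatError(
                    f"{path}: trial {chrono} channel {ch} has {len(sub)} samples, "
                    f"expected {n_s} (first offending row {sub.index[0] + 2})"
                )
            sub = sub.sort_values("time_ms")
            data[ch_pos[ch]] = sub["amplitude_uv"].to_numpy()
        if np.isnan(data).any():
            absent = [ch for ch in channels if np.isnan(data[ch_pos[ch]]).all()]
            raise FormatError(f"{path}: trial {chrono} missing channel(s) {absent}")
        valid = str(grp["valid"].iloc[0]).strip().lower() in ("true", "1")
        trials.append(
            TrialRecord(chrono_index=int(chrono), condition=str(condition), valid=valid, data=data)
        )
    es.trials = trials
    es.validate()
    return es


# ---------------------------------------------------------------------------
# detection report JSON
# ---------------------------------------------------------------------------

def write_report(r: DetectionReport, path: str | Path) -> None:
    """Serialise a detection report to JSON.

    A p of exactly 0 is kept numerically but additionally rendered as
    the display string ``"<1/B"`` — zero only means the observed value
    exceeded every one of the B resamples.
    """
    payload = {
        "subject_id": r.subject_id,
        "observed_p2p_uv": {ch: float(v) for ch, v in r.observed.items()},
        "p_per_channel": {ch: float(p) for ch, p in r.p_per_channel.items()},
        "p_display": {ch: r.p_display(p) for ch, p in r.p_per_channel.items()},
        "fisher_p": float(r.fisher_p),
        "fisher_p_display": r.p_display(r.fisher_p),
        "alpha": r.alpha,
        "decision": r.decision,
        "B": r.B,
        "seed": r.seed,
        "m": r.m,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> DetectionReport:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return DetectionReport(
        subject_id=d["subject_id"],
        observed=d["observed_p2p_uv"],
        p_per_channel=d["p_per_channel"],
        fisher_p=d["fisher_p"],
        alpha=d["alpha"],
        B=d["B"],
        seed=d["seed"],
        m=d.get("m"),
    )
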