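"""Synthetic RSVP-EEG epoch generation.

Emulates the trial structure of a name-based RSVP concealed-information
experiment: four critical conditions (Probe, Fake, Irrelevant1,
Irrelevant2) of ~50 stimulus-locked epochs each on a −100…1000 ms grid
at Fz/Cz/Pz, plus a pool of distractor-locked no-signal epochs used by
the validity simulation.

Single-trial model::

    trial = background noise + Σ components(condition)

* background — channel-correlated 1/f-spectrum noise (flattened below
  1 Hz, mimicking the recording high-pass) scaled to a target SD, plus
  a 10 Hz alpha sinusoid with a random phase per trial. White noise is
  available as an alternative model.
* components — one or two Gaussian bumps per component: a biphasic
  (positive-then-negative) fronto-central template for the P3a, and a
  broad monophasic parietal template for the P3b, each with per-trial
  latency jitter and per-channel gain.

A cohort draws per-subject amplitude and latency perturbations from
hyper-distributions, giving the random-effects structure real cohorts
show (peak positions vary from individual to individual).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .epochs_io import EpochSet, TrialRecord

__all__ = [
    "ComponentSpec",
    "SynthConfig",
    "component_waveform",
    "background_noise",
    "simulate_subject",
    "simulate_cohort",
    "preset_config",
    "config_from_dict",
    "config_to_dict",
]

DISTRACTOR = "distractor"
MAIN_CONDITIONS = ("Probe", "Fake", "Irrelevant1", "Irrelevant2")


@dataclass(frozen=True)
class ComponentSpec:
    """A one- or two-bump Gaussian ERP component template.

    ``shape`` is ``"biphasic"`` (positive bump followed by a negative
    one — the P3a's full oscillation cycle) or ``"monophasic"`` (the
    negative bump is ignored — a broad P3b-like positivity). Widths are
    Gaussian σ in ms; ``latency_jitter_sd`` shifts the whole template
    per trial.
    """

    channel_weights: Mapping[str, float]
    shape: str = "biphasic"
    pos_peak: float = 240.0
    pos_width: float = 40.0
    pos_amp: float = 8.0
    neg_peak: float = 400.0
    neg_width: float = 60.0
    neg_amp: float = -6.0
    latency_jitter_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.shape not in ("biphasic", "monophasic"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.pos_width <= 0 or self.neg_width <= 0:
            raise ValueError("widths must be positive")
        if self.shape == "biphasic":
            if self.neg_amp > 0:
                raise ValueError("neg_amp must be <= 0")
            if not self.pos_peak < self.neg_peak:
                raise ValueError("pos_peak must precede neg_peak for biphasic shape")


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration (times ms, amplitudes µV)."""

    n_subjects: int = 15
    trials_per_condition: int = 50
    sampling_rate: float = 250.0
    epoch_start: float = -100.0
    epoch_end: float = 1000.0
    channels: tuple[str, ...] = ("Fz", "Cz", "Pz")
    noise_sd: float = 10.0
    noise_model: str = "one_over_f"  # or "white"
    alpha_amp: float = 2.0  # 10 Hz alpha sinusoid amplitude, µV
    channel_noise_correlation: float = 0.7
    components: Mapping[str, tuple[ComponentSpec, ...]] = field(default_factory=dict)
    distractor_pool_size: int = 240
    subject_amp_sd: float = 0.15  # fractional, per-subject amplitude scaling
    subject_latency_sd: float = 20.0  # ms, per-subject latency shift
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("white", "one_over_f"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.channel_noise_correlation <= 1.0:
            raise ValueError("channel_noise_correlation must lie in [0, 1]")
        unknown = set(self.components) - set(MAIN_CONDITIONS)
        if unknown:
            raise ValueError(f"components given for unknown condition(s) {unknown}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return MAIN_CONDITIONS + (DISTRACTOR,)


# ---------------------------------------------------------------------------
# component templates
# ---------------------------------------------------------------------------

def component_waveform(
    c: ComponentSpec,
    times: np.ndarray,
    jitter: float,
    channels: Sequence[str],
    amp_scale: float = 1.0,
    latency_shift: float = 0.0,
) -> np.ndarray:
    """Evaluate a component on the grid; shape (n_channels, n_samples).

    ``jitter`` (per trial) and ``latency_shift`` (per subject) displace
    the whole template; ``amp_scale`` multiplies both bumps. Channels
    without an entry in ``channel_weights`` get gain 0.
    """
    t = np.asarray(times, dtype=float)
    shift = jitter + latency_shift
    base = c.pos_amp * np.exp(-((t - c.pos_peak - shift) ** 2) / (2 * c.pos_width**2))
    if c.shape == "biphasic":
        base = base + c.neg_amp * np.exp(
            -((t - c.neg_peak - shift) ** 2) / (2 * c.neg_width**2)
        )
    gains = np.array([float(c.channel_weights.get(ch, 0.0)) for ch in channels])
    return amp_scale * gains[:, None] * base[None, :]


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------

def _one_over_f_gain(n_samples: int, fs: float, f_floor: float = 1.0) -> np.ndarray:
    """rfft amplitude gains giving a 1/f power spectrum above f_floor.

    The gain is flattened below ``f_floor`` (the recording chain's
    high-pass region), which keeps the process's variance estimable,
    and normalised so the output time series has unit variance.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    nz = freqs > 0
    gain[nz] = np.maximum(freqs[nz], f_floor) ** -0.5
    # expected variance of irfft(rfft(white) * gain)
    mult = np.full_like(freqs, 2.0)
    mult[0] = 1.0
    if n_samples % 2 == 0:
        mult[-1] = 1.0
    var = float(np.sum(mult * gain**2) / n_samples)
    return gain / np.sqrt(var)


def background_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_samples: int,
    times: np.ndarray,
    fs: float,
    n_channels: int = 3,
    noise_sd: float = 10.0,
    model: str = "one_over_f",
    alpha_amp: float = 0.0,
    alpha_freq: float = 10.0,
    channel_correlation: float = 0.0,
) -> np.ndarray:
    """Correlated EEG-like background, shape (n_trials, n_ch, n_samples).

    Each channel's stochastic part has SD ``noise_sd`` and the requested
    pairwise correlation; the optional alpha sinusoid (random phase per
    trial, shared across channels) is added on top.
    """
    w = rng.standard_normal((n_trials, n_channels, n_samples))
    if model == "one_over_f":
        gain = _one_over_f_gain(n_samples, fs)
        x = np.fft.irfft(np.fft.rfft(w, axis=-1) * gain, n=n_samples, axis=-1)
    elif model == "white":
        x = w
    else:
        raise ValueError(f"unknown noise model {model!r}")
    if channel_correlation > 0 and n_channels > 1:
        corr = np.full((n_channels, n_channels), channel_correlation)
        np.fill_diagonal(corr, 1.0)
        x = np.einsum("ij,tjs->tis", np.linalg.cholesky(corr), x)
    x *= noise_sd
    if alpha_amp > 0:
        phase = rng.uniform(0.0, 2 * np.pi, size=n_trials)
        x += alpha_amp * np.sin(
            2 * np.pi * alpha_freq * times[None, None, :] / 1000.0
            + phase[:, None, None]
        )
    return x


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _subject_rng(cfg: SynthConfig, subject_index: int) -> np.random.Generator:
    entropy = 0 if cfg.seed is None else int(cfg.seed)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=entropy, spawn_key=(subject_index,))
    )


def simulate_subject(cfg: SynthConfig, subject_index: int = 0) -> EpochSet:
    """One subject's epoch set: four critical conditions + distractor pool.

    Chronological indices interleave all conditions in random order.
    Per-subject random effects (amplitude scale, latency shift) are
    drawn once per component, then every trial adds its own latency
    jitter on top.
    """
    rng = _subject_rng(cfg, subject_index)
    es = EpochSet(
        subject_id=f"synth-{subject_index + 1:02d}",
        sampling_rate=cfg.sampling_rate,
        channels=cfg.channels,
        conditions=cfg.conditions,
        epoch_start=cfg.epoch_start,
        epoch_end=cfg.epoch_end,
    )
    times = es.times
    n_s, n_ch = es.n_samples, len(cfg.channels)

    # per-subject random effects, in fixed condition order
    effects: dict[str, list[tuple[ComponentSpec, float, float]]] = {}
    for cond in MAIN_CONDITIONS:
        effects[cond] = []
        for comp in cfg.components.get(cond, ()):
            amp_scale = max(0.1, 1.0 + rng.normal(0.0, cfg.subject_amp_sd))
            shift = rng.normal(0.0, cfg.subject_latency_sd)
            effects[cond].append((comp, amp_scale, shift))

    # chronological interleaving of every epoch
    counts = [cfg.trials_per_condition] * len(MAIN_CONDITIONS) + [cfg.distractor_pool_size]
    labels = np.repeat(np.arange(len(counts)), counts)
    order = rng.permutation(len(labels))
    chrono_of: dict[int, list[int]] = {i: [] for i in range(len(counts))}
    for chrono0, lab in enumerate(labels[order]):
        chrono_of[int(lab)].append(chrono0 + 1)

    trials: list[TrialRecord] = []
    all_conditions = MAIN_CONDITIONS + (DISTRACTOR,)
    for ci, cond in enumerate(all_conditions):
        n_trials = counts[ci]
        data = background_noise(
            rng,
            n_trials,
            n_s,
            times,
            cfg.sampling_rate,
            n_channels=n_ch,
            noise_sd=cfg.noise_sd,
            model=cfg.noise_model,
            alpha_amp=cfg.alpha_amp,
            channel_correlation=cfg.channel_noise_correlation,
        )
        for comp, amp_scale, shift in effects.get(cond, ()):
            jitters = (
                rng.normal(0.0, comp.latency_jitter_sd, size=n_trials)
                if comp.latency_jitter_sd > 0
                else np.zeros(n_trials)
            )
            for k in range(n_trials):
                data[k] += component_waveform(
                    comp, times, jitters[k], cfg.channels, amp_scale, shift
                )
        for k in range(n_trials):
            trials.append(
                TrialRecord(
                    chrono_index=chrono_of[ci][k],
                    condition=cond,
                    valid=True,
                    data=data[k],
                )
            )
    trials.sort(key=lambda tr: tr.chrono_index)
    es.trials = trials
    es.validate()
    return es


def simulate_cohort(cfg: SynthConfig) -> list[EpochSet]:
    """Independent subjects sharing the generator configuration."""
    return [simulate_subject(cfg, i) for i in range(cfg.n_subjects)]


# ---------------------------------------------------------------------------
# config (de)serialisation and shipped presets
# ---------------------------------------------------------------------------

def config_to_dict(cfg: SynthConfig) -> dict:
    d = {
        "n_subjects": cfg.n_subjects,
        "trials_per_condition": cfg.trials_per_condition,
        "sampling_rate": cfg.sampling_rate,
        "epoch_start": cfg.epoch_start,
        "epoch_end": cfg.epoch_end,
        "channels": list(cfg.channels),
        "noise_sd": cfg.noise_sd,
        "noise_model": cfg.noise_model,
        "alpha_amp": cfg.alpha_amp,
        "channel_noise_correlation": cfg.channel_noise_correlation,
        "distractor_pool_size": cfg.distractor_pool_size,
        "subject_amp_sd": cfg.subject_amp_sd,
        "subject_latency_sd": cfg.subject_latency_sd,
        "seed": cfg.seed,
        "components": {
            cond: [
                {
                    "channel_weights": dict(comp.channel_weights),
                    "shape": comp.shape,
                    "pos_peak": comp.pos_peak,
                    "pos_width": comp.pos_width,
                    "pos_amp": comp.pos_amp,
                    "neg_peak": comp.neg_peak,
                    "neg_width": comp.neg_width,
                    "neg_amp": comp.neg_amp,
                    "latency_jitter_sd": comp.latency_jitter_sd,
                }
                for comp in comps
            ]
            for cond, comps in cfg.components.items()
        },
    }
    return d


def config_from_dict(d: Mapping) -> SynthConfig:
    d = dict(d)
    comps = {
        cond: tuple(ComponentSpec(**spec) for spec in specs)
        for cond, specs in d.pop("components", {}).items()
    }
    if "channels" in d:
        d["channels"] = tuple(d["channels"])
    return SynthConfig(components=comps, **d)


def preset_config(name: str, **overrides) -> SynthConfig:
    """Load a shipped preset: ``null``, ``guilty`` or ``innocent``."""
    ref = resources.files("p300cit.presets").joinpath(f"{name}.json")
    try:
        payload = json.loads(ref.read_text(encoding="utf-8"))
    except FileNotFoundError:
        raise ValueError(f"unknown preset {name!r}") from None
    cfg = config_from_dict(payload)
    return replace(cfg, **overrides) if overrides else cfg
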