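"""Type-I error calibration of the detection pipeline.

Two complementary null constructions:

* **Intrinsic validity** — datasets in which the null hypothesis holds
  by construction: epochs from a no-signal pool (e.g. distractor-locked
  segments, which preserve the background temporal correlations of real
  EEG) are relabelled fully at random into fabricated Probe / Fake /
  Irrelevant1 / Irrelevant2 conditions, and the standard analysis is
  run on each fabricated dataset. In the limit the fraction of runs
  with p < alpha should equal alpha, and the mean p should be 0.5.

* **Pairwise screen** — the design for an empirically enforced null:
  three interchangeable no-signal conditions yield six ordered pairs,
  each analysed with the first member playing the Probe role.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Mapping, Sequence

import numpy as np

from .epochs_io import DetectionReport, EpochSet, TrialRecord
from .randtest import DetectConfig, detect_subject

__all__ = [
    "ValidityRunResult",
    "fabricate_null_dataset",
    "intrinsic_fp_rate",
    "pairwise_null_screen",
    "FABRICATED_CONDITIONS",
]

FABRICATED_CONDITIONS = ("Probe", "Fake", "Irrelevant1", "Irrelevant2")


@dataclass
class ValidityRunResult:
    """Per-run p-values and their summary over R null-simulation runs."""

    dimensions: tuple[str, ...]  # channels + "fisher"
    p_values: dict[str, np.ndarray]  # dimension -> (R,)
    fp_rate: dict[str, float]
    mean_p: dict[str, float]
    R: int
    alpha: float


def fabricate_null_dataset(
    noise_pool: EpochSet,
    n_per_condition: int,
    rng: np.random.Generator | int | None = None,
    conditions: Sequence[str] = FABRICATED_CONDITIONS,
) -> EpochSet:
    """Relabel no-signal epochs at random into fabricated conditions.

    Draws ``len(conditions) × n_per_condition`` valid epochs from the
    pool without replacement and assigns them to the fabricated
    conditions fully at random, with equal counts. Chronological order
    of the drawn epochs is preserved (indices are re-ranked 1..4n).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pool = sorted(noise_pool.valid_trials(), key=lambda tr: tr.chrono_index)
    need = len(conditions) * n_per_condition
    if len(pool) < need:
        raise ValueError(
            f"pool has {len(pool)} artifact-free epochs, need {need} "
            f"({len(conditions)} conditions × {n_per_condition})"
        )
    drawn = rng.choice(len(pool), size=need, replace=False)
    # position in the shuffled draw determines the fabricated condition
    label_of = {}
    for j, src in enumerate(drawn):
        label_of[int(src)] = conditions[j // n_per_condition]
    trials = [
        TrialRecord(
            chrono_index=rank + 1,
            condition=label_of[src],
            valid=True,
            data=pool[src].data,
        )
        for rank, src in enumerate(sorted(label_of))
    ]
    out = noise_pool.with_trials([])
    out.conditions = tuple(conditions)
    out.trials = trials
    out.validate()
    return out


def intrinsic_fp_rate(
    noise_source: EpochSet | Callable[[int], EpochSet],
    R: int,
    cfg: DetectConfig = DetectConfig(),
    alpha: float = 0.05,
    n_per_condition: int = 50,
    rng: np.random.Generator | int | None = None,
) -> ValidityRunResult:
    """Monte-Carlo Type-I error rate of the full detection pipeline.

    For each of R runs, a fresh fabricated null dataset is built from
    ``noise_source`` (an epoch pool, or a callable returning one per
    run) and passed through the standard per-electrode randomisation and
    Fisher combination. Reported per dimension (each electrode plus the
    combined test): the fraction of runs with p < alpha and the mean p.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dims = tuple(cfg.channels) + ("fisher",)
    p_values = {dim: np.empty(R) for dim in dims}
    for r in range(R):
        pool = noise_source(r) if callable(noise_source) else noise_source
        fabricated = fabricate_null_dataset(pool, n_per_condition, rng=rng)
        report = detect_subject(fabricated, cfg, rng=rng)
        for ch in cfg.channels:
            p_values[ch][r] = report.p_per_channel[ch]
        p_values["fisher"][r] = report.fisher_p
    fp_rate = {dim: float(np.mean(p_values[dim] < alpha)) for dim in dims}
    mean_p = {dim: float(np.mean(p_values[dim])) for dim in dims}
    return ValidityRunResult(
        dimensions=dims,
        p_values=p_values,
        fp_rate=fp_rate,
        mean_p=mean_p,
        R=R,
        alpha=alpha,
    )


def pairwise_null_screen(
    es: EpochSet,
    cfg: DetectConfig = DetectConfig(),
    conditions: Sequence[str] = ("Irrelevant1", "Irrelevant2", "Irrelevant3"),
    rng: np.random.Generator | int | None = None,
) -> dict[tuple[str, str], DetectionReport]:
    """Run detection on every ordered pair of no-signal conditions.

    With three interchangeable conditions this yields six analyses; the
    first member of each pair plays the Probe role and the second the
    Irrelevant role. The fraction of significant outcomes across a
    cohort estimates the empirical false-positive rate of the protocol.
    """
    if len(set(conditions)) != len(conditions):
        raise ValueError("screen conditions must be distinct")
    missing = [c for c in conditions if c not in es.conditions]
    if missing:
        raise ValueError(f"conditions missing from epoch set: {missing}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    from dataclasses import replace as dc_replace

    out: dict[tuple[str, str], DetectionReport] = {}
    for x, y in permutations(conditions, 2):
        pair_cfg = dc_replace(cfg, probe_condition=x, irrelevant_condition=y)
        out[(x, y)] = detect_subject(es, pair_cfg, rng=rng)
    return out
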