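import numpy as np
import pytest

from p300cit import (
    DetectConfig,
    FirstLevelConfig,
    combined_p,
    detect_subject,
    first_level,
    fisher_score,
    per_resample_pvalues,
    simulate_subject,
    preset_config,
)
from p300cit.peaks import P3B, PeakParams
from p300cit.randtest import FirstLevelResult
from conftest import make_epochset
from oracles import exact_randomisation_p

TOY_PARAMS = PeakParams(0.0, 120.0, 30.0, None)


def toy_epochs(rng, n_probe=3, n_irr=3, n_samples=12, effect=0.0):
    # the effect is a localised bump: peak-to-peak is offset-invariant,
    # so a constant shift would be invisible to it
    bump = np.zeros(n_samples)
    bump[3:6] = effect
    trials = []
    for i in range(n_probe):
        trials.append((i + 1, "Probe", True, rng.normal(size=n_samples) + bump))
    for i in range(n_irr):
        trials.append((n_probe + i + 1, "Irrelevant1", True, rng.normal(size=n_samples)))
    return make_epochset(trials, fs=100.0, epoch_start=0.0, epoch_end=120.0)


# -- per_resample_pvalues ----------------------------------------------------

def test_per_resample_pvalues_hand_enumeration():
    p = per_resample_pvalues(np.array([[1.0], [2.0], [3.0], [4.0]]))
    np.testing.assert_allclose(p[:, 0], [0.75, 0.5, 0.25, 0.0])


def test_per_resample_pvalues_all_equal_column():
    p = per_resample_pvalues(np.full((5, 1), 2.0))
    np.testing.assert_allclose(p, 0.0)


def test_per_resample_pvalues_distinct_rank_identity(rng):
    B = 40
    col = rng.normal(size=(B, 1))
    p = np.sort(per_resample_pvalues(col)[:, 0])
    np.testing.assert_allclose(p, np.arange(B) / B)


# -- fisher_score ------------------------------------------------------------

def test_fisher_score_values():
    assert fisher_score([1.0, 1.0, 1.0]) == 0.0
    assert np.isclose(fisher_score([0.05, 0.05, 0.05]), -6 * np.log(0.05))
    assert np.isclose(fisher_score([0.05, 0.05, 0.05]), 17.9744, atol=1e-4)


def test_fisher_score_zero_replacement_uses_floor():
    assert np.isclose(fisher_score([0.0, 0.0, 0.0], B=1000), -6 * np.log(0.001))
    assert np.isclose(fisher_score([0.0], B=200), -2 * np.log(1 / 200))


def test_fisher_score_rejects_out_of_range():
    with pytest.raises(ValueError):
        fisher_score([0.5, 1.2])


# -- combined_p --------------------------------------------------------------

def _single_channel_result(null_col, observed):
    null = np.asarray(null_col, float).reshape(-1, 1)
    p = float(np.sum(null[:, 0] > observed) / len(null))
    return FirstLevelResult(
        m=2, channels=("Pz",), observed={"Pz": observed},
        null_matrix=null, p_per_channel={"Pz": p},
    )


def test_combined_p_hand_count():
    res = combined_p(_single_channel_result([1.0, 2.0, 3.0, 4.0], 2.5))
    assert res.fisher_p == 0.5


def test_combined_p_observed_above_all_nulls_is_zero():
    res = combined_p(_single_channel_result([1.0, 2.0, 3.0, 4.0], 99.0))
    assert res.fisher_p == 0.0


def test_single_channel_fisher_matches_first_level_p(rng):
    """Fisher is monotone in one p, so ranks coincide up to 1/B."""
    for _ in range(10):
        null = rng.normal(size=64)
        obs = rng.normal()
        fl = _single_channel_result(null, obs)
        res = combined_p(fl)
        assert abs(res.fisher_p - fl.p_per_channel["Pz"]) <= 1 / 64 + 1e-12


# -- first_level -------------------------------------------------------------

def test_extreme_separation_gives_zero_p(rng):
    es = toy_epochs(rng, n_probe=8, n_irr=8, effect=50.0)
    cfg = FirstLevelConfig(B=100, channels=("Fz",), params_per_channel={"Fz": TOY_PARAMS})
    fl = first_level(es.subset("Probe"), es.subset("Irrelevant1"), cfg,
                     rng=np.random.default_rng(1))
    assert fl.p_per_channel["Fz"] == 0.0
    assert fl.m == 8
    assert fl.null_matrix.shape == (100, 1)


def test_p_values_live_on_the_b_grid(rng):
    es = toy_epochs(rng, n_probe=6, n_irr=5)
    cfg = FirstLevelConfig(B=50, channels=("Fz",), params_per_channel={"Fz": TOY_PARAMS})
    fl = first_level(es.subset("Probe"), es.subset("Irrelevant1"), cfg,
                     rng=np.random.default_rng(2))
    assert fl.m == 5
    p = fl.p_per_channel["Fz"]
    assert np.isclose(p * 50, round(p * 50))


def test_too_few_trials_rejected(rng):
    es = toy_epochs(rng, n_probe=1, n_irr=5)
    cfg = FirstLevelConfig(B=10, channels=("Fz",), params_per_channel={"Fz": TOY_PARAMS})
    with pytest.raises(ValueError):
        first_level(es.subset("Probe"), es.subset("Irrelevant1"), cfg)


def test_randomisation_p_matches_exhaustive_permutations(rng):
    """Monte-Carlo p within 3 s.e. of the exact 20-split permutation p."""
    for trial_seed in (3, 4, 5):
        local = np.random.default_rng(trial_seed)
        es = toy_epochs(local, n_probe=3, n_irr=3, effect=1.0)
        probe = es.stack("Probe")[:, 0, :]
        irr = es.stack("Irrelevant1")[:, 0, :]
        p_exact, _ = exact_randomisation_p(probe, irr, es.times, TOY_PARAMS)
        B = 10_000
        cfg = FirstLevelConfig(B=B, channels=("Fz",), params_per_channel={"Fz": TOY_PARAMS})
        fl = first_level(es.subset("Probe"), es.subset("Irrelevant1"), cfg,
                         rng=np.random.default_rng(trial_seed + 100))
        se = np.sqrt(max(p_exact * (1 - p_exact), 1 / B) / B)
        assert abs(fl.p_per_channel["Fz"] - p_exact) <= 3 * se + 1e-12


def test_null_first_level_p_centred_on_half(rng):
    """Probe and irrelevant from one distribution: mean p ≈ 0.5."""
    ps = []
    for i in range(120):
        local = np.random.default_rng(1000 + i)
        es = toy_epochs(local, n_probe=5, n_irr=5)
        cfg = FirstLevelConfig(B=50, channels=("Fz",), params_per_channel={"Fz": TOY_PARAMS})
        fl = first_level(es.subset("Probe"), es.subset("Irrelevant1"), cfg, rng=local)
        ps.append(fl.p_per_channel["Fz"])
    assert abs(np.mean(ps) - 0.5) < 0.06


# -- detect_subject ----------------------------------------------------------

def test_detect_guilty_subject_significant():
    cfg = preset_config("guilty", seed=77, n_subjects=1)
    es = simulate_subject(cfg, 0)
    report = detect_subject(es, DetectConfig(B=200, seed=5))
    assert report.fisher_p < 0.05 and report.decision
    assert report.m >= 48  # ±50 µV rejection may drop the odd noisy trial


def test_detect_fixed_seed_reproducible():
    es = simulate_subject(preset_config("null", seed=9, n_subjects=1), 0)
    r1 = detect_subject(es, DetectConfig(B=100, seed=42))
    r2 = detect_subject(es, DetectConfig(B=100, seed=42))
    assert r1.p_per_channel == r2.p_per_channel
    assert r1.fisher_p == r2.fisher_p
    assert r1.observed == r2.observed


def test_channel_order_does_not_change_fisher_p():
    """Trial triples are preserved: electrode order is irrelevant."""
    es = simulate_subject(preset_config("null", seed=13, n_subjects=1), 0)
    p = {}
    for chans in (("Fz", "Cz", "Pz"), ("Pz", "Fz", "Cz")):
        report = detect_subject(es, DetectConfig(B=100, channels=chans, seed=3))
        p[chans] = report.fisher_p
    assert len(set(p.values())) == 1


def test_monotonicity_of_p_in_observed_statistic(rng):
    null = rng.normal(size=(200, 1))
    obs = np.sort(rng.normal(size=20))
    ps = [float(np.sum(null[:, 0] > o) / 200) for o in obs]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
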