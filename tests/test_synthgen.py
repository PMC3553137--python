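import numpy as np
import pytest

from p300cit import (
    ComponentSpec,
    SynthConfig,
    background_noise,
    component_waveform,
    preset_config,
    simulate_cohort,
    simulate_subject,
)
from p300cit.synthgen import config_from_dict, config_to_dict

TIMES = -100.0 + 4.0 * np.arange(275)  # 250 Hz, −100…1000 ms
CHANNELS = ("Fz", "Cz", "Pz")


def mono(peak=500.0, amp=5.0, **kw):
    return ComponentSpec(
        channel_weights={"Fz": 1.0}, shape="monophasic",
        pos_peak=peak, pos_width=50.0, pos_amp=amp, **kw,
    )


# -- component templates -----------------------------------------------------

def test_zero_amplitude_component_is_silent():
    c = ComponentSpec(channel_weights={"Fz": 1.0}, shape="biphasic",
                      pos_amp=0.0, neg_amp=0.0)
    vals = component_waveform(c, TIMES, 0.0, CHANNELS)
    np.testing.assert_array_equal(vals, 0.0)


def test_monophasic_peak_at_requested_latency():
    vals = component_waveform(mono(peak=500.0), TIMES, 0.0, CHANNELS)
    assert TIMES[np.argmax(vals[0])] == 500.0
    np.testing.assert_array_equal(vals[1], 0.0)  # no Cz weight
    np.testing.assert_array_equal(vals[2], 0.0)


def test_jitter_shifts_template_exactly_on_grid():
    base = component_waveform(mono(), TIMES, 0.0, CHANNELS)[0]
    shifted = component_waveform(mono(), TIMES, 40.0, CHANNELS)[0]
    assert TIMES[np.argmax(shifted)] - TIMES[np.argmax(base)] == 40.0
    # shift-equivariance: 40 ms is exactly 10 samples at 250 Hz
    np.testing.assert_allclose(shifted[10:], base[:-10], atol=1e-12)


def test_channel_weights_scale_linearly():
    c = ComponentSpec(channel_weights={"Fz": 1.0, "Cz": 0.5}, shape="monophasic",
                      pos_peak=400.0, pos_width=40.0, pos_amp=6.0)
    vals = component_waveform(c, TIMES, 0.0, CHANNELS)
    np.testing.assert_allclose(vals[1], 0.5 * vals[0])


def test_biphasic_spec_validation():
    with pytest.raises(ValueError):
        ComponentSpec(channel_weights={}, shape="biphasic", pos_peak=500.0, neg_peak=400.0)
    with pytest.raises(ValueError):
        ComponentSpec(channel_weights={}, shape="biphasic", neg_amp=2.0)
    with pytest.raises(ValueError):
        ComponentSpec(channel_weights={}, shape="wiggly")


# -- background noise --------------------------------------------------------

@pytest.mark.parametrize("model", ["white", "one_over_f"])
def test_noise_mean_and_sd_match_configuration(model):
    rng = np.random.default_rng(8)
    n = 100_000
    times = 4.0 * np.arange(n)
    x = background_noise(rng, 1, n, times, 250.0, n_channels=1,
                         noise_sd=10.0, model=model, alpha_amp=0.0)
    assert abs(x.mean()) < 0.3
    assert abs(x.std() / 10.0 - 1.0) < 0.03


def test_one_over_f_spectral_slope():
    rng = np.random.default_rng(9)
    n = 2**15
    fs = 250.0
    times = np.arange(n) / fs * 1000.0
    x = background_noise(rng, 8, n, times, fs, n_channels=1,
                         noise_sd=1.0, model="one_over_f", alpha_amp=0.0)
    spec = np.abs(np.fft.rfft(x[:, 0, :], axis=-1)) ** 2
    psd = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    band = (freqs >= 1.0) & (freqs <= 30.0)
    slope = np.polyfit(np.log(freqs[band]), np.log(psd[band]), 1)[0]
    assert abs(slope - (-1.0)) < 0.2


def test_channel_correlation_recovered():
    rng = np.random.default_rng(10)
    n = 10_000
    times = 4.0 * np.arange(n)
    x = background_noise(rng, 1, n, times, 250.0, n_channels=3,
                         noise_sd=5.0, model="one_over_f", alpha_amp=0.0,
                         channel_correlation=0.6)[0]
    corr = np.corrcoef(x)
    off_diag = corr[np.triu_indices(3, k=1)]
    assert np.all(np.abs(off_diag - 0.6) < 0.05)


def test_alpha_oscillation_power_at_10hz():
    rng = np.random.default_rng(11)
    n = 2500  # 10 s at 250 Hz
    times = 4.0 * np.arange(n)
    x = background_noise(rng, 50, n, times, 250.0, n_channels=1,
                         noise_sd=0.0, model="white", alpha_amp=3.0)
    spec = np.abs(np.fft.rfft(x[:, 0, :], axis=-1)).mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1 / 250.0)
    assert abs(freqs[np.argmax(spec)] - 10.0) < 0.2
    np.testing.assert_allclose(x.std(), 3.0 / np.sqrt(2), rtol=0.05)


# -- subject / cohort simulation --------------------------------------------

def test_noiseless_subject_reproduces_template_exactly():
    probe_comp = mono(peak=400.0, amp=6.0, latency_jitter_sd=0.0)
    cfg = SynthConfig(
        n_subjects=1, trials_per_condition=5, noise_sd=0.0, alpha_amp=0.0,
        components={"Probe": (probe_comp,)}, distractor_pool_size=4,
        subject_amp_sd=0.0, subject_latency_sd=0.0, seed=1,
    )
    es = simulate_subject(cfg, 0)
    tmpl = component_waveform(probe_comp, es.times, 0.0, cfg.channels)
    for tr in es.valid_trials("Probe"):
        np.testing.assert_array_equal(tr.data, tmpl)
    for tr in es.valid_trials("Irrelevant1"):
        np.testing.assert_array_equal(tr.data, 0.0)


def test_fixed_seed_reproducible():
    cfg = preset_config("guilty", seed=5, n_subjects=1, trials_per_condition=5,
                        distractor_pool_size=10)
    a = simulate_subject(cfg, 0)
    b = simulate_subject(cfg, 0)
    assert [(t.chrono_index, t.condition) for t in a.trials] == [
        (t.chrono_index, t.condition) for t in b.trials
    ]
    for ta, tb in zip(a.trials, b.trials):
        np.testing.assert_array_equal(ta.data, tb.data)


def test_subjects_differ_and_chrono_interleaves():
    cfg = preset_config("null", seed=6, n_subjects=2, trials_per_condition=10,
                        distractor_pool_size=10)
    a, b = simulate_cohort(cfg)
    assert not np.array_equal(a.trials[0].data, b.trials[0].data)
    # chronological indices cover 1..N across all conditions jointly
    idx = sorted(t.chrono_index for t in a.trials)
    assert idx == list(range(1, len(a.trials) + 1))
    first_ten = [t.condition for t in sorted(a.trials, key=lambda t: t.chrono_index)[:10]]
    assert len(set(first_ten)) > 1  # conditions interleaved, not blocked


def test_cohort_of_one_matches_simulate_subject():
    cfg = preset_config("null", seed=3, n_subjects=1, trials_per_condition=5,
                        distractor_pool_size=8)
    (a,) = simulate_cohort(cfg)
    b = simulate_subject(cfg, 0)
    for ta, tb in zip(a.trials, b.trials):
        np.testing.assert_array_equal(ta.data, tb.data)


def test_zero_hyper_sd_shares_templates_across_subjects():
    comp = mono(peak=400.0, amp=6.0, latency_jitter_sd=0.0)
    cfg = SynthConfig(
        n_subjects=2, trials_per_condition=3, noise_sd=0.0, alpha_amp=0.0,
        components={"Probe": (comp,)}, distractor_pool_size=2,
        subject_amp_sd=0.0, subject_latency_sd=0.0, seed=4,
    )
    s1, s2 = simulate_cohort(cfg)
    np.testing.assert_array_equal(
        s1.valid_trials("Probe")[0].data, s2.valid_trials("Probe")[0].data
    )


def test_config_roundtrips_through_dict():
    cfg = preset_config("guilty")
    back = config_from_dict(config_to_dict(cfg))
    assert back == cfg
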