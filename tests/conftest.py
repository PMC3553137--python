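import numpy as np
import pytest

from p300cit import EpochSet, TrialRecord


def make_epochset(
    trial_data,
    *,
    channels=("Fz",),
    conditions=None,
    fs=100.0,
    epoch_start=-100.0,
    epoch_end=1000.0,
    subject_id="s1",
):
    """Build an EpochSet from [(chrono, condition, valid, data), ...].

    ``data`` may be a scalar (constant trial), a 1-D per-sample array
    (broadcast over channels), or a full (channels × samples) array.
    """
    n_s = int(round((epoch_end - epoch_start) * fs / 1000.0))
    cond_labels = []
    trials = []
    for chrono, cond, valid, data in trial_data:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 0:
            arr = np.full((len(channels), n_s), float(arr))
        elif arr.ndim == 1:
            arr = np.tile(arr, (len(channels), 1))
        trials.append(TrialRecord(chrono, cond, valid, arr))
        cond_labels.append(cond)
    if conditions is None:
        conditions = tuple(dict.fromkeys(cond_labels)) or ("Probe",)
    return EpochSet(
        subject_id=subject_id,
        sampling_rate=fs,
        channels=tuple(channels),
        conditions=tuple(conditions),
        trials=trials,
        epoch_start=epoch_start,
        epoch_end=epoch_end,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240922)


@pytest.fixture(scope="session")
def null_subject():
    """One synthetic no-signal subject, shared across tests."""
    from p300cit import preset_config, simulate_subject

    return simulate_subject(preset_config("null", seed=424242), 0)
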