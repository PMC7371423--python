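import numpy as np
import pytest

from fiberlearn import photometry as pho
from fiberlearn import synthetic as syn
from fiberlearn.config import SimConfig


@pytest.fixture(scope="session")
def std_config() -> SimConfig:
    """The standard synthetic mouse used by cross-module tests."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def std_table(std_config):
    return syn.simulate_behavior(std_config)


@pytest.fixture(scope="session")
def std_bundle(std_config, std_table):
    """(table, normalized session, ground truth) for the standard mouse."""
    session, gt = syn.simulate_photometry(std_table, std_config)
    return std_table, pho.normalize_trials(session), gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_session(traces, sampling_rate=30.0, t0=-3.0, normalized=True,
                 mouse_id="t0"):
    """Hand-built PhotometrySession on the standard -3 s-anchored clock."""
    from fiberlearn.io import PhotometrySession

    traces = np.asarray(traces, dtype=float)
    time_s = t0 + np.arange(traces.shape[1]) / sampling_rate
    return PhotometrySession(
        mouse_id=mouse_id,
        traces=traces,
        time_s=time_s,
        sampling_rate=sampling_rate,
        normalized=normalized,
    )


def make_table(stimulus_class, lick_times, mouse_id="t0"):
    """Hand-built TrialTable with outcomes derived from the lick evidence."""
    import pandas as pd

    from fiberlearn.io import TRIAL_TABLE_COLUMNS, TrialTable, expected_outcome

    n = len(stimulus_class)
    licks = [np.asarray(lt, dtype=float) for lt in lick_times]
    df = pd.DataFrame(
        {
            "mouse_id": mouse_id,
            "trial_index": np.arange(n),
            "day": 1,
            "stimulus_freq_hz": [
                10000.0 if c == "go" else 7071.0 for c in stimulus_class
            ],
            "stimulus_class": list(stimulus_class),
            "outcome": [
                expected_outcome(c, lt) for c, lt in zip(stimulus_class, licks)
            ],
            "lick_times_s": licks,
        },
        columns=list(TRIAL_TABLE_COLUMNS),
    )
    return TrialTable(df)
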