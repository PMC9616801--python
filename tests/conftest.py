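"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from commdyn.session import SessionData
from commdyn.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """Compact default-mode session for container/filter/behaviour tests."""
    cfg = SimConfig(
        n_source=12, n_target=15, n_control=60, n_silencing_per_window=20, seed=11
    )
    session, truth = simulate_session(cfg)
    return session, truth


@pytest.fixture()
def toy_session():
    """Hand-built 2-neuron, 4-trial session with known spike times."""
    neurons = pd.DataFrame(
        dict(area=["source", "target"], depth=[100.0, 200.0],
             rf_distance=[1.0, 5.0], mean_rate=[5.0, 5.0])
    )
    trials = pd.DataFrame(
        dict(
            stimulus=["go", "nogo", "go", "nogo"],
            condition=["control", "control", "silencing", "silencing"],
            silencing_window=[0, 0, 1, 2],
            lick_time=[300.0, np.nan, 120.0, 700.0],
        )
    )
    spike_neuron = np.array([0, 0, 0, 1, 1, 1, 0, 1])
    spike_trial = np.array([0, 0, 0, 0, 1, 1, 2, 3])
    spike_time = np.array([10.0, 60.0, 200.0, 150.0, -100.0, 499.0, 0.0, 250.0])
    return SessionData(
        animal_id="toy",
        neurons=neurons,
        trials=trials,
        spike_neuron=spike_neuron,
        spike_trial=spike_trial,
        spike_time=spike_time,
    )
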