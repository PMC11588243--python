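import numpy as np
import pandas as pd
import pytest

import ethostate as es


@pytest.fixture(scope="session")
def feature_study():
    """Default feature-level synthetic study (8 individuals x 2000 windows)."""
    windows, truth = es.simulate_feature_study(seed=1)
    return windows, truth


@pytest.fixture(scope="session")
def small_feature_study():
    """Reduced feature-level study for fast fitting tests."""
    cfg = es.default_config()
    for ind in cfg.individuals:
        ind.n_windows = 400
    windows, truth = es.simulate_feature_study(cfg, seed=7)
    return windows, truth


@pytest.fixture(scope="session")
def fitted_default_study(feature_study):
    """One full fit of the default study, shared across tests."""
    windows, _ = feature_study
    return es.fit_hmm(windows, seed=0, max_iter=2500)


def make_burst(n_seconds=60, accel_hz=10, seed=0, **kw):
    """A random but in-range burst for identity checks."""
    rng = np.random.default_rng(seed)
    n = int(n_seconds * accel_hz)
    defaults = dict(
        individual_id="T1",
        sex="female",
        gravid=False,
        start_time=pd.Timestamp("2023-05-10T12:00:00Z"),
        ax=rng.uniform(-1.5, 1.5, n),
        ay=rng.uniform(-1.5, 1.5, n),
        az=rng.uniform(-1.5, 1.5, n),
        analog_immersion=rng.uniform(0, 1000, int(np.ceil(n_seconds))),
        accel_hz=accel_hz,
    )
    defaults.update(kw)
    return es.RawBurst(**defaults)


@pytest.fixture
def random_burst():
    return make_burst(n_seconds=120, seed=3)
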