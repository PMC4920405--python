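import numpy as np
import pytest

from guts import ModelConfig, ParameterSet, load_diazinon, make_experiment

#: maximum-posterior parameter vector of the diazinon example (hb, ke, kk, mn, sd)
DIAZINON_MAP = np.array([0.05473022, 0.09215698, 1.80652237, 15.63446045, 6.01160431])


@pytest.fixture(scope="session")
def diazinon():
    return load_diazinon()


@pytest.fixture
def diazinon_map():
    return DIAZINON_MAP.copy()


def random_instance(rng, n_obs=5, conc_scale=100.0):
    """A small random experiment + proper parameter set for cross-checks."""
    nseg = int(rng.integers(2, 5))
    ct = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 10.0, nseg))])
    c = rng.uniform(0.0, conc_scale, nseg + 1)
    yt = np.concatenate([[0.0], np.sort(rng.uniform(0.5, ct[-1], n_obs - 1))])
    y = np.arange(2 * n_obs, n_obs, -1)
    experiment = make_experiment(c, ct, y, yt)
    params = ParameterSet(
        hb=float(rng.uniform(0.0, 0.1)),
        ke=float(rng.uniform(0.05, 1.0)),
        kk=float(rng.uniform(0.1, 5.0)),
        mn=float(rng.uniform(5.0, 40.0)),
        sd=float(rng.uniform(1.0, 20.0)),
    )
    return experiment, params


@pytest.fixture
def rng():
    return np.random.default_rng(20160624)
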