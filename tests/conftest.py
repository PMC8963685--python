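import logging

import numpy as np
import pytest

import tndbridge as tb

# solver validity warnings are expected noise in simulation-heavy tests
logging.getLogger("tndbridge.bridge").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def binary_config():
    return tb.binary_rare(beta0=-0.693)


@pytest.fixture(scope="session")
def binary_population(binary_config):
    return tb.simulate_binary_population(binary_config, seed=20260901)


@pytest.fixture(scope="session")
def binary_sample(binary_population):
    return tb.select_tnd_sample(binary_population)


@pytest.fixture(scope="session")
def continuous_config():
    return tb.continuous_rare(beta0=-0.693)


@pytest.fixture(scope="session")
def continuous_population(continuous_config):
    return tb.simulate_continuous_population(continuous_config, seed=20260902)


@pytest.fixture(scope="session")
def continuous_sample(continuous_population):
    return tb.select_tnd_sample(continuous_population)


@pytest.fixture(scope="session")
def fitted_binary(binary_sample):
    """Bridge fit + log-RR estimate on the shared binary sample."""
    m = tb.binary_moment_basis()
    model, report = tb.estimate_bridge_params(
        binary_sample, tb.BridgeModel("saturated-binary"), m)
    beta = tb.estimate_log_rr(binary_sample, model)
    return {"sample": binary_sample, "m": m, "model": model,
            "report": report, "beta": beta}


def hand_sample(a, y, z, w, x=None):
    return tb.TNDSample(a=np.asarray(a), y=np.asarray(y),
                        z=np.asarray(z), w=np.asarray(w), x=x)
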