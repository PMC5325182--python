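import numpy as np
import pytest

import spikestab as ss


def thin(times, gap):
    """Drop events closer than ``gap`` to their predecessor."""
    times = np.sort(np.asarray(times, dtype=float))
    keep = np.concatenate([[True], np.diff(times) > gap])
    return times[keep]


@pytest.fixture(scope="session")
def exp_stable():
    return ss.reference_model("exp_stable")


@pytest.fixture(scope="session")
def exp_fragile():
    return ss.reference_model("exp_fragile")


@pytest.fixture(scope="session")
def exp_divergent():
    return ss.reference_model("exp_divergent")


@pytest.fixture(scope="session")
def refractory_only():
    return ss.reference_model("refractory_only")


@pytest.fixture(scope="session")
def poisson():
    return ss.reference_model("poisson")


@pytest.fixture(scope="session")
def basis_model():
    return ss.reference_model("basis_model")


@pytest.fixture(scope="session")
def basis_train(basis_model):
    """One 400-s spike train simulated from the basis-kernel model."""
    cfg = ss.SimulationConfig(duration=400.0, n_replicates=1, seed=101,
                              stop_on_divergence=True)
    return ss.simulate(basis_model, cfg)[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
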