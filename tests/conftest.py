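import numpy as np
import pytest

from dlca import stimgen


@pytest.fixture(scope="session")
def experiment_2s():
    """Moderate 2-s perturbation-design experiment shared across tests."""
    cfg = stimgen.DesignConfig(durations=(2,))
    return stimgen.make_experiment(cfg, 1, 4000, seed=11)


@pytest.fixture(scope="session")
def small_experiment_3s():
    cfg = stimgen.DesignConfig(durations=(3,))
    return stimgen.make_experiment(cfg, 1, 600, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
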