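import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrakit as mk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth3() -> mk.GroundTruth:
    """A fixed, well-conditioned noiseless 3-module truth."""
    return mk.random_ground_truth(3, seed=11)


@pytest.fixture(scope="session")
def design3(truth3) -> mk.ExperimentDesign:
    return mk.design_for(truth3, k_t=3, n_r=2)


@pytest.fixture(scope="session")
def noiseless_data(truth3, design3) -> mk.AbundanceSet:
    return mk.simulate_dataset(truth3, design3)


@pytest.fixture(scope="session")
def net3(truth3, design3, noiseless_data) -> mk.LocalResponseNetwork:
    R = mk.build_global_response(noiseless_data, design3, "pooled_mean")
    return mk.infer_network(R)


@pytest.fixture(scope="session")
def R3(truth3) -> mk.GlobalResponseMatrix:
    return mk.GlobalResponseMatrix(truth3.R_true, truth3.modules)
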