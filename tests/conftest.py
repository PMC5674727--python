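import numpy as np
import pytest

from dsaddle import PhantomConfig, TransformSpec, generate_fundus, generate_pair
from dsaddle.registration import MsacConfig, RegistrationConfig


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic small fundus phantom plus its centerline mask."""
    return generate_fundus(PhantomConfig(size=160, seed=5))


@pytest.fixture(scope="session")
def pair_s():
    """A super-resolution-regime phantom pair at desk scale."""
    return generate_pair(
        PhantomConfig(size=192, seed=9),
        TransformSpec(model="similarity", overlap=0.9),
        "S",
    )


@pytest.fixture(scope="session")
def desk_registration_config():
    """Reduced MSAC schedule for fast unit tests."""
    return RegistrationConfig(
        msac=MsacConfig(repeats_per_distance=10, max_trials=300, seed=3)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
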