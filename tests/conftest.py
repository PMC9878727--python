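import numpy as np
import pytest

from cgmotor.fixtures import toy_motor
from cgmotor.sampler import SamplerConfig, build_initial_coords, sample


@pytest.fixture(scope="session")
def toy_spec():
    return toy_motor()


@pytest.fixture(scope="session")
def toy_start(toy_spec):
    return build_initial_coords(toy_spec.topology, seed=1)


@pytest.fixture(scope="session")
def motor_ensemble(toy_spec, toy_start):
    """A medium-length equilibrium sample of the toy motor, shared by the
    statistics and fitting tests."""
    cfg = SamplerConfig(n_steps=400_000, stride=10, seed=1)
    return sample(toy_spec.topology, cfg, start=toy_start)


@pytest.fixture(scope="session")
def roundtrip_result():
    """The full decorate -> map -> fit -> resample recovery experiment."""
    from cgmotor.roundtrip import roundtrip_experiment

    return roundtrip_experiment(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
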