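import numpy as np
import pytest
from hypothesis import settings

import choroidseg as cs

settings.register_profile("default", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("default")


SMALL_SPEC = cs.PhantomSpec(
    n_rows=128,
    n_cols=160,
    rpe_depth_mean=40.0,
    choroid_thickness_mean=30.0,
    choroid_thickness_amplitude=5.0,
    vessel_count=6,
    boundary_smoothness=25.0,
    seed=0,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    samples, manifest = cs.generate_dataset(small_spec, 6, base_seed=11, n_train=4)
    return samples, manifest


@pytest.fixture(scope="session")
def small_model(small_dataset):
    samples, _ = small_dataset
    train = samples[:4]
    return cs.train_model([s.image for s in train], [s.mask for s in train])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
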