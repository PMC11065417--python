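import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", deadline=None, derandomize=True)
settings.load_profile("repeatable")

from oodeval import (
    FeatureSpaceSpec,
    LinearAdapter,
    generate_id_features,
    make_class_size_profile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """5 well-separated classes in 4 dimensions, unit within-class variance."""
    return FeatureSpaceSpec(n_classes=5, dim=4, mean_scale=3.0, within_cov=1.0, seed=7)


@pytest.fixture
def small_id_table(small_spec):
    profile = make_class_size_profile("balanced", 200, small_spec.n_classes)
    return generate_id_features(small_spec, profile)


@pytest.fixture
def random_linear_adapter(rng):
    """A fixed random 5-class linear logit map over 4-dim features."""
    return LinearAdapter(rng.normal(size=(5, 4)), rng.normal(size=5))
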