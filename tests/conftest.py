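import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic image set (36 samples, 32 px) for fast tests."""
    from dbofuse.synthetic import SyntheticSpec, generate_dataset

    return generate_dataset(
        SyntheticSpec(class_counts=(12, 12, 12), image_size=32, seed=7)
    )


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Single-surrogate features of the reduced set (36 x 16)."""
    from dbofuse.backbones import BackboneSpec, extract_features

    spec = BackboneSpec(name="surrogate_tiny", feature_dim=16, input_size=32, seed=3)
    return extract_features(small_dataset.images, spec), small_dataset.labels


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale fixture: 100 images at the study's class counts."""
    from dbofuse.synthetic import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(seed=0))
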