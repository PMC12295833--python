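import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def blob_images():
    """A small seeded batch of structured fixture images."""
    from synthdetect import FixtureSpec, make_fixture_dataset

    return make_fixture_dataset(FixtureSpec(kind="blobs", n=32, seed=7))


@pytest.fixture(scope="session")
def random_images():
    """Unstructured random uint8 images (descriptor stress inputs)."""
    rng = np.random.default_rng(42)
    return rng.integers(0, 256, size=(8, 28, 28)).astype(np.uint8)


@pytest.fixture(scope="session")
def tiny_training_run(blob_images):
    """One-epoch GAN training at toy scale, shared across tests."""
    from synthdetect import GanConfig, ImageBatch, normalize_images, train

    config = GanConfig(epochs=1, snapshot_size=10, batch_size=32, seed=5)
    return train(normalize_images(ImageBatch(blob_images, "raw")), config)
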