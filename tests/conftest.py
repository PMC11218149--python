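import numpy as np
import pytest

from slicefill.phantom import PhantomConfig, generate_phantom


def small_phantom_config(seed: int = 5, **overrides) -> PhantomConfig:
    """A compact phantom (16 x 48 x 48) that keeps tests fast."""
    kwargs = dict(
        shape=(16, 48, 48),
        spacing=(4.0, 1.5, 1.5),
        kidney_semi_axes=(28.0, 20.0, 20.0),
        tumor_radius=10.0,
        tumor_center_offset=(0.0, 4.0, 0.0),
        tumor_elongation=2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """(volume, labels) of the compact default phantom."""
    return generate_phantom(small_phantom_config())


@pytest.fixture(scope="session")
def small_labels(small_phantom):
    return small_phantom[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
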