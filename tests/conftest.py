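import numpy as np
import pytest

from renalseg.nn import NetworkConfig, R2PBlockConfig
from renalseg.phantoms import PhantomConfig, generate_slice_dataset
from renalseg.training import CascadeConfig, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_cfg():
    return PhantomConfig(image_size=64, n_slices=4, tumor_area_range=(20, 60),
                         seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_phantom_cfg):
    return generate_slice_dataset(12, small_phantom_cfg)


def tiny_block(**kw):
    defaults = dict(kernel_sizes=(3,), recurrence_steps=0, dropout_rate=0.0)
    defaults.update(kw)
    return R2PBlockConfig(**defaults)


@pytest.fixture
def tiny_cascade_cfg():
    """Smallest structurally valid cascade, for plumbing tests only."""
    block = tiny_block()
    return CascadeConfig(
        coarse_net=NetworkConfig(input_size=32, depth=2, base_filters=2,
                                 n_classes=2, block=block),
        fine_net=NetworkConfig(input_size=16, depth=2, base_filters=2,
                               n_classes=3, block=block),
        coarse_train=TrainConfig(steps_per_epoch=2, epochs=1, seed=0),
        fine_train=TrainConfig(steps_per_epoch=2, epochs=1, seed=1),
        roi_small=16, roi_large=32, balance_bin_width=20,
    )


@pytest.fixture
def tiny_phantom_cfg():
    return PhantomConfig(image_size=32, n_slices=3, tumor_area_range=(6, 16),
                         kidney_count_range=(1, 1), seed=5)
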