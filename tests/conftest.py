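import numpy as np
import pytest

from vesselseg.architectures import ArchitectureSpec, build_model
from vesselseg.io_datasets import DatasetSplit
from vesselseg.synth_fundus import default_configs, make_synthetic_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_samples():
    """Four 64x64 synthetic fundus samples."""
    tree, render = default_configs((64, 64), seed=11)
    return make_synthetic_dataset(4, tree, render, seed=11)


@pytest.fixture(scope="session")
def small_split():
    """6-train / 2-test split of 32x32 synthetic samples."""
    tree, render = default_configs((32, 32), seed=21)
    samples = make_synthetic_dataset(8, tree, render, seed=21)
    return DatasetSplit(train=samples[:6], test=samples[6:])


@pytest.fixture(scope="session")
def small_models():
    """Untrained instances of all four architectures at 32x32, width 4."""
    models = {}
    for i, name in enumerate(["unet", "resnet50_seg", "unet_resnet_backbone",
                              "ctu_net"]):
        spec = ArchitectureSpec(name=name, input_size=(32, 32),
                                base_channels=4, seed=100 + i)
        models[name] = build_model(spec)
    return models
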