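import numpy as np
import pytest

from berryfuse import dataset_io
from berryfuse.synthetic_scenes import SceneParams, generate_dataset


@pytest.fixture(scope="session")
def tiny_params():
    """Small scenes that still satisfy the expert backbone's minimum size."""
    return SceneParams(image_size=(48, 48), count_range=(1, 4),
                       size_range=(5.0, 9.0), scene_extent_mm=120.0,
                       noise_sigma=0.5, seed=123)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_params, tmp_path_factory):
    """24 48x48 scenes on disk, shared across the whole test session."""
    out = tmp_path_factory.mktemp("tiny_data")
    return generate_dataset(24, tiny_params, out)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return dataset_io.split_manifest(tiny_dataset, 0.75, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
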