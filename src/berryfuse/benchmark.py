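"""The bundled synthetic benchmark: fixed data conditions and a desk-scale
model configuration under which the full pipeline trains on one CPU.

The standard benchmark uses 300 training and 50 test scenes at 96x96
pixels, a width-0.25 expert backbone with 4 shallow channels, and 30
epochs of the published optimization protocol (Adam, lr 1e-3, weight
decay 1e-4, beta1 0.9) at batch size 8.
"""

from __future__ import annotations

from pathlib import Path

from . import dataset_io
from .dataset_io import DatasetManifest
from .fusion_network import FusionConfig
from .objectives import LossConfig
from .synthetic_scenes import SceneParams, generate_dataset
from .training_engine import TrainConfig

N_TRAIN, N_TEST = 300, 50
IMAGE_SIZE = 96
SHALLOW_CHANNELS = 4
WIDTH_MULTIPLIER = 0.25
EPOCHS = 30


def benchmark_scene_params(seed: int = 7, image_size: int = IMAGE_SIZE) -> SceneParams:
    return SceneParams(image_size=(image_size, image_size), seed=seed)


def make_benchmark(out_dir, n_train: int = N_TRAIN, n_test: int = N_TEST,
                   image_size: int = IMAGE_SIZE,
                   seed: int = 7) -> tuple[DatasetManifest, DatasetManifest]:
    """Generate the benchmark scenes and return (train, test) manifests."""
    out_dir = Path(out_dir)
    n = n_train + n_test
    manifest = generate_dataset(n, benchmark_scene_params(seed, image_size), out_dir)
    return dataset_io.split_manifest(manifest, n_train / n, seed=seed)


def benchmark_train_config(seed: int = 7, epochs: int = EPOCHS,
                           lam: float = 0.1, tau: float = 0.1,
                           **overrides) -> TrainConfig:
    """The full (A + E + L_h) desk-scale configuration."""
    kwargs = dict(
        seed=seed,
        epochs=epochs,
        fusion_config=FusionConfig(shallow_channels=SHALLOW_CHANNELS,
                                   width_multiplier=WIDTH_MULTIPLIER),
        loss_config=LossConfig(tau=tau, lam=lam),
    )
    kwargs.update(overrides)
    return TrainConfig(**kwargs)
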