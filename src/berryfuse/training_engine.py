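"""Reproducible training and evaluation for the fusion expert network.

The optimizer is Adam with learning rate 1e-3, weight decay 1e-4 and
first-moment decay beta1 = 0.9.  Targets are z-scored per task with
training-set statistics before the loss (the three tasks live on wildly
different scales — grams, percent, counts) and de-standardized for
metric computation; a flag restores the raw-scale objective.

Checkpoints are single ``.npz`` archives holding the parameters, the
model / loss configuration, and the label statistics used for
standardization, so evaluation never needs the training context.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import dataset_io, nn, objectives
from .autodiff import Tensor
from .dataset_io import AugmentConfig, DatasetManifest
from .fusion_network import FusionConfig, FusionExpertNet
from .objectives import LossConfig
from .trait_metrics import MetricsReport, metrics_report


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    standardize_targets: bool = True
    loss_config: LossConfig = dataclasses.field(default_factory=LossConfig)
    fusion_config: FusionConfig = dataclasses.field(default_factory=FusionConfig)
    augment_config: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay, self.beta1, self.beta2) < 0:
            raise ValueError("all rates must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss_config.lam > 0 and self.fusion_config.ablate_experts:
            raise ValueError("heritable loss (lambda > 0) requires the expert "
                             "branches; disable ablate_experts or set lambda = 0")

    @classmethod
    def paper_protocol(cls, **overrides) -> "TrainConfig":
        """The full published optimization protocol (batch 2, 200 epochs)."""
        base = dict(batch_size=2, epochs=200)
        base.update(overrides)
        return cls(**base)


@dataclasses.dataclass
class TrainHistory:
    epochs: list  # per-epoch dicts of mean loss components (+ val metrics)
    steps: list  # per-step loss component dicts

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        self.to_frame().to_csv(out_dir / "history.csv", index=False)
        with open(out_dir / "steps.jsonl", "w") as fh:
            for rec in self.steps:
                fh.write(json.dumps(rec) + "\n")


class TraitStandardizer:
    """Per-task z-scoring with training-set statistics."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, np.float64)
        self.std = np.where(np.asarray(std, np.float64) == 0, 1.0, std)

    @classmethod
    def fit(cls, labels: np.ndarray, enabled: bool = True) -> "TraitStandardizer":
        if not enabled:
            return cls(np.zeros(3), np.ones(3))
        return cls(labels.mean(axis=0), labels.std(axis=0))

    def transform(self, labels: np.ndarray) -> np.ndarray:
        return (labels - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean


class InputNormalizer:
    """Z-scoring of both modalities with training-set statistics.

    Depth maps carry a large constant offset (the camera height, ~600 mm)
    with only millimetres of signal on top; feeding them raw would leave
    the depth branch numerically dead at He-scaled initialization.
    """

    def __init__(self, rgb_mean, rgb_std, depth_mean, depth_std):
        self.rgb_mean = np.asarray(rgb_mean, np.float32).reshape(1, 1, 1, 3)
        self.rgb_std = np.asarray(np.where(np.asarray(rgb_std) == 0, 1.0, rgb_std),
                                  np.float32).reshape(1, 1, 1, 3)
        self.depth_mean = float(depth_mean)
        self.depth_std = float(depth_std) if depth_std > 0 else 1.0

    @classmethod
    def fit(cls, rgb: np.ndarray, depth: np.ndarray) -> "InputNormalizer":
        return cls(rgb.mean(axis=(0, 1, 2)), rgb.std(axis=(0, 1, 2)),
                   depth.mean(), depth.std())

    def __call__(self, rgb: np.ndarray, depth: np.ndarray):
        return ((rgb - self.rgb_mean) / self.rgb_std,
                (depth - self.depth_mean) / self.depth_std)


def _to_chw(rgb: np.ndarray, depth: np.ndarray):
    return (np.ascontiguousarray(rgb.transpose(0, 3, 1, 2), dtype=np.float32),
            np.ascontiguousarray(depth[:, None], dtype=np.float32))


def save_checkpoint(path, model: FusionExpertNet, config: TrainConfig,
                    standardizer: TraitStandardizer,
                    normalizer: InputNormalizer) -> None:
    meta = {
        "fusion_config": config.fusion_config.to_dict(),
        "loss_config": dataclasses.asdict(config.loss_config),
        "seed": config.seed,
        "standardize_targets": config.standardize_targets,
    }
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             label_mean=standardizer.mean, label_std=standardizer.std,
             rgb_mean=normalizer.rgb_mean.ravel(), rgb_std=normalizer.rgb_std.ravel(),
             depth_stats=np.array([normalizer.depth_mean, normalizer.depth_std]),
             **arrays)


def load_checkpoint(path):
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["meta"].tobytes()).decode())
        config = FusionConfig.from_dict(meta["fusion_config"])
        model = FusionExpertNet(config, seed=meta["seed"])
        state = {k[len("param::"):]: archive[k] for k in archive.files
                 if k.startswith("param::")}
        model.load_state_dict(state)
        standardizer = TraitStandardizer(archive["label_mean"], archive["label_std"])
        normalizer = InputNormalizer(archive["rgb_mean"], archive["rgb_std"],
                                     archive["depth_stats"][0], archive["depth_stats"][1])
        loss_config = LossConfig(**meta["loss_config"])
    return model, standardizer, normalizer, loss_config


def train_step(model: FusionExpertNet, optimizer: nn.Adam, rgb_t: Tensor,
               depth_t: Tensor, labels_z: np.ndarray, loss_config: LossConfig):
    """One optimization step; returns the logged loss components."""
    preds, embeddings, _ = model(rgb_t, depth_t)
    l_task = objectives.task_loss(preds, Tensor(labels_z.astype(np.float32)),
                                  literal_middle_term=loss_config.literal_middle_term)
    if loss_config.lam > 0:
        l_her, comps = objectives.heritable_loss(embeddings, loss_config)
        l_tot = objectives.total_loss(l_task, l_her, loss_config.lam)
    else:
        comps = objectives.LossComponents(*([np.nan] * 5), np.nan, np.nan)
        comps.l_heritable = 0.0
        l_tot = l_task
    comps.l_task = float(l_task.item())
    comps.l_total = float(l_tot.item())
    optimizer.zero_grad()
    l_tot.backward()
    optimizer.step()
    return comps


def train(train_manifest: DatasetManifest, config: TrainConfig, out_dir,
          val_manifest: DatasetManifest | None = None):
    """Train on a manifest; returns (best checkpoint path, TrainHistory).

    Deterministic given the config seed: seeded initialization, one data
    permutation stream, seeded augmentation.  The best checkpoint is the
    epoch with the highest validation mean R-squared across traits (final
    epoch when no validation manifest is given).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rgb, depth, labels = dataset_io.load_split_arrays(train_manifest)
    standardizer = TraitStandardizer.fit(labels, enabled=config.standardize_targets)
    normalizer = InputNormalizer.fit(rgb, depth)
    labels_z = standardizer.transform(labels)

    model = FusionExpertNet(config.fusion_config, seed=config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2,
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDA7A]))
    n = rgb.shape[0]
    history = TrainHistory(epochs=[], steps=[])
    best = (-np.inf, None)
    best_path = out_dir / "best.ckpt.npz"
    final_path = out_dir / "final.ckpt.npz"

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_comps = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch_rgb = np.empty_like(rgb[idx])
            batch_depth = np.empty_like(depth[idx])
            for j, i in enumerate(idx):
                batch_rgb[j], batch_depth[j] = dataset_io.augment_pair(
                    rgb[i], depth[i], config.augment_config, rng)
            batch_rgb, batch_depth = normalizer(batch_rgb, batch_depth)
            rgb_t, depth_t = _to_chw(batch_rgb, batch_depth)
            comps = train_step(model, optimizer, Tensor(rgb_t), Tensor(depth_t),
                               labels_z[idx], config.loss_config)
            rec = comps.as_dict()
            rec.update(epoch=epoch, step=len(history.steps))
            history.steps.append(rec)
            epoch_comps.append(comps)
        epoch_rec = {
            "epoch": epoch,
            "l_task": float(np.mean([c.l_task for c in epoch_comps])),
            "l_heritable": float(np.nanmean([c.l_heritable for c in epoch_comps])),
            "l_total": float(np.mean([c.l_total for c in epoch_comps])),
        }
        if val_manifest is not None:
            report = _evaluate_model(model, standardizer, normalizer, val_manifest, "val")
            epoch_rec["val_mean_r2"] = report.mean_r_squared()
            if epoch_rec["val_mean_r2"] > best[0]:
                best = (epoch_rec["val_mean_r2"], epoch)
                save_checkpoint(best_path, model, config, standardizer, normalizer)
        history.epochs.append(epoch_rec)

    save_checkpoint(final_path, model, config, standardizer, normalizer)
    if val_manifest is None or best[1] is None:
        save_checkpoint(best_path, model, config, standardizer, normalizer)
    history.save(out_dir)
    return best_path, history


def _evaluate_model(model: FusionExpertNet, standardizer: TraitStandardizer,
                    normalizer: InputNormalizer, manifest: DatasetManifest,
                    split_tag: str, batch_size: int = 16,
                    round_counts: bool = False) -> MetricsReport:
    rgb, depth, labels = dataset_io.load_split_arrays(manifest)
    rgb, depth = normalizer(rgb, depth)
    model.eval()
    preds = []
    with ad.no_grad():
        for lo in range(0, rgb.shape[0], batch_size):
            rgb_t, depth_t = _to_chw(rgb[lo:lo + batch_size], depth[lo:lo + batch_size])
            p, _, _ = model(Tensor(rgb_t), Tensor(depth_t))
            preds.append(p.data)
    model.train()
    preds = standardizer.inverse(np.concatenate(preds, axis=0).astype(np.float64))
    return metrics_report(preds, labels, split_tag, round_counts=round_counts)


def evaluate(checkpoint_path, manifest: DatasetManifest, split_tag: str = "test",
             round_counts: bool = False) -> MetricsReport:
    """Forward passes without augmentation; metrics on de-standardized predictions."""
    model, standardizer, normalizer, _ = load_checkpoint(checkpoint_path)
    return _evaluate_model(model, standardizer, normalizer, manifest, split_tag,
                           round_counts=round_counts)


def predict_embeddings(checkpoint_path, manifest: DatasetManifest,
                       batch_size: int = 16):
    """Collect father/mother/child embeddings over a manifest (n, d) each."""
    model, _, normalizer, _ = load_checkpoint(checkpoint_path)
    if model.config.ablate_experts:
        raise ValueError("checkpoint was trained with experts ablated; "
                         "no per-branch embeddings exist")
    rgb, depth, _ = dataset_io.load_split_arrays(manifest)
    rgb, depth = normalizer(rgb, depth)
    model.eval()
    out = {"father": [], "mother": [], "child": []}
    with ad.no_grad():
        for lo in range(0, rgb.shape[0], batch_size):
            rgb_t, depth_t = _to_chw(rgb[lo:lo + batch_size], depth[lo:lo + batch_size])
            _, emb, _ = model(Tensor(rgb_t), Tensor(depth_t))
            out["father"].append(emb.father.data)
            out["mother"].append(emb.mother.data)
            out["child"].append(emb.child.data)
    return {k: np.concatenate(v, axis=0) for k, v in out.items()}
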