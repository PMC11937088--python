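"""Experiment harness: component ablations, baseline comparisons, expert
contribution readout and PCA feature-cluster analysis, all on the bundled
synthetic benchmark.

The ablation grid crosses three components — A (spatial attention),
E (the three expert branches) and L_h (the heritable loss) — over the six
valid combinations (L_h requires E).  The baseline comparison trains
schematic stand-ins that reuse this package's building blocks, so the
differences isolate the fusion strategy rather than implementation
details: single-modality experts, a two-branch network without fusion
features, an attention-on-RGB-then-fuse single network, a
mixture-of-experts with a softmax gating network, and the proposed model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import dataset_io, nn, objectives
from .autodiff import Tensor
from .dataset_io import DatasetManifest
from .fusion_network import (EXPERTS, TASKS, ExpertEmbeddings, ExpertNetwork,
                             FusionConfig, FusionExpertNet, ShallowExtractor,
                             SpatialAttention, shallow_extract, split_masked)
from .objectives import LossConfig
from .trait_metrics import TRAIT_NAMES
from . import training_engine as engine

#: (A, E, Lh) rows of the ablation grid, in presentation order
ABLATION_GRID = (
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (True, True, False),
    (False, True, True),
    (True, True, True),
)

BASELINE_KINDS = ("single_rgb", "single_depth", "branch_no_fusion",
                  "attention_fusion", "moe_gating", "proposed")


def _flags_to_config(base: engine.TrainConfig, attention: bool, experts: bool,
                     heritable: bool, seed: int) -> engine.TrainConfig:
    if heritable and not experts:
        raise ValueError("invalid ablation cell: the heritable loss relies on "
                         "the presence of multiple experts")
    fusion = dataclasses.replace(base.fusion_config,
                                 ablate_attention=not attention,
                                 ablate_experts=not experts)
    loss = dataclasses.replace(base.loss_config,
                               lam=base.loss_config.lam if heritable else 0.0)
    return dataclasses.replace(base, fusion_config=fusion, loss_config=loss, seed=seed)


def run_ablation(train_manifest: DatasetManifest, test_manifest: DatasetManifest,
                 base_config: engine.TrainConfig, seeds, out_dir) -> pd.DataFrame:
    """Train every valid (A, E, Lh) combination per seed and tabulate
    per-trait NRMSE (train), NRMSEP (test) and R-squared (test), averaged
    over seeds.  Writes ``ablation.csv`` under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for attention, experts, heritable in ABLATION_GRID:
        per_seed = []
        for seed in seeds:
            cfg = _flags_to_config(base_config, attention, experts, heritable, seed)
            run_dir = out_dir / f"A{int(attention)}_E{int(experts)}_Lh{int(heritable)}_s{seed}"
            ckpt, _ = engine.train(train_manifest, cfg, run_dir)
            train_rep = engine.evaluate(ckpt, train_manifest, "train")
            test_rep = engine.evaluate(ckpt, test_manifest, "test")
            per_seed.append((train_rep, test_rep))
        row = {"A": attention, "E": experts, "Lh": heritable}
        for trait in TRAIT_NAMES:
            row[f"{trait}_nrmse"] = float(np.mean(
                [tr.per_trait[trait]["nrmse"] for tr, _ in per_seed]))
            row[f"{trait}_nrmsep"] = float(np.mean(
                [te.per_trait[trait]["nrmsep"] for _, te in per_seed]))
            row[f"{trait}_r_squared"] = float(np.mean(
                [te.per_trait[trait]["r_squared"] for _, te in per_seed]))
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ablation.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# baseline models
# ---------------------------------------------------------------------------

class SingleModalNet(nn.Module):
    """One shallow extractor + one expert on a single modality."""

    def __init__(self, modality: str, config: FusionConfig, seed: int = 0):
        super().__init__()
        if modality not in ("rgb", "depth"):
            raise ValueError("modality must be 'rgb' or 'depth'")
        self.modality = modality
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
        c = config.shallow_channels
        self.shallow = ShallowExtractor(3 if modality == "rgb" else 1, c, rng)
        self.expert = ExpertNetwork(c, config, rng)
        self.heads = [nn.Linear(config.embedding_dim, 1, rng=rng) for _ in TASKS]

    def __call__(self, rgb: Tensor, depth: Tensor):
        feats = self.shallow(rgb if self.modality == "rgb" else depth)
        emb = self.expert(feats)
        preds = ad.concat([head(emb) for head in self.heads], axis=1)
        return preds, None, None


class BranchNoFusionNet(nn.Module):
    """Two modality branches whose embeddings are simply concatenated."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x52]))
        c = config.shallow_channels
        self.shallow_rgb = ShallowExtractor(3, c, rng)
        self.shallow_depth = ShallowExtractor(1, c, rng)
        self.expert_rgb = ExpertNetwork(c, config, rng)
        self.expert_depth = ExpertNetwork(c, config, rng)
        self.heads = [nn.Linear(2 * config.embedding_dim, 1, rng=rng) for _ in TASKS]

    def __call__(self, rgb: Tensor, depth: Tensor):
        f_rgb, f_d = shallow_extract(rgb, depth, self.shallow_rgb, self.shallow_depth)
        emb = ad.concat([self.expert_rgb(f_rgb), self.expert_depth(f_d)], axis=1)
        preds = ad.concat([head(emb) for head in self.heads], axis=1)
        return preds, None, None


class AttentionFusionNet(nn.Module):
    """Spatial attention on the RGB features only, then concatenation with
    depth features into one general network."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x53]))
        c = config.shallow_channels
        self.shallow_rgb = ShallowExtractor(3, c, rng)
        self.shallow_depth = ShallowExtractor(1, c, rng)
        self.attention = SpatialAttention(config.attention_kernel, rng)
        self.general = ExpertNetwork(2 * c, config, rng)
        self.heads = [nn.Linear(config.embedding_dim, 1, rng=rng) for _ in TASKS]

    def __call__(self, rgb: Tensor, depth: Tensor):
        f_rgb, f_d = shallow_extract(rgb, depth, self.shallow_rgb, self.shallow_depth)
        f_rgb = self.attention(f_rgb) * f_rgb
        emb = self.general(ad.concat([f_rgb, f_d], axis=1))
        preds = ad.concat([head(emb) for head in self.heads], axis=1)
        return preds, None, None


class MoENet(nn.Module):
    """Three experts on the split (unmasked) fused features, combined by a
    per-sample softmax gating network over pooled shallow features."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x54]))
        c = config.shallow_channels
        self.shallow_rgb = ShallowExtractor(3, c, rng)
        self.shallow_depth = ShallowExtractor(1, c, rng)
        self.experts = [ExpertNetwork(c, config, rng),
                        ExpertNetwork(2 * c, config, rng),
                        ExpertNetwork(c, config, rng)]
        self.gate = nn.Linear(2 * c, 3, rng=rng)
        self.heads = [nn.Linear(config.embedding_dim, 1, rng=rng) for _ in TASKS]

    def gate_weights(self, f_rgbd: Tensor) -> Tensor:
        pooled = ad.global_avg_pool(f_rgbd)
        logits = self.gate(pooled)
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = shifted.exp()
        return ex / ex.sum(axis=1, keepdims=True)

    def __call__(self, rgb: Tensor, depth: Tensor):
        f_rgb, f_d = shallow_extract(rgb, depth, self.shallow_rgb, self.shallow_depth)
        f_rgbd = ad.concat([f_rgb, f_d], axis=1)
        m_rgb, m_rgbd, m_d = split_masked(f_rgbd)
        embs = [self.experts[0](m_rgb), self.experts[1](m_rgbd), self.experts[2](m_d)]
        gates = self.gate_weights(f_rgbd)  # (n, 3), rows sum to 1
        mixed = None
        for e, emb in enumerate(embs):
            term = gates[:, e:e + 1] * emb
            mixed = term if mixed is None else mixed + term
        preds = ad.concat([head(mixed) for head in self.heads], axis=1)
        return preds, None, None


def build_baseline(kind: str, config: FusionConfig, seed: int = 0):
    if kind == "single_rgb":
        return SingleModalNet("rgb", config, seed)
    if kind == "single_depth":
        return SingleModalNet("depth", config, seed)
    if kind == "branch_no_fusion":
        return BranchNoFusionNet(config, seed)
    if kind == "attention_fusion":
        return AttentionFusionNet(config, seed)
    if kind == "moe_gating":
        return MoENet(config, seed)
    if kind == "proposed":
        return FusionExpertNet(config, seed)
    raise ValueError(f"unknown baseline kind {kind!r}")


def run_baselines(train_manifest: DatasetManifest, test_manifest: DatasetManifest,
                  base_config: engine.TrainConfig, seeds, out_dir) -> pd.DataFrame:
    """Train every baseline on identical data/seeds; emit a per-trait
    test R-squared comparison table (``baselines.csv``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind in BASELINE_KINDS:
        per_seed = []
        for seed in seeds:
            cfg = dataclasses.replace(
                base_config, seed=seed,
                loss_config=dataclasses.replace(
                    base_config.loss_config,
                    lam=base_config.loss_config.lam if kind == "proposed" else 0.0))
            run_dir = out_dir / f"{kind}_s{seed}"
            if kind == "proposed":
                ckpt, _ = engine.train(train_manifest, cfg, run_dir)
                per_seed.append(engine.evaluate(ckpt, test_manifest, "test"))
            else:
                model = build_baseline(kind, cfg.fusion_config, seed)
                report = _train_and_eval_model(model, train_manifest, test_manifest, cfg)
                per_seed.append(report)
        row = {"model": kind}
        for trait in TRAIT_NAMES:
            row[f"{trait}_r_squared"] = float(np.mean(
                [rep.per_trait[trait]["r_squared"] for rep in per_seed]))
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "baselines.csv", index=False)
    return table


def _train_and_eval_model(model, train_manifest, test_manifest,
                          config: engine.TrainConfig):
    """Minimal task-loss-only training loop shared by the baseline models."""
    rgb, depth, labels = dataset_io.load_split_arrays(train_manifest)
    standardizer = engine.TraitStandardizer.fit(labels, config.standardize_targets)
    normalizer = engine.InputNormalizer.fit(rgb, depth)
    labels_z = standardizer.transform(labels)
    optimizer = nn.Adam(model.parameters(), lr=config.learning_rate,
                        beta1=config.beta1, beta2=config.beta2,
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDA7A]))
    n = rgb.shape[0]
    for _ in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            batch_rgb = np.empty_like(rgb[idx])
            batch_depth = np.empty_like(depth[idx])
            for j, i in enumerate(idx):
                batch_rgb[j], batch_depth[j] = dataset_io.augment_pair(
                    rgb[i], depth[i], config.augment_config, rng)
            batch_rgb, batch_depth = normalizer(batch_rgb, batch_depth)
            rgb_t, depth_t = engine._to_chw(batch_rgb, batch_depth)
            preds, _, _ = model(Tensor(rgb_t), Tensor(depth_t))
            l_task = objectives.task_loss(preds, Tensor(labels_z[idx].astype(np.float32)))
            optimizer.zero_grad()
            l_task.backward()
            optimizer.step()
    # evaluate
    t_rgb, t_depth, t_labels = dataset_io.load_split_arrays(test_manifest)
    t_rgb, t_depth = normalizer(t_rgb, t_depth)
    model.eval()
    preds = []
    with ad.no_grad():
        for lo in range(0, t_rgb.shape[0], 16):
            rgb_t, depth_t = engine._to_chw(t_rgb[lo:lo + 16], t_depth[lo:lo + 16])
            p, _, _ = model(Tensor(rgb_t), Tensor(depth_t))
            preds.append(p.data)
    preds = standardizer.inverse(np.concatenate(preds).astype(np.float64))
    from .trait_metrics import metrics_report

    return metrics_report(preds, t_labels, "test")


# ---------------------------------------------------------------------------
# model introspection
# ---------------------------------------------------------------------------

def expert_contributions(checkpoint_path) -> pd.DataFrame:
    """Learned per-task, per-expert gate magnitudes (3 tasks x 3 experts),
    read out of the checkpoint, not recomputed."""
    model, _, _, _ = engine.load_checkpoint(checkpoint_path)
    if model.config.ablate_experts:
        raise ValueError("checkpoint was trained with experts ablated; "
                         "no expert contributions exist")
    gates = model.gates().data
    return pd.DataFrame(gates, index=list(TASKS), columns=list(EXPERTS))


def branch_pca(embeddings: dict, n_components: int = 2):
    """Shared PCA over father/mother/child embeddings plus the silhouette
    score of the 3-way branch labeling.

    The silhouette is computed on the full-dimensional embeddings (the
    2-D PCA projection is for visualization only).  ``embeddings``:
    branch name -> (n, d) array.  Raises on degenerate (all-identical)
    embeddings, where the silhouette is undefined.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    names = sorted(embeddings)
    X = np.concatenate([embeddings[k] for k in names], axis=0)
    labels = np.concatenate([[k] * len(embeddings[k]) for k in names])
    if np.allclose(X, X[0]):
        raise ValueError("all embeddings identical; silhouette undefined")
    pca = PCA(n_components=n_components, random_state=0)
    proj = pca.fit_transform(X)
    score = float(silhouette_score(X, labels))
    points = pd.DataFrame(proj, columns=[f"pc{i + 1}" for i in range(n_components)])
    points["branch"] = labels
    return points, score, pca


def feature_pca(checkpoint_path, manifest: DatasetManifest, n_components: int = 2,
                out_path=None):
    """Collect per-branch embeddings over a manifest, project with one
    shared PCA, and score the branch separation; optionally writes the
    scatter data as CSV."""
    if len(manifest) < 3:
        raise ValueError("feature PCA needs at least 3 scenes")
    embeddings = engine.predict_embeddings(checkpoint_path, manifest)
    points, score, pca = branch_pca(embeddings, n_components)
    if out_path is not None:
        points.to_csv(Path(out_path), index=False)
    return points, score


def plot_feature_clusters(points: pd.DataFrame, out_png) -> None:
    """Scatter plot of the PCA projections colored by branch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for branch, sub in points.groupby("branch"):
        ax.scatter(sub["pc1"], sub["pc2"], s=12, label=branch, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
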