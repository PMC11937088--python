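"""Scene file and manifest I/O, train/test splitting, and augmentation.

Manifests are plain CSV (scene_id, rgb_path, depth_path, weight_g,
uniformity_cv, count) with a leading comment line recording the depth
encoding scale; image paths are relative to the manifest location.
Depth maps are stored as 16-bit grayscale PNGs at a fixed mm-per-unit
scale (0.1 mm by default, i.e. one quantization step is 0.1 mm and the
worst-case round-trip error is half a step).

Training augmentation follows the usual color/geometry split: a
horizontal flip, when drawn, is applied jointly to both modalities so
they stay registered; a multiplicative brightness jitter touches the
color image only — rescaling depth values would corrupt the scene
geometry.  All three trait labels are invariant under this family.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synthetic_scenes import RGBDScene, TraitLabels

_SCALE_PREFIX = "# depth_scale_mm_per_unit="


@dataclasses.dataclass
class DatasetManifest:
    rows: list[tuple]  # (scene_id, rgb_path, depth_path, TraitLabels)
    depth_scale: float
    split_tag: str = "unsplit"
    base_dir: Path | None = None

    def __post_init__(self):
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("scene_ids in a manifest must be unique")

    def __len__(self):
        return len(self.rows)

    def labels_array(self) -> np.ndarray:
        """(n, 3) array of [weight_g, uniformity_cv, count]."""
        return np.stack([r[3].as_array() for r in self.rows])


def write_rgb_png(path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))


def write_depth_png(path, depth_mm: np.ndarray, scale: float) -> None:
    units = np.clip(np.round(depth_mm / scale), 0, np.iinfo(np.uint16).max)
    iio.imwrite(Path(path), units.astype(np.uint16))


def save_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [(sid, rp, dp, lab.weight_g, lab.uniformity_cv, lab.count)
         for sid, rp, dp, lab in manifest.rows],
        columns=["scene_id", "rgb_path", "depth_path",
                 "weight_g", "uniformity_cv", "count"])
    buf = io.StringIO()
    buf.write(f"{_SCALE_PREFIX}{manifest.depth_scale}\n")
    df.to_csv(buf, index=False, float_format="%.10g", lineterminator="\n")
    path.write_text(buf.getvalue())


def load_manifest(path, split_tag: str = "unsplit") -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(_SCALE_PREFIX):
        raise ValueError(f"manifest {path} lacks the depth-scale header line")
    depth_scale = float(first[len(_SCALE_PREFIX):])
    df = pd.read_csv(path, comment="#")
    rows = [
        (r.scene_id, r.rgb_path, r.depth_path,
         TraitLabels(weight_g=float(r.weight_g),
                     uniformity_cv=float(r.uniformity_cv),
                     count=int(r.count)))
        for r in df.itertuples()
    ]
    return DatasetManifest(rows=rows, depth_scale=depth_scale,
                           split_tag=split_tag, base_dir=path.parent)


def load_scene(manifest_row, depth_scale: float, base_dir) -> RGBDScene:
    """Load one manifest row into memory (rgb in [0,1], depth in mm)."""
    sid, rgb_path, depth_path, labels = manifest_row
    base_dir = Path(base_dir)
    rgb_file = base_dir / rgb_path
    depth_file = base_dir / depth_path
    for f in (rgb_file, depth_file):
        if not f.exists():
            raise FileNotFoundError(f"scene {sid}: missing file {f}")
    try:
        rgb = iio.imread(rgb_file).astype(np.float32) / 255.0
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise ValueError(f"scene {sid}: corrupt RGB image {rgb_file}: {exc}") from exc
    try:
        depth = iio.imread(depth_file).astype(np.float32) * depth_scale
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"scene {sid}: corrupt depth image {depth_file}: {exc}") from exc
    return RGBDScene(rgb=rgb, depth=depth, labels=labels, berry_list=[])


def split_manifest(manifest: DatasetManifest, train_fraction: float,
                   seed: int) -> tuple[DatasetManifest, DatasetManifest]:
    """Random disjoint, exhaustive partition; train size = round(f * n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    n_train = int(round(train_fraction * len(manifest)))
    train_rows = [manifest.rows[i] for i in sorted(perm[:n_train])]
    test_rows = [manifest.rows[i] for i in sorted(perm[n_train:])]
    mk = lambda rows, tag: DatasetManifest(rows=rows, depth_scale=manifest.depth_scale,
                                           split_tag=tag, base_dir=manifest.base_dir)
    return mk(train_rows, "train"), mk(test_rows, "test")


@dataclasses.dataclass
class AugmentConfig:
    flip_probability: float = 0.5
    brightness_range: tuple[float, float] = (0.8, 1.2)
    enabled: bool = True

    def __post_init__(self):
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.brightness_range[0] <= 0:
            raise ValueError("brightness_range bounds must be positive")


def augment_pair(rgb: np.ndarray, depth: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Jointly flip both modalities; brightness-jitter the color image only."""
    if rgb.shape[:2] != depth.shape[:2]:
        raise ValueError("rgb and depth must be spatially aligned")
    if not config.enabled:
        return rgb, depth
    if rng.random() < config.flip_probability:
        rgb = rgb[:, ::-1].copy()
        depth = depth[:, ::-1].copy()
    factor = rng.uniform(*config.brightness_range)
    rgb = np.clip(rgb * factor, 0.0, 1.0)
    return rgb, depth


def load_split_arrays(manifest: DatasetManifest):
    """Load every scene of a manifest into (rgb (n,H,W,3), depth (n,H,W),
    labels (n,3)) arrays for training."""
    rgbs, depths = [], []
    for row in manifest.rows:
        scene = load_scene(row, manifest.depth_scale, manifest.base_dir)
        rgbs.append(scene.rgb)
        depths.append(scene.depth)
    return np.stack(rgbs), np.stack(depths), manifest.labels_array()
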