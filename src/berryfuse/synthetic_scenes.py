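"""Synthetic RGB-D berry scenes with exact ground-truth trait labels.

Each scene is a top-down orthographic view of 1..N ellipsoidal berries
resting on a flat plane.  The color image shows Lambertian-shaded
reddish ellipses on a dark background; the depth map is the z-buffer
distance from an overhead camera (background pixels = camera height,
berry pixels = camera height minus the local surface height).  The three
scene labels are computed analytically from the generating geometry:

* fresh weight  — tissue density x sum of ellipsoid volumes (4/3 pi a b c),
* size uniformity — coefficient of variation (population standard
  deviation / mean, in percent) of the per-berry aspect ratios,
* count — number of berries.

To emulate a real stereo depth sensor whose depth stream has lower
resolution than its color stream, the rendered depth map can be
block-downsampled, restored by bilinear interpolation and Gaussian
smoothed (``degrade_and_restore_depth``), and perturbed with Gaussian
noise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

DEPTH_SCALE_MM = 0.1  # mm per stored 16-bit unit in depth PNGs


class SceneTooCrowdedError(RuntimeError):
    """Raised when non-overlapping berry placement fails after max retries."""


@dataclasses.dataclass
class TraitLabels:
    """Ground-truth targets: total fresh weight (g), aspect-ratio CV (%), count."""

    weight_g: float
    uniformity_cv: float
    count: int

    def __post_init__(self):
        if self.weight_g < 0 or self.uniformity_cv < 0 or self.count < 0:
            raise ValueError("trait labels must be nonnegative")
        if self.count <= 1 and self.uniformity_cv != 0:
            raise ValueError("uniformity_cv must be 0 for batches of size <= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.weight_g, self.uniformity_cv, self.count], dtype=np.float64)


@dataclasses.dataclass
class BerryGeometry:
    """One ellipsoidal berry: in-plane position (px), semi-axes a,b,c (mm),
    in-plane rotation (rad) and base RGB color. a is the half-length, b the
    half-width (aspect_ratio = a/b), c the vertical semi-axis."""

    center_xy: tuple[float, float]
    semi_axes_abc: tuple[float, float, float]
    aspect_ratio: float
    base_color: tuple[float, float, float]
    rotation: float = 0.0

    def __post_init__(self):
        a, b, c = self.semi_axes_abc
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if not np.isclose(self.aspect_ratio, a / b, rtol=1e-9):
            raise ValueError("aspect_ratio must equal a/b")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_abc
        return 4.0 / 3.0 * np.pi * a * b * c

    def to_dict(self) -> dict:
        return {
            "center_xy": list(self.center_xy),
            "semi_axes_abc": list(self.semi_axes_abc),
            "aspect_ratio": self.aspect_ratio,
            "base_color": list(self.base_color),
            "rotation": self.rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BerryGeometry":
        return cls(tuple(d["center_xy"]), tuple(d["semi_axes_abc"]),
                   d["aspect_ratio"], tuple(d["base_color"]), d["rotation"])


@dataclasses.dataclass
class SceneParams:
    """Generator settings.

    The camera looks straight down from ``camera_height`` (mm); the image
    spans ``scene_extent_mm`` horizontally, so one pixel covers
    scene_extent_mm / width millimetres.  ``size_range`` bounds the berry
    half-width b; the half-length is b x aspect and the vertical semi-axis
    b x (a ratio drawn from ``c_ratio_range``).
    """

    image_size: tuple[int, int] = (224, 224)
    count_range: tuple[int, int] = (1, 8)
    size_range: tuple[float, float] = (6.0, 14.0)
    aspect_range: tuple[float, float] = (0.9, 1.9)
    aspect_spread_range: tuple[float, float] = (0.0, 0.45)
    c_ratio_range: tuple[float, float] = (0.8, 1.2)
    camera_height: float = 600.0
    tissue_density: float = 0.00095  # g/mm^3, slightly below water
    scene_extent_mm: float = 240.0
    depth_downsample_factor: int = 2
    depth_smoothing_sigma: float = 1.0
    noise_sigma: float = 1.0  # depth noise std, mm
    rgb_noise_sigma: float = 0.01
    supersample: int = 2  # sub-pixel sampling factor emulating the camera PSF
    seed: int = 0
    max_place_retries: int = 200

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ValueError("count_range must be an interval with lower bound >= 1")
        for name in ("size_range", "aspect_range", "c_ratio_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (possibly point) interval")
        lo, hi = self.aspect_spread_range
        if lo < 0 or hi < lo:
            raise ValueError("aspect_spread_range must be a nonnegative interval")
        if self.depth_downsample_factor < 1:
            raise ValueError("depth_downsample_factor must be >= 1")
        if self.camera_height <= 2 * self.size_range[1] * self.c_ratio_range[1]:
            raise ValueError("camera_height must clear the tallest berry")

    @property
    def mm_per_px(self) -> float:
        return self.scene_extent_mm / self.image_size[1]


@dataclasses.dataclass
class RGBDScene:
    """One paired color image + depth map with its ground-truth labels."""

    rgb: np.ndarray  # H x W x 3 in [0, 1]
    depth: np.ndarray  # H x W, mm from camera
    labels: TraitLabels
    berry_list: list[BerryGeometry]


def coefficient_of_variation(values, use_population_std: bool = True) -> float:
    """CV in percent: (population) standard deviation / mean x 100.

    Batches of size 0 or 1 have zero dispersion by convention.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size <= 1:
        return 0.0
    std = values.std(ddof=0 if use_population_std else 1)
    return float(std / values.mean() * 100.0)


def compute_labels(berries: list[BerryGeometry], params: SceneParams,
                   uniformity_on_size: bool = False) -> TraitLabels:
    """Analytic labels from geometry.

    ``uniformity_on_size`` switches the CV statistic from aspect ratios to
    per-berry lengths (2a, mm).
    """
    weight = params.tissue_density * sum(b.volume_mm3 for b in berries)
    if uniformity_on_size:
        xs = [2.0 * b.semi_axes_abc[0] for b in berries]
    else:
        xs = [b.aspect_ratio for b in berries]
    return TraitLabels(weight_g=weight,
                       uniformity_cv=coefficient_of_variation(xs),
                       count=len(berries))


def sample_berries(params: SceneParams, rng: np.random.Generator) -> list[BerryGeometry]:
    """Draw a non-overlapping berry layout by rejection sampling.

    Batches carry structure: each scene first draws a latent aspect center
    and half-spread, and its berries' aspect ratios come from that narrow
    scene-specific interval.  Harvested batches genuinely differ in shape
    uniformity (deliberately uniform premium boxes vs mixed field batches),
    so a scene's dispersion is a generative property, not merely sampling
    noise from one global shape distribution.

    Overlap is tested conservatively on bounding circles of radius a (the
    in-plane half-length).  Raises :class:`SceneTooCrowdedError` when a berry
    cannot be placed within ``max_place_retries`` attempts.
    """
    h, w = params.image_size
    mm_px = params.mm_per_px
    n = int(rng.integers(params.count_range[0], params.count_range[1] + 1))
    a_lo, a_hi = params.aspect_range
    half_spread = min(float(rng.uniform(*params.aspect_spread_range)),
                      (a_hi - a_lo) / 2.0)
    aspect_center = float(rng.uniform(a_lo + half_spread, a_hi - half_spread)) \
        if a_hi - half_spread > a_lo + half_spread else (a_lo + a_hi) / 2.0
    berries: list[BerryGeometry] = []
    for _ in range(n):
        for attempt in range(params.max_place_retries):
            b = rng.uniform(*params.size_range)
            aspect = rng.uniform(aspect_center - half_spread,
                                 aspect_center + half_spread)
            a = b * aspect
            c = b * rng.uniform(*params.c_ratio_range)
            r_px = a / mm_px
            if 2 * r_px + 2 > min(h, w):
                continue
            cx = rng.uniform(r_px + 1, w - r_px - 1)
            cy = rng.uniform(r_px + 1, h - r_px - 1)
            ok = all(
                np.hypot(cx - o.center_xy[0], cy - o.center_xy[1]) * mm_px
                > a + o.semi_axes_abc[0]
                for o in berries
            )
            if ok:
                color = (rng.uniform(0.6, 0.9), rng.uniform(0.05, 0.25),
                         rng.uniform(0.05, 0.2))
                berries.append(BerryGeometry(
                    center_xy=(cx, cy), semi_axes_abc=(a, b, c),
                    aspect_ratio=a / b, base_color=color,
                    rotation=float(rng.uniform(0.0, 2 * np.pi))))
                break
        else:
            raise SceneTooCrowdedError(
                f"could not place berry {len(berries) + 1}/{n} after "
                f"{params.max_place_retries} retries; reduce count_range or "
                f"enlarge the image")
    return berries


def _pixel_grid(params: SceneParams, ss: int):
    """Sub-pixel sample centers in base-pixel coordinates (ss x supersampling)."""
    h, w = params.image_size
    ys = (np.arange(h * ss) + 0.5) / ss - 0.5
    xs = (np.arange(w * ss) + 0.5) / ss - 0.5
    return np.meshgrid(ys, xs, indexing="ij")


def _height_field(berries: list[BerryGeometry], params: SceneParams,
                  ss: int = 1) -> np.ndarray:
    """Surface height above the plane (mm) per (sub)pixel; z-buffer max over berries."""
    mm_px = params.mm_per_px
    yy, xx = _pixel_grid(params, ss)
    height = np.zeros_like(xx)
    for berry in berries:
        a, b, c = berry.semi_axes_abc
        cx, cy = berry.center_xy
        dx = (xx - cx) * mm_px
        dy = (yy - cy) * mm_px
        ct, st = np.cos(berry.rotation), np.sin(berry.rotation)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        s = 1.0 - (u / a) ** 2 - (v / b) ** 2
        # berry rests on the plane: center at height c, upper surface c(1+sqrt(s))
        hb = np.where(s > 0, c * (1.0 + np.sqrt(np.clip(s, 0.0, None))), 0.0)
        np.maximum(height, hb, out=height)
    return height


def _block_mean(arr: np.ndarray, ss: int) -> np.ndarray:
    if ss == 1:
        return arr
    if arr.ndim == 2:
        h, w = arr.shape
        return arr.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))
    h, w, c = arr.shape
    return arr.reshape(h // ss, ss, w // ss, ss, c).mean(axis=(1, 3))


def degrade_and_restore_depth(depth: np.ndarray, factor: int,
                              smoothing_sigma: float) -> np.ndarray:
    """Block-average downsample by ``factor``, bilinear-upsample back, then
    Gaussian-smooth — emulating a low-resolution depth stream upsampled to
    the color resolution.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = depth.shape
    if h % factor or w % factor:
        raise ValueError(f"factor {factor} does not divide image size {depth.shape}")
    out = depth
    if factor > 1:
        small = depth.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
        # half-pixel-centered bilinear upsample with edge clamping
        yi = (np.arange(h) + 0.5) / factor - 0.5
        xi = (np.arange(w) + 0.5) / factor - 0.5
        grid = np.meshgrid(yi, xi, indexing="ij")
        out = ndimage.map_coordinates(small, grid, order=1, mode="nearest")
    if smoothing_sigma > 0:
        out = ndimage.gaussian_filter(out, smoothing_sigma, mode="nearest")
    return out


def render_scene(berries: list[BerryGeometry], params: SceneParams,
                 rng: np.random.Generator | None = None) -> RGBDScene:
    """Render color + z-buffer depth and attach analytic labels.

    Depth pipeline: raw z-buffer -> Gaussian sensor noise (noise_sigma) ->
    resolution degradation/restoration (depth_downsample_factor); values are
    clamped to the camera height (nothing lies behind the supporting plane).
    """
    rng = rng or np.random.default_rng(params.seed)
    h, w = params.image_size
    ss = max(1, params.supersample)
    height = _height_field(berries, params, ss)
    depth = _block_mean(params.camera_height - height, ss)
    if params.noise_sigma > 0:
        depth = depth + rng.normal(0.0, params.noise_sigma, size=depth.shape)
    if params.depth_downsample_factor > 1:
        depth = degrade_and_restore_depth(depth, params.depth_downsample_factor,
                                          params.depth_smoothing_sigma)
    depth = np.minimum(depth, params.camera_height)

    # Lambertian-style shading from the (supersampled) height field
    gy, gx = np.gradient(height, params.mm_per_px / ss)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    light = np.array([0.35, -0.35, 1.0])
    light = light / np.linalg.norm(light)
    shade = np.clip((-gx * light[0] - gy * light[1] + light[2]) / norm, 0.0, 1.0)

    rgb = np.empty((h * ss, w * ss, 3))
    rgb[..., 0], rgb[..., 1], rgb[..., 2] = 0.08, 0.10, 0.06  # dark background
    mask = height > 0
    color = np.zeros((h * ss, w * ss, 3))
    if berries:  # per-(sub)pixel color by tallest-berry ownership
        owner = np.full((h * ss, w * ss), -1, dtype=np.int64)
        best = np.zeros((h * ss, w * ss))
        mm_px = params.mm_per_px
        yy, xx = _pixel_grid(params, ss)
        for i, berry in enumerate(berries):
            a, b, c = berry.semi_axes_abc
            cx, cy = berry.center_xy
            dx = (xx - cx) * mm_px
            dy = (yy - cy) * mm_px
            ct, st = np.cos(berry.rotation), np.sin(berry.rotation)
            u = dx * ct + dy * st
            v = -dx * st + dy * ct
            s = 1 - (u / a) ** 2 - (v / b) ** 2
            hb = np.where(s > 0, c * (1.0 + np.sqrt(np.clip(s, 0, None))), 0.0)
            take = hb > best
            owner[take] = i
            best[take] = hb[take]
        for i, berry in enumerate(berries):
            sel = owner == i
            color[sel] = berry.base_color
    rgb[mask] = color[mask] * (0.35 + 0.65 * shade[mask, None])
    rgb = _block_mean(rgb, ss)
    if params.rgb_noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, params.rgb_noise_sigma, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)

    return RGBDScene(rgb=rgb, depth=depth,
                     labels=compute_labels(berries, params),
                     berry_list=berries)


def generate_dataset(n_scenes: int, params: SceneParams, out_dir):
    """Write ``n_scenes`` scenes (RGB PNG, 16-bit depth PNG, geometry JSON)
    plus a manifest CSV; fully deterministic given ``params.seed``.

    Returns the loaded :class:`berryfuse.dataset_io.DatasetManifest`.
    """
    from . import dataset_io  # deferred: dataset_io imports scene types from here

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(params.seed).spawn(n_scenes)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        berries = sample_berries(params, rng)
        scene = render_scene(berries, params, rng)
        sid = f"scene_{i:05d}"
        rgb_path = f"{sid}_rgb.png"
        depth_path = f"{sid}_depth.png"
        try:
            dataset_io.write_rgb_png(out_dir / rgb_path, scene.rgb)
            dataset_io.write_depth_png(out_dir / depth_path, scene.depth, DEPTH_SCALE_MM)
        except OSError as exc:
            raise OSError(f"failed writing scene files for {sid} under {out_dir}: {exc}") from exc
        with open(out_dir / f"{sid}_berries.json", "w") as fh:
            json.dump([b.to_dict() for b in berries], fh, indent=None, sort_keys=True)
        rows.append((sid, rgb_path, depth_path, scene.labels))
    manifest = dataset_io.DatasetManifest(rows=rows, depth_scale=DEPTH_SCALE_MM,
                                          split_tag="unsplit", base_dir=out_dir)
    dataset_io.save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
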