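"""Generator correctness: placement, rendering physics, analytic labels,
depth degradation, dataset round trips and determinism."""

import dataclasses

import numpy as np
import pytest

from berryfuse import dataset_io
from berryfuse.synthetic_scenes import (BerryGeometry, SceneParams,
                                        SceneTooCrowdedError,
                                        coefficient_of_variation,
                                        compute_labels,
                                        degrade_and_restore_depth,
                                        generate_dataset, render_scene,
                                        sample_berries)


def clean_params(**overrides):
    """Noise-free, full-resolution rendering for exact geometric checks."""
    base = dict(image_size=(64, 64), scene_extent_mm=128.0, noise_sigma=0.0,
                rgb_noise_sigma=0.0, depth_downsample_factor=1,
                depth_smoothing_sigma=0.0, supersample=1, seed=3)
    base.update(overrides)
    return SceneParams(**base)


def sphere(radius, center=(32.0, 32.0)):
    return BerryGeometry(center_xy=center, semi_axes_abc=(radius,) * 3,
                         aspect_ratio=1.0, base_color=(0.8, 0.1, 0.1))


class TestSampleBerries:
    def test_degenerate_count_interval_forces_count(self, rng):
        params = clean_params(count_range=(3, 3))
        assert len(sample_berries(params, rng)) == 3

    def test_point_aspect_interval_gives_zero_cv(self, rng):
        params = clean_params(count_range=(4, 4), aspect_range=(1.4, 1.4))
        berries = sample_berries(params, rng)
        assert all(np.isclose(b.aspect_ratio, 1.4) for b in berries)
        assert compute_labels(berries, params).uniformity_cv == 0.0

    def test_same_seed_same_layout(self):
        params = clean_params(count_range=(2, 5))
        a = sample_berries(params, np.random.default_rng(9))
        b = sample_berries(params, np.random.default_rng(9))
        assert [x.to_dict() for x in a] == [y.to_dict() for y in b]

    def test_berries_do_not_overlap(self, rng):
        params = clean_params(count_range=(4, 4))
        berries = sample_berries(params, rng)
        for i, x in enumerate(berries):
            for y in berries[i + 1:]:
                dist_mm = np.hypot(x.center_xy[0] - y.center_xy[0],
                                   x.center_xy[1] - y.center_xy[1]) * params.mm_per_px
                assert dist_mm > x.semi_axes_abc[0] + y.semi_axes_abc[0]

    def test_crowded_scene_raises(self, rng):
        params = clean_params(image_size=(64, 64), scene_extent_mm=64.0,
                              count_range=(8, 8), size_range=(14.0, 16.0),
                              max_place_retries=20)
        with pytest.raises(SceneTooCrowdedError):
            sample_berries(params, rng)


class TestRenderScene:
    def test_sphere_apex_depth(self):
        """Apex of a sphere resting on the plane sits 2r above it."""
        params = clean_params()
        r = 10.0
        scene = render_scene([sphere(r)], params)
        assert np.isclose(scene.depth.min(), params.camera_height - 2 * r,
                          atol=params.mm_per_px)

    def test_sphere_depth_matches_raycast_oracle(self):
        """Full depth map against a brute-force per-pixel ray cast."""
        params = clean_params()
        r = 10.0
        scene = render_scene([sphere(r)], params)
        h, w = params.image_size
        oracle = np.full((h, w), params.camera_height)
        for i in range(h):
            for j in range(w):
                dx = (j - 32.0) * params.mm_per_px
                dy = (i - 32.0) * params.mm_per_px
                d2 = dx * dx + dy * dy
                if d2 < r * r:
                    # vertical ray hits the sphere (center at height r) at
                    # height r + sqrt(r^2 - d^2)
                    oracle[i, j] = params.camera_height - (r + np.sqrt(r * r - d2))
        np.testing.assert_allclose(scene.depth, oracle, atol=1e-9)

    def test_empty_scene(self):
        params = clean_params()
        scene = render_scene([], params)
        assert np.all(scene.depth == params.camera_height)
        assert scene.labels.count == 0 and scene.labels.weight_g == 0.0

    def test_output_shapes(self, rng):
        params = clean_params(image_size=(48, 64), scene_extent_mm=128.0)
        scene = render_scene(sample_berries(params, rng), params, rng)
        assert scene.rgb.shape == (48, 64, 3)
        assert scene.depth.shape == (48, 64)

    def test_supersampled_depth_close_to_exact(self):
        """PSF-style sub-pixel averaging only softens silhouette edges."""
        params_exact = clean_params()
        params_ss = clean_params(supersample=3)
        exact = render_scene([sphere(10.0)], params_exact).depth
        soft = render_scene([sphere(10.0)], params_ss).depth
        interior = exact < params_exact.camera_height - 5.0
        np.testing.assert_allclose(soft[interior], exact[interior], atol=1.5)
        background = exact == params_exact.camera_height
        # pixels far from the silhouette are untouched
        from scipy import ndimage

        far_bg = ndimage.binary_erosion(background, iterations=2)
        assert np.all(soft[far_bg] == params_exact.camera_height)

    def test_depth_physicality(self, rng):
        params = clean_params(count_range=(3, 5))
        berries = sample_berries(params, rng)
        scene = render_scene(berries, params)
        max_axis = max(max(b.semi_axes_abc) for b in berries)
        assert scene.depth.min() >= params.camera_height - 2 * max_axis - 1e-9
        assert scene.depth.max() == params.camera_height  # background exact
        assert np.all(scene.depth <= params.camera_height)


class TestComputeLabels:
    def test_cv_hand_example(self):
        """Aspect ratios (1, 3): mean 2, population std 1 -> CV = 50%."""
        assert np.isclose(coefficient_of_variation([1.0, 3.0]), 50.0)

    def test_equal_ratios_zero_cv(self):
        assert coefficient_of_variation([1.3] * 5) == 0.0
        assert coefficient_of_variation([2.0]) == 0.0
        assert coefficient_of_variation([]) == 0.0

    @pytest.mark.parametrize("c", [0.1, 1.0, 7.5])
    def test_cv_scale_invariance(self, rng, c):
        ratios = rng.uniform(1.0, 2.0, size=12)
        assert np.isclose(coefficient_of_variation(ratios),
                          coefficient_of_variation(c * ratios))

    def test_sphere_weight(self):
        params = clean_params(tissue_density=0.001)
        labels = compute_labels([sphere(10.0)], params)
        assert np.isclose(labels.weight_g, 4.0 / 3.0 * np.pi * 1000 * 0.001,
                          rtol=1e-12)
        assert np.isclose(labels.weight_g, 4.18879, atol=1e-5)

    def test_size_mode_uses_lengths(self):
        params = clean_params()
        berries = [sphere(8.0, (20.0, 20.0)), sphere(12.0, (44.0, 44.0))]
        by_aspect = compute_labels(berries, params)
        by_size = compute_labels(berries, params, uniformity_on_size=True)
        assert by_aspect.uniformity_cv == 0.0  # both spheres: aspect 1
        assert np.isclose(by_size.uniformity_cv,
                          coefficient_of_variation([16.0, 24.0]))


class TestDegradeRestore:
    def test_identity(self, rng):
        d = rng.normal(600, 5, size=(8, 8))
        np.testing.assert_array_equal(degrade_and_restore_depth(d, 1, 0.0), d)

    @pytest.mark.parametrize("factor", [1, 2, 4])
    def test_constant_preserved(self, factor):
        d = np.full((8, 8), 600.0)
        np.testing.assert_allclose(degrade_and_restore_depth(d, factor, 1.0), d)

    def test_ramp_hand_oracle(self):
        """4x4 column ramp, factor 2: block means (0.5, 2.5), half-pixel
        bilinear upsample -> columns (0.5, 1.0, 2.0, 2.5)."""
        d = np.tile(np.arange(4.0), (4, 1))
        out = degrade_and_restore_depth(d, 2, 0.0)
        expected = np.tile([0.5, 1.0, 2.0, 2.5], (4, 1))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_non_divisible_factor_raises(self):
        with pytest.raises(ValueError, match="does not divide"):
            degrade_and_restore_depth(np.zeros((9, 9)), 2, 0.0)


class TestGenerateDataset:
    def test_manifest_counts_and_files(self, tiny_dataset):
        assert len(tiny_dataset) == 24
        for sid, rgb_path, depth_path, _ in tiny_dataset.rows:
            assert (tiny_dataset.base_dir / rgb_path).exists()
            assert (tiny_dataset.base_dir / depth_path).exists()

    def test_label_self_consistency(self, tiny_dataset, tiny_params):
        """Manifest labels equal analytic recomputation from the stored
        per-berry geometry sidecars."""
        import json

        for sid, _, _, labels in tiny_dataset.rows:
            with open(tiny_dataset.base_dir / f"{sid}_berries.json") as fh:
                berries = [BerryGeometry.from_dict(d) for d in json.load(fh)]
            recomputed = compute_labels(berries, tiny_params)
            assert labels.count == len(berries)
            assert np.isclose(labels.weight_g, recomputed.weight_g, rtol=1e-9)
            ratios = [b.aspect_ratio for b in berries]
            assert np.isclose(labels.uniformity_cv,
                              coefficient_of_variation(ratios), rtol=1e-9)

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        params = clean_params(seed=77)
        generate_dataset(3, params, tmp_path / "a")
        generate_dataset(3, params, tmp_path / "b")
        ma = (tmp_path / "a" / "manifest.csv").read_bytes()
        mb = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert ma == mb
        pa = (tmp_path / "a" / "scene_00000_depth.png").read_bytes()
        pb = (tmp_path / "b" / "scene_00000_depth.png").read_bytes()
        assert pa == pb

    def test_roundtrip_uniformity_within_quantization(self, tiny_dataset):
        loaded = dataset_io.load_manifest(tiny_dataset.base_dir / "manifest.csv")
        for (sid, _, _, lab_a), (_, _, _, lab_b) in zip(tiny_dataset.rows, loaded.rows):
            assert np.isclose(lab_a.uniformity_cv, lab_b.uniformity_cv, atol=1e-8)
            assert lab_a.count == lab_b.count


class TestInvariantViolations:
    def test_bad_semi_axes(self):
        with pytest.raises(ValueError):
            BerryGeometry((0, 0), (1.0, -1.0, 1.0), 1.0, (1, 0, 0))

    def test_inconsistent_aspect(self):
        with pytest.raises(ValueError):
            BerryGeometry((0, 0), (2.0, 1.0, 1.0), 1.5, (1, 0, 0))

    def test_bad_count_range(self):
        with pytest.raises(ValueError):
            SceneParams(count_range=(0, 3))

    def test_negative_labels_rejected(self):
        from berryfuse.synthetic_scenes import TraitLabels

        with pytest.raises(ValueError):
            TraitLabels(weight_g=-1.0, uniformity_cv=0.0, count=1)
        with pytest.raises(ValueError):
            TraitLabels(weight_g=1.0, uniformity_cv=5.0, count=1)
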