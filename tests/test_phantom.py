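"""Phantom geometry, ray-cast rendering, RGB ground truth and datasets."""

import numpy as np
import pytest

from conftest import dense_first_hit
from woundkit.geometry import default_camera
from woundkit.phantom import (DEFAULT_NOISE_SD, PhantomSpec, TissueLayout,
                              default_invitro_grid, default_rgb_camera,
                              generate_dataset, make_cavity_scene,
                              make_skin_scene, render_lidar, render_rgb,
                              split_sizes, sweep_invitro)


class TestCavityGeometry:
    def test_vertical_walls_full_floor(self):
        spec = PhantomSpec(aperture=(40, 40), true_depth=10,
                           edge_angle_deg=90)
        assert spec.floor_width == (40.0, 40.0)
        sc = make_cavity_scene(spec)
        # floor exactly 10 mm below skin
        assert np.isclose(float(sc.height_field(0.0, 0.0)), 10.0)
        assert float(sc.height_field(25.0, 0.0)) == 0.0

    def test_walls_meeting_in_v(self):
        # 20 - 2 * 10 / tan(45 deg) = 0: the walls meet exactly
        spec = PhantomSpec(aperture=(20, 20), true_depth=10,
                           edge_angle_deg=45)
        assert spec.floor_width == (0.0, 0.0)
        sc = make_cavity_scene(spec)
        assert np.isclose(float(sc.height_field(0.0, 0.0)), 10.0, atol=1e-9)

    def test_bump_mirrors_cavity(self):
        spec = PhantomSpec(aperture=(30, 30), true_depth=-4,
                           edge_angle_deg=60)
        sc = make_cavity_scene(spec)
        u = np.linspace(-20, 20, 201)
        h = sc.height_field(u, np.zeros_like(u))
        assert np.isclose(h.min(), -4.0)     # 4 mm above the skin plane
        assert h.max() == 0.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(aperture=(0, 40))
        with pytest.raises(ValueError):
            PhantomSpec(edge_angle_deg=0)
        with pytest.raises(ValueError):
            PhantomSpec(noise_sd=-1)


class TestRenderLidar:
    def test_flat_scene_exact_plane_ranges(self, sensor_cam):
        sc = make_skin_scene(PhantomSpec(noise_sd=0))
        dm = render_lidar(sc, sensor_cam)
        exact = 350.0 * sensor_cam.ray_scale()
        assert np.abs(dm.values - exact).max() < 1e-9

    def test_seeded_determinism(self, sensor_cam):
        sc = make_cavity_scene(PhantomSpec(noise_sd=1.0, seed=42))
        a = render_lidar(sc, sensor_cam)
        b = render_lidar(sc, sensor_cam)
        assert np.array_equal(a.values, b.values)
        c = render_lidar(sc, sensor_cam, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_cavity_deepens_and_bump_shortens_ranges(self, sensor_cam):
        flat = render_lidar(make_skin_scene(PhantomSpec(noise_sd=0)),
                            sensor_cam).values
        cav = render_lidar(make_cavity_scene(
            PhantomSpec(true_depth=10, noise_sd=0)), sensor_cam).values
        bump = render_lidar(make_cavity_scene(
            PhantomSpec(true_depth=-5, noise_sd=0)), sensor_cam).values
        assert (cav >= flat - 1e-9).all()
        assert cav[96, 128] > flat[96, 128] + 9      # ~10 mm deeper on-axis
        assert (bump <= flat + 1e-9).all()
        assert bump[96, 128] < flat[96, 128] - 4     # ~5 mm closer on-axis

    @pytest.mark.parametrize("spec", [
        PhantomSpec(aperture=(40, 40), true_depth=10, edge_angle_deg=90),
        PhantomSpec(aperture=(30, 30), true_depth=15, edge_angle_deg=60),
        PhantomSpec(aperture=(12, 12), true_depth=35, edge_angle_deg=80),
        PhantomSpec(aperture=(35, 25), true_depth=8, edge_angle_deg=50,
                    shape="elliptical"),
        PhantomSpec(aperture=(30, 30), true_depth=-6, edge_angle_deg=70,
                    skin_tilt_deg=10),
    ], ids=["vertical", "sloped", "deep-narrow", "ellipse", "tilted-bump"])
    def test_first_hit_matches_dense_oracle(self, spec, sensor_cam):
        """Analytic ray casting vs independent dense-sampling + bisection
        along a horizontal scan line through the wound, within 0.05 mm."""
        sc = make_cavity_scene(spec)
        ranges, _, _ = sc.ray_cast(sensor_cam)
        row = 95
        for col in range(90, 166, 5):
            oracle = dense_first_hit(sc, sensor_cam, row, col)
            assert abs(ranges[row, col] - oracle) < 0.05, (
                f"col {col}: cast {ranges[row, col]:.4f} vs "
                f"oracle {oracle:.4f}")

    def test_occluded_deep_narrow_floor(self, sensor_cam):
        """Steep, narrow cavity: part of the floor is invisible, so the
        deepest observed point is shallower than the spec depth."""
        sc = make_cavity_scene(PhantomSpec(aperture=(12, 12), true_depth=35,
                                           edge_angle_deg=80, noise_sd=0))
        ranges, mask, _ = sc.ray_cast(sensor_cam)
        exact_skin = 350.0 * sensor_cam.ray_scale()
        extra = (ranges - exact_skin)[mask]
        assert extra.max() < 35.0

    def test_occlusion_monotone_in_edge_angle(self, sensor_cam):
        """Visible cavity maximum depth never grows as walls get shallower."""
        maxima = []
        for ang in (80, 60, 50, 45, 40):
            sc = make_cavity_scene(PhantomSpec(aperture=(30, 30),
                                               true_depth=20,
                                               edge_angle_deg=ang,
                                               noise_sd=0))
            ranges, mask, _ = sc.ray_cast(sensor_cam)
            exact = 350.0 * sensor_cam.ray_scale()
            maxima.append((ranges - exact)[mask].max())
        assert all(a >= b - 1e-9 for a, b in zip(maxima, maxima[1:]))


class TestRenderRgb:
    def test_tissue_fractions_hit_targets(self):
        sc = make_cavity_scene(
            PhantomSpec(seed=5),
            TissueLayout(slough_fraction=0.5, necrosis_fraction=0.0, seed=5))
        _, mask, tmap = render_rgb(sc)
        frac = (tmap.labels == 1).sum() / mask.sum()
        assert abs(frac - 0.5) < 0.05
        assert (tmap.labels == 2).sum() == 0

    def test_zero_layout_has_no_tissue(self):
        sc = make_cavity_scene(PhantomSpec(seed=2), TissueLayout(0, 0, seed=2))
        _, _, tmap = render_rgb(sc)
        assert not np.isin(tmap.labels, [1, 2]).any()

    def test_seeds_vary_geometry_not_aggregates(self):
        fracs, first = [], None
        for seed in range(6):
            sc = make_cavity_scene(
                PhantomSpec(seed=seed),
                TissueLayout(slough_fraction=0.4, necrosis_fraction=0.2,
                             seed=seed))
            _, mask, tmap = render_rgb(sc)
            fracs.append(((tmap.labels == 1).sum() / mask.sum(),
                          (tmap.labels == 2).sum() / mask.sum()))
            if first is None:
                first = tmap.labels
            elif seed == 1:
                assert not np.array_equal(first, tmap.labels)
        fr = np.array(fracs)
        assert np.abs(fr[:, 0] - 0.4).max() < 0.05
        assert np.abs(fr[:, 1] - 0.2).max() < 0.05

    def test_labels_confined_to_mask(self):
        sc = make_cavity_scene(PhantomSpec(seed=3),
                               TissueLayout(0.6, 0.3, seed=3))
        _, mask, tmap = render_rgb(sc)
        assert not np.isin(tmap.labels[~mask], [1, 2]).any()

    def test_class_colours_are_separated(self):
        """Mean colours of rendered classes stay distinguishable."""
        sc = make_cavity_scene(PhantomSpec(seed=9),
                               TissueLayout(0.4, 0.2, seed=9))
        rgb, mask, tmap = render_rgb(sc)
        means = {}
        means["skin"] = rgb[~mask].mean(axis=0)
        means["gran"] = rgb[mask & (tmap.labels == 0)].mean(axis=0)
        means["slough"] = rgb[tmap.labels == 1].mean(axis=0)
        means["nec"] = rgb[tmap.labels == 2].mean(axis=0)
        names = list(means)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert np.linalg.norm(means[a] - means[b]) > 40


class TestDataset:
    def test_split_proportions(self):
        assert split_sizes(100) == (70, 20, 10)
        assert split_sizes(10) == (7, 2, 1)

    def test_generate_dataset_splits_disjoint_exhaustive(self):
        ds = generate_dataset(30, seed=3, image_size=64)
        idx = [set(ds.indices(s)) for s in ("train", "val", "test")]
        assert sum(len(s) for s in idx) == 30
        assert idx[0] | idx[1] | idx[2] == set(range(30))
        assert not (idx[0] & idx[1] or idx[0] & idx[2] or idx[1] & idx[2])

    def test_manifest_deterministic(self):
        a = generate_dataset(12, seed=7, image_size=64)
        b = generate_dataset(12, seed=7, image_size=64)
        assert a.manifest.equals(b.manifest)
        assert np.array_equal(a.images, b.images)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(9, seed=0)


class TestSweep:
    def test_row_count_matches_protocol(self):
        grid = default_invitro_grid()
        assert 40 <= len(grid) <= 80      # bench protocol scale (51 wounds)

    def test_noise_free_repeats_identical(self):
        df = sweep_invitro([10], [40], [80], repeats=2, seed=0, noise_sd=0.0)
        est = df["estimated_depth"].to_numpy()
        assert np.ptp(est) == 0.0

    def test_tidy_columns(self):
        df = sweep_invitro([5], [30], [90], repeats=2, seed=1)
        assert {"true_depth", "aperture", "edge_angle_deg", "repeat",
                "estimated_depth", "sentinel", "error"} <= set(df.columns)
        assert len(df) == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_invitro([35], [10], [40], min_floor_mm=4.0)
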