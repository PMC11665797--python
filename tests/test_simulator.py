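"""Synthetic scene generation: instrument building, pose sampling, rendering,
occluders, and dataset output."""

import json

import numpy as np
import pytest

from surgipose.geometry import project_points
from surgipose.simulator import (
    SceneConfig,
    add_occluder,
    build_instrument,
    default_intrinsics,
    generate_dataset,
    generate_sample,
    render_scene,
    sample_pose,
    tip_visibility,
)


class TestBuildInstrument:
    def test_diameter_matches_exhaustive_pairwise_oracle(self):
        model = build_instrument(80, 4, 0.0, 2000, 10)
        expected = np.sqrt(80**2 + 8**2)
        assert abs(model.diameter - expected) / expected < 0.01
        # exhaustive oracle on a subsample
        sub = model.surface_points[::5]
        d2 = np.sum((sub[:, None] - sub[None]) ** 2, axis=-1)
        assert model.diameter >= np.sqrt(d2.max()) - 1e-9

    def test_ten_distinct_keypoints(self, instrument):
        assert instrument.keypoints3d.shape == (10, 3)
        d = np.linalg.norm(
            instrument.keypoints3d[:, None] - instrument.keypoints3d[None], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1.0  # mm: FPS spreads keypoints far apart

    def test_keypoint_stability_across_density(self):
        # on a rotationally symmetric shaft the azimuth of an FPS pick is
        # degenerate, so stability is asserted along the axis: doubling the
        # surface density moves each keypoint's axial position by less than
        # half the radius
        a = build_instrument(80, 4, 12, 4000, 10)
        b = build_instrument(80, 4, 12, 8000, 10)
        dz = np.abs(a.keypoints3d[:, None, 2] - b.keypoints3d[None, :, 2])
        assert dz.min(axis=1).max() < 2.0

    def test_degenerate_dimensions_raise(self):
        with pytest.raises(ValueError):
            build_instrument(0, 4, 12, 1000, 10)
        with pytest.raises(ValueError):
            build_instrument(80, -1, 12, 1000, 10)


class TestSamplePose:
    def test_zero_width_ranges_fix_the_pose(self):
        cfg = SceneConfig(
            depth_range=(120, 120), tilt_range=(10, 10), roll_range=(45, 45),
            lateral_fraction=0.0,
        )
        rng = np.random.default_rng(0)
        a = sample_pose(cfg, rng)
        # spin is still free; depth and centre must be pinned
        centre = a.apply(np.array([0.0, 0.0, (80 + 12) / 2]))
        assert centre[2] == pytest.approx(120)
        assert abs(centre[0]) < 1e-9 and abs(centre[1]) < 1e-9

    def test_depths_respect_configured_range(self, scene_config):
        rng = np.random.default_rng(1)
        model_centre = np.array([0.0, 0.0, (80 + 12) / 2])
        for _ in range(200):
            pose = sample_pose(scene_config, rng)
            z = pose.apply(model_centre)[2]
            assert scene_config.depth_range[0] <= z <= scene_config.depth_range[1]

    def test_different_seeds_differ(self, scene_config):
        a = sample_pose(scene_config, np.random.default_rng(1))
        b = sample_pose(scene_config, np.random.default_rng(2))
        assert not np.allclose(a.as_matrix(), b.as_matrix())


class TestRenderScene:
    def test_sample_contract(self, sample, instrument, camera):
        assert sample.image.shape == (270, 480, 3) and sample.image.dtype == np.uint8
        assert sample.seg.shape == (270, 480)
        assert sample.vfield.shape == (10, 270, 480, 2)
        assert sample.seg.sum() > 0
        proj = project_points(instrument.keypoints3d, sample.pose, camera)
        assert np.allclose(
            sample.keypoints2d.xy[~proj.behind], proj.xy[~proj.behind], atol=1e-6
        )

    def test_light_scale_darkens_instrument(self, instrument, camera):
        samples = {}
        for light in (0.4, 1.0):
            cfg = SceneConfig(width=480, height=270, light_range=(light, light))
            rng = np.random.default_rng(7)
            pose = sample_pose(cfg, rng)
            samples[light] = render_scene(instrument, pose, camera, cfg, rng)
        lo = samples[0.4].image[samples[0.4].seg > 0].mean()
        hi = samples[1.0].image[samples[1.0].seg > 0].mean()
        assert lo < hi

    def test_same_seed_identical_sample(self, instrument, scene_config):
        a = generate_sample(instrument, scene_config, np.random.default_rng(9), 0)
        b = generate_sample(instrument, scene_config, np.random.default_rng(9), 0)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.seg, b.seg)
        assert np.array_equal(a.vfield, b.vfield)
        assert np.allclose(a.pose.as_matrix(), b.pose.as_matrix())


class TestAddOccluder:
    def test_zero_coverage_unchanged(self, sample):
        out = add_occluder(sample, "disk", 0.0, np.random.default_rng(0))
        assert np.array_equal(out.image, sample.image)
        assert np.array_equal(out.seg, sample.seg)

    @pytest.mark.parametrize("shape", ["disk", "bar", "polygon"])
    def test_coverage_close_to_target(self, sample, shape):
        out = add_occluder(sample, shape, 0.4, np.random.default_rng(1))
        remaining = out.seg.sum() / sample.seg.sum()
        assert abs(remaining - 0.6) < 0.02

    def test_pose_and_keypoints_unchanged(self, sample):
        out = add_occluder(sample, "disk", 0.4, np.random.default_rng(2))
        assert np.allclose(out.pose.as_matrix(), sample.pose.as_matrix())
        assert np.allclose(out.keypoints2d.xy, sample.keypoints2d.xy, equal_nan=True)

    def test_tip_visibility_monotone_in_coverage(self, sample, instrument):
        vis = []
        for cov in (0.0, 0.3, 0.6):
            out = add_occluder(sample, "disk", cov, np.random.default_rng(5))
            vis.append(tip_visibility(out, instrument))
        assert vis[0] >= vis[1] >= vis[2]


class TestGenerateDataset:
    def test_layout_manifest_and_determinism(self, tmp_path, toy_instrument):
        cfg = SceneConfig(
            width=96, height=96, surface_density=3000, n_frames=6, seed=3,
            visibility_threshold=0.0,
        )
        s1 = generate_dataset(cfg, tmp_path / "a", model=toy_instrument)
        s2 = generate_dataset(cfg, tmp_path / "b", model=toy_instrument)
        assert s1["retained"] == 6 and s1["excluded"] == 0
        m1 = (tmp_path / "a" / "manifest.jsonl").read_text()
        m2 = (tmp_path / "b" / "manifest.jsonl").read_text()
        assert m1 == m2
        rec = json.loads(m1.splitlines()[0])
        for key in ("image", "mask", "vfield", "pose"):
            assert (tmp_path / "a" / rec[key]).exists()
        assert (tmp_path / "a" / "intrinsics.json").exists()
        assert (tmp_path / "a" / "model.ply").exists()

    def test_strict_threshold_excludes_occluded_frames(self, tmp_path, toy_instrument):
        base = dict(width=96, height=96, surface_density=3000, n_frames=8, seed=4,
                    occluders=("disk",), occluder_coverage=(0.5, 0.7))
        lax = generate_dataset(
            SceneConfig(**base, visibility_threshold=0.0), tmp_path / "lax",
            model=toy_instrument,
        )
        strict = generate_dataset(
            SceneConfig(**base, visibility_threshold=0.9), tmp_path / "strict",
            model=toy_instrument,
        )
        assert lax["excluded"] == 0
        assert strict["excluded"] >= lax["excluded"]

    def test_dataset_roundtrip_through_loader(self, tmp_path, toy_instrument):
        from surgipose.dataset_io import load_dataset_samples

        cfg = SceneConfig(
            width=96, height=96, surface_density=3000, n_frames=3, seed=5,
            visibility_threshold=0.0,
        )
        generate_dataset(cfg, tmp_path / "ds", model=toy_instrument)
        samples = list(load_dataset_samples(tmp_path / "ds"))
        assert len(samples) == 3
        s = samples[0]
        assert s.image.shape == (96, 96, 3)
        assert s.vfield.shape == (10, 96, 96, 2)
        mask = s.seg > 0
        norms = np.linalg.norm(s.vfield[:, mask], axis=-1)
        assert np.allclose(norms[norms > 0], 1.0, atol=1e-6)


class TestClosedLoop:
    def test_noise_free_pipeline_recovers_stored_pose(self, instrument, scene_config, camera):
        # render -> vote -> PnP must close to well under a tenth of a degree
        from surgipose.metrics import add_metric, translation_rotation_error
        from surgipose.pose_solver import RansacPnPConfig, solve_pnp
        from surgipose.voting import VotingConfig, localize_keypoints

        for seed in (11, 23):
            s = generate_sample(instrument, scene_config, np.random.default_rng(seed), 0)
            res = localize_keypoints(s.seg, s.vfield, VotingConfig(seed=1))
            est = solve_pnp(
                res.keypoints, instrument.keypoints3d, camera, RansacPnPConfig(seed=2)
            )
            t_err, r_err = translation_rotation_error(est.transform, s.pose)
            assert r_err < 0.1 and t_err < 0.1
            assert add_metric(est.transform, s.pose, instrument.surface_points) < 0.1
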