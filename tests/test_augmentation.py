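"""Regular and mask-based occlusion augmentation."""

import numpy as np
import pytest
from scipy.stats import binom

from surgipose.augmentation import (
    AugmentationConfig,
    JitterConfig,
    augment_sample,
    blackout_background,
    grid_occlude,
    instrument_bbox,
    regular_augment,
)
from surgipose.simulator import SceneConfig, generate_sample


@pytest.fixture(scope="module")
def small_sample(toy_instrument, toy_scene_config):
    return generate_sample(toy_instrument, toy_scene_config, np.random.default_rng(7), 0)


def zero_jitter() -> JitterConfig:
    return JitterConfig(
        translation_px=0, rotation_deg=0, scale_range=(1.0, 1.0), colour_range=(1.0, 1.0)
    )


class TestInstrumentBbox:
    def test_single_pixel(self):
        seg = np.zeros((10, 10), dtype=np.uint8)
        seg[3, 7] = 1  # row 3, col 7
        assert instrument_bbox(seg) == (7, 3, 7, 3)

    def test_full_frame(self):
        seg = np.ones((6, 9), dtype=np.uint8)
        assert instrument_bbox(seg) == (0, 0, 8, 5)

    def test_two_extreme_pixels(self):
        seg = np.zeros((12, 12), dtype=np.uint8)
        seg[2, 2] = seg[5, 10] = 1
        assert instrument_bbox(seg) == (2, 2, 10, 5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            instrument_bbox(np.zeros((4, 4), dtype=np.uint8))


class TestRegularAugment:
    def test_zero_jitter_is_identity(self, small_sample):
        cfg = AugmentationConfig(jitter=zero_jitter())
        out = regular_augment(small_sample, cfg, np.random.default_rng(0))
        assert np.array_equal(out.image, small_sample.image)
        assert np.array_equal(out.seg, small_sample.seg)
        assert np.array_equal(out.vfield, small_sample.vfield)

    def test_pure_translation_shifts_keypoints_only(self, small_sample):
        cfg = AugmentationConfig(
            jitter=JitterConfig(
                translation_px=6, rotation_deg=0, scale_range=(1, 1), colour_range=(1, 1)
            )
        )
        out = regular_augment(small_sample, cfg, np.random.default_rng(3))
        ra = out.meta["regular_augment"]
        dx, dy = int(ra["dx"]), int(ra["dy"])
        assert (dx, dy) != (0, 0)
        shift = out.keypoints2d.xy - small_sample.keypoints2d.xy
        assert np.allclose(shift[:, 0], dx) and np.allclose(shift[:, 1], dy)
        # vector directions at shifted pixels are exactly preserved
        rows, cols = np.nonzero(small_sample.seg)
        keep = (
            (rows + dy >= 0) & (rows + dy < out.seg.shape[0])
            & (cols + dx >= 0) & (cols + dx < out.seg.shape[1])
        )
        src = small_sample.vfield[:, rows[keep], cols[keep]]
        moved = out.vfield[:, rows[keep] + dy, cols[keep] + dx]
        assert np.allclose(moved, src, atol=1e-6)

    def test_rotation_rotates_vector_directions(self, small_sample):
        cfg = AugmentationConfig(
            jitter=JitterConfig(
                translation_px=0, rotation_deg=90, scale_range=(1, 1), colour_range=(1, 1)
            )
        )
        rng = np.random.default_rng(11)
        out = regular_augment(small_sample, cfg, rng)
        ang = out.meta["regular_augment"]["angle_rad"]
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        # every unit vector of the output field equals some input direction
        # rotated by the drawn angle: check against the keypoint geometry
        rows, cols = np.nonzero(out.seg)
        i = 0
        px = np.stack([cols, rows], axis=1).astype(float)
        d = out.keypoints2d.xy[i] - px
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(out.vfield[i, rows, cols], d, atol=1e-5)
        # and the keypoints themselves moved by the rotation matrix
        h, w = small_sample.seg.shape
        centre = np.array([(w - 1) / 2, (h - 1) / 2])
        expected = (small_sample.keypoints2d.xy - centre) @ R.T + centre
        assert np.allclose(out.keypoints2d.xy, expected, atol=1e-9)

    def test_label_consistency_after_augment(self, small_sample):
        cfg = AugmentationConfig()
        out = regular_augment(small_sample, cfg, np.random.default_rng(5))
        mask = out.seg > 0
        norms = np.linalg.norm(out.vfield[:, mask], axis=-1)
        assert np.allclose(norms[norms > 0], 1.0, atol=1e-6)
        assert not out.vfield[:, ~mask].any()


class TestGridOcclude:
    def test_zero_probability_is_identity(self, small_sample):
        bbox = instrument_bbox(small_sample.seg)
        out = grid_occlude(small_sample, bbox, 0.0, 0.4, 8, np.random.default_rng(0))
        assert np.array_equal(out.image, small_sample.image)
        assert np.array_equal(out.seg, small_sample.seg)

    def test_saturation_removes_all_bbox_instrument(self, small_sample):
        bbox = instrument_bbox(small_sample.seg)
        out = grid_occlude(small_sample, bbox, 1.0, 1.0, 8, np.random.default_rng(0))
        x0, y0, x1, y1 = bbox
        assert out.seg[y0 : y1 + 1, x0 : x1 + 1].sum() == 0
        assert out.meta["grid_occlude"]["cells_noise"] == out.meta["grid_occlude"]["cells_replaced"]

    def test_unreplaced_pixels_bit_identical(self, small_sample):
        bbox = instrument_bbox(small_sample.seg)
        out = grid_occlude(small_sample, bbox, 0.35, 0.4, 8, np.random.default_rng(1))
        unchanged = out.seg.astype(bool) & small_sample.seg.astype(bool)
        assert np.array_equal(out.image[unchanged], small_sample.image[unchanged])

    def test_replacement_statistics_match_binomial(self, small_sample):
        # 1000 seeded draws at p = 0.3 on an 8x8 grid; replaced-cell fraction
        # within the 99% binomial band, noise share within its 99% band at 0.4
        bbox = instrument_bbox(small_sample.seg)
        rng = np.random.default_rng(42)
        replaced = noise = total = 0
        for _ in range(1000):
            out = grid_occlude(small_sample, bbox, 0.3, 0.4, 8, rng)
            g = out.meta["grid_occlude"]
            replaced += g["cells_replaced"]
            noise += g["cells_noise"]
            total += g["cells_total"]
        lo, hi = binom.ppf([0.005, 0.995], total, 0.3)
        assert lo <= replaced <= hi
        lo, hi = binom.ppf([0.005, 0.995], replaced, 0.4)
        assert lo <= noise <= hi

    def test_labels_erased_in_replaced_cells(self, small_sample):
        bbox = instrument_bbox(small_sample.seg)
        out = grid_occlude(small_sample, bbox, 0.5, 0.5, 8, np.random.default_rng(2))
        removed = small_sample.seg.astype(bool) & ~out.seg.astype(bool)
        assert removed.any()
        assert not out.vfield[:, removed].any()


class TestBlackout:
    def test_full_image_bbox_unchanged(self, small_sample):
        h, w = small_sample.seg.shape
        out = blackout_background(small_sample, (0, 0, w - 1, h - 1))
        assert np.array_equal(out.image, small_sample.image)

    def test_outside_bbox_zeroed_labels_kept(self, small_sample):
        bbox = instrument_bbox(small_sample.seg)
        out = blackout_background(small_sample, bbox)
        x0, y0, x1, y1 = bbox
        mask = np.ones(small_sample.seg.shape, dtype=bool)
        mask[y0 : y1 + 1, x0 : x1 + 1] = False
        assert not out.image[mask].any()
        assert np.array_equal(out.seg, small_sample.seg)
        assert np.array_equal(out.vfield, small_sample.vfield)


class TestAugmentSample:
    def test_all_zero_probabilities_identity(self, small_sample):
        cfg = AugmentationConfig(
            p_occlusion_range=(0.0, 0.0), p_apply_occlusion=0.0, p_blackout=0.0,
            jitter=zero_jitter(),
        )
        out = augment_sample(small_sample, cfg, np.random.default_rng(0))
        assert np.array_equal(out.image, small_sample.image)
        assert np.array_equal(out.seg, small_sample.seg)

    def test_fixed_seed_bit_identical(self, small_sample):
        cfg = AugmentationConfig()
        a = augment_sample(small_sample, cfg, np.random.default_rng(33))
        b = augment_sample(small_sample, cfg, np.random.default_rng(33))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.seg, b.seg)
        assert np.array_equal(a.vfield, b.vfield)

    def test_apply_rates_match_configured_probabilities(self, small_sample):
        # 2000 seeded samples: occlusion ~0.6 and blackout ~0.2 within their
        # 99% binomial bands (the full 10k-draw check runs in acceptance)
        cfg = AugmentationConfig(jitter=zero_jitter())
        rng = np.random.default_rng(8)
        occ = blk = 0
        n = 2000
        for _ in range(n):
            out = augment_sample(small_sample, cfg, rng)
            occ += out.meta["augment"]["occlusion_applied"]
            blk += out.meta["augment"]["blackout_applied"]
        lo, hi = binom.ppf([0.005, 0.995], n, 0.6)
        assert lo <= occ <= hi
        lo, hi = binom.ppf([0.005, 0.995], n, 0.2)
        assert lo <= blk <= hi

    def test_label_consistency_preserved(self, small_sample):
        cfg = AugmentationConfig()
        rng = np.random.default_rng(13)
        for _ in range(5):
            out = augment_sample(small_sample, cfg, rng)
            mask = out.seg > 0
            norms = np.linalg.norm(out.vfield[:, mask], axis=-1)
            assert np.allclose(norms[norms > 0], 1.0, atol=1e-6)
            assert not out.vfield[:, ~mask].any()

    def test_end_to_end_pose_recovery_after_occlusion(self, sample, instrument, camera):
        # voting + PnP on the remaining instrument pixels of an occluded
        # sample recovers the pose at noise-free accuracy (rigid-body core)
        from surgipose.metrics import add_metric
        from surgipose.pose_solver import RansacPnPConfig, solve_pnp
        from surgipose.voting import VotingConfig, localize_keypoints

        bbox = instrument_bbox(sample.seg)
        out = grid_occlude(sample, bbox, 0.4, 0.4, 8, np.random.default_rng(21))
        res = localize_keypoints(out.seg, out.vfield, VotingConfig(seed=2))
        est = solve_pnp(
            res.keypoints, instrument.keypoints3d, camera, RansacPnPConfig(seed=3)
        )
        assert add_metric(est.transform, sample.pose, instrument.surface_points) < 0.5
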