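"""Occlusion-robust data augmentation.

Two stages. Regular augmentation applies one planar similarity transform
(translation, rotation, scale) to the image, mask, vector field and 2D
keypoints in tandem, plus colour jitter on the image alone. Mask-based
occlusion augmentation then covers the instrument's bounding box with a grid
and replaces random cells with either uniform pixel noise or an image patch
shifted in from an instrument-free region; with a further probability the
whole background outside the bounding box is blacked out.

The defining property of the masking stage is that it edits the labels too:
a replaced cell becomes background in the segmentation and vector-field
ground truth, so the model is trained to treat occluded pixels as
irrelevant rather than to hallucinate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import SimilarityTransform, warp

from .labels import Keypoints2D, render_vector_field
from .simulator import Sample

__all__ = [
    "JitterConfig",
    "AugmentationConfig",
    "regular_augment",
    "instrument_bbox",
    "grid_occlude",
    "blackout_background",
    "augment_sample",
]


@dataclass(frozen=True)
class JitterConfig:
    """Ranges of the regular augmentations. Translation in px, rotation in
    degrees, scale and colour as multiplicative factor ranges."""

    translation_px: float = 20.0
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    colour_range: tuple[float, float] = (0.7, 1.3)

    @property
    def is_identity(self) -> bool:
        return (
            self.translation_px == 0
            and self.rotation_deg == 0
            and self.scale_range == (1.0, 1.0)
            and self.colour_range == (1.0, 1.0)
        )


@dataclass(frozen=True)
class AugmentationConfig:
    """Occlusion-augmentation parameters.

    Defaults are the training conditions of the method: grid-replacement
    probability drawn from [0.15, 0.5], 40% of replaced cells noise patches,
    occlusion applied to 60% of samples and background blackout to 20%.
    """

    p_occlusion_range: tuple[float, float] = (0.15, 0.5)
    noise_fraction: float = 0.4
    p_apply_occlusion: float = 0.6
    p_blackout: float = 0.2
    grid_count: int = 8
    jitter: JitterConfig = field(default_factory=JitterConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.p_occlusion_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("p_occlusion_range must be within [0, 1]")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must be within [0, 1]")
        if self.grid_count < 1:
            raise ValueError("grid_count must be >= 1")


def instrument_bbox(seg: np.ndarray) -> tuple[int, int, int, int]:
    """Tightest axis-aligned rectangle (x0, y0, x1, y1), inclusive, around
    the instrument pixels."""
    rows, cols = np.nonzero(seg)
    if len(rows) == 0:
        raise ValueError("empty segmentation has no bounding box")
    return int(cols.min()), int(rows.min()), int(cols.max()), int(rows.max())


def _colour_jitter(img: np.ndarray, rng: np.random.Generator, rng_range) -> np.ndarray:
    out = img.astype(float)
    brightness = rng.uniform(*rng_range)
    contrast = rng.uniform(*rng_range)
    saturation = rng.uniform(*rng_range)
    out = out * brightness
    mean = out.mean()
    out = (out - mean) * contrast + mean
    grey = out.mean(axis=2, keepdims=True)
    out = grey + (out - grey) * saturation
    return np.clip(out, 0, 255).astype(np.uint8)


def regular_augment(
    sample: Sample, config: AugmentationConfig, rng: np.random.Generator
) -> Sample:
    """One planar similarity transform applied consistently to the whole
    sample, plus colour jitter on the image only.

    The vector field is re-rendered from the transformed keypoints and the
    warped mask — for a similarity transform this equals rotating the stored
    directions, but stays exactly unit-norm. If the transform pushes the
    instrument fully out of frame the draw is retried a bounded number of
    times, after which the sample is returned unaugmented with a
    ``skip_augment`` flag in the meta.
    """
    jit = config.jitter
    if jit.is_identity:
        return sample

    h, w = sample.seg.shape
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    for _ in range(10):
        angle = np.radians(rng.uniform(-jit.rotation_deg, jit.rotation_deg))
        scale = rng.uniform(*jit.scale_range)
        dx = rng.uniform(-jit.translation_px, jit.translation_px)
        dy = rng.uniform(-jit.translation_px, jit.translation_px)
        if angle == 0 and scale == 1.0:
            # a pure translation of the pixel grid is exact only for integer
            # shifts; round so image, labels and keypoints stay consistent
            dx, dy = float(round(dx)), float(round(dy))
        # rotate+scale about the image centre, then translate
        tf = (
            SimilarityTransform(translation=-centre)
            + SimilarityTransform(rotation=angle, scale=scale)
            + SimilarityTransform(translation=centre + [dx, dy])
        )
        if angle == 0 and scale == 1.0:
            seg_w = _translate_nn(sample.seg, dx, dy) if (dx or dy) else sample.seg.copy()
            img_w = (
                _translate_nn(sample.image, dx, dy) if (dx or dy) else sample.image.copy()
            )
        else:
            inv = tf.inverse
            img_w = warp(
                sample.image, inv, order=1, preserve_range=True, output_shape=(h, w)
            ).astype(np.uint8)
            seg_w = (
                warp(sample.seg, inv, order=0, preserve_range=True, output_shape=(h, w))
                > 0.5
            ).astype(np.uint8)
        if seg_w.any():
            break
    else:
        out = replace(sample, meta={**sample.meta, "skip_augment": True})
        return out

    kp_xy = tf(np.asarray(sample.keypoints2d.xy, dtype=float))
    visible = (
        np.isfinite(kp_xy).all(axis=1)
        & (kp_xy[:, 0] >= -0.5)
        & (kp_xy[:, 0] <= w - 0.5)
        & (kp_xy[:, 1] >= -0.5)
        & (kp_xy[:, 1] <= h - 0.5)
    )
    kp = Keypoints2D(xy=kp_xy, visible=visible)
    vfield = render_vector_field(kp, seg_w)
    img_w = _colour_jitter(img_w, rng, jit.colour_range)
    return replace(
        sample,
        image=img_w,
        seg=seg_w,
        vfield=vfield,
        keypoints2d=kp,
        meta={**sample.meta, "regular_augment": {"angle_rad": float(angle),
                                                 "scale": float(scale),
                                                 "dx": float(dx), "dy": float(dy)}},
    )


def _translate_nn(arr: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Integer-rounded translation; exact for the pure-translation case."""
    out = np.zeros_like(arr)
    idx, idy = int(round(dx)), int(round(dy))
    h, w = arr.shape[:2]
    ys = slice(max(idy, 0), min(h + idy, h))
    xs = slice(max(idx, 0), min(w + idx, w))
    ys_src = slice(max(-idy, 0), min(h - idy, h))
    xs_src = slice(max(-idx, 0), min(w - idx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def _cell_edges(lo: int, hi: int, count: int) -> np.ndarray:
    return np.unique(np.linspace(lo, hi + 1, count + 1).round().astype(int))


def grid_occlude(
    sample: Sample,
    bbox: tuple[int, int, int, int],
    p_occlusion: float,
    noise_fraction: float,
    grid_count: int,
    rng: np.random.Generator,
) -> Sample:
    """Replace random grid cells of the instrument bounding box.

    Each of the ``grid_count`` x ``grid_count`` cells is independently
    replaced with probability ``p_occlusion``; a replaced cell becomes either
    uniform per-channel noise in [0, 255] (with probability
    ``noise_fraction``) or a same-size image patch copied from a region fully
    outside the bounding box containing no instrument pixels. Replaced cells
    are erased from the segmentation and vector-field labels. Untouched
    pixels are bit-identical to the input.
    """
    if not 0 <= p_occlusion <= 1:
        raise ValueError("p_occlusion must be in [0, 1]")
    x0, y0, x1, y1 = bbox
    h, w = sample.seg.shape
    if not (0 <= x0 <= x1 < w and 0 <= y0 <= y1 < h):
        raise ValueError("bounding box outside the image")
    out = replace(
        sample,
        image=sample.image.copy(),
        seg=sample.seg.copy(),
        vfield=sample.vfield.copy(),
        meta=dict(sample.meta),
    )
    xs = _cell_edges(x0, x1, grid_count)
    ys = _cell_edges(y0, y1, grid_count)
    cells_total = (len(xs) - 1) * (len(ys) - 1)
    replaced = 0
    noisy = 0
    fallbacks = 0
    for yi in range(len(ys) - 1):
        for xi in range(len(xs) - 1):
            if rng.random() >= p_occlusion:
                continue
            replaced += 1
            ca, cb = ys[yi], ys[yi + 1]
            cc, cd = xs[xi], xs[xi + 1]
            ch, cw = cb - ca, cd - cc
            use_noise = rng.random() < noise_fraction
            if use_noise:
                noisy += 1
                patch = rng.integers(0, 256, size=(ch, cw, 3), dtype=np.uint8)
            else:
                patch = _donor_patch(sample, bbox, ch, cw, rng)
                if patch is None:
                    fallbacks += 1
                    patch = rng.integers(0, 256, size=(ch, cw, 3), dtype=np.uint8)
            out.image[ca:cb, cc:cd] = patch
            out.seg[ca:cb, cc:cd] = 0
            out.vfield[:, ca:cb, cc:cd] = 0.0
    out.meta["grid_occlude"] = {
        "p_occlusion": float(p_occlusion),
        "cells_total": cells_total,
        "cells_replaced": replaced,
        "cells_noise": noisy,
        "donor_fallbacks": fallbacks,
    }
    return out


def _donor_patch(
    sample: Sample, bbox: tuple[int, int, int, int], ch: int, cw: int,
    rng: np.random.Generator, attempts: int = 50,
) -> np.ndarray | None:
    """Rejection-sample a same-size window fully outside the bounding box
    with no instrument pixels; None if no donor found."""
    x0, y0, x1, y1 = bbox
    h, w = sample.seg.shape
    if ch > h or cw > w:
        return None
    for _ in range(attempts):
        ty = int(rng.integers(0, h - ch + 1))
        tx = int(rng.integers(0, w - cw + 1))
        if not (tx + cw - 1 < x0 or tx > x1 or ty + ch - 1 < y0 or ty > y1):
            continue  # intersects the bbox
        if sample.seg[ty : ty + ch, tx : tx + cw].any():
            continue
        return sample.image[ty : ty + ch, tx : tx + cw].copy()
    return None


def blackout_background(sample: Sample, bbox: tuple[int, int, int, int]) -> Sample:
    """Zero every image pixel outside the bounding box; labels untouched
    (background labels are already zero there)."""
    x0, y0, x1, y1 = bbox
    out = replace(sample, image=sample.image.copy(), meta=dict(sample.meta))
    mask = np.ones(sample.seg.shape, dtype=bool)
    mask[y0 : y1 + 1, x0 : x1 + 1] = False
    out.image[mask] = 0
    out.meta["blackout"] = True
    return out


def augment_sample(
    sample: Sample, config: AugmentationConfig, rng: np.random.Generator
) -> Sample:
    """The full augmentation pipeline for one training sample.

    Regular augmentation always runs; grid occlusion with probability
    ``p_apply_occlusion`` (its ``p_occlusion`` drawn uniformly from
    ``p_occlusion_range``); background blackout with probability
    ``p_blackout``. Deterministic given the generator state; the meta
    records what was applied.
    """
    out = regular_augment(sample, config, rng)
    apply_occ = rng.random() < config.p_apply_occlusion
    apply_blackout = rng.random() < config.p_blackout
    p_occ = rng.uniform(*config.p_occlusion_range)
    bbox = instrument_bbox(out.seg) if out.seg.any() else None
    if apply_occ and bbox is not None:
        out = grid_occlude(
            out, bbox, p_occ, config.noise_fraction, config.grid_count, rng
        )
    if apply_blackout and bbox is not None:
        out = blackout_background(out, bbox)
    out.meta["augment"] = {
        "occlusion_applied": bool(apply_occ),
        "blackout_applied": bool(apply_blackout),
        "p_occlusion_drawn": float(p_occ),
    }
    return out
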