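"""Ground-truth label rendering: segmentation masks and unit-vector maps.

The keypoint representation is pixel-wise: every instrument pixel stores, for
each of the n keypoints, the 2D unit vector pointing from that pixel toward
the keypoint's (sub-pixel) image location. Because the instrument is rigid,
any subset of instrument pixels carries enough information to recover every
keypoint — including keypoints that project outside the image — which is what
makes the representation robust to partial visibility.

Array layouts:

* segmentation: ``(H, W)`` uint8 in {0, 1};
* vector field: ``(n, H, W, 2)`` float32, last axis is ``(dx, dy)`` in the
  package pixel convention (x = column, y = row); background pixels are zero.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image
from skimage.morphology import closing as _morph_closing, footprint_rectangle

from .geometry import CameraIntrinsics, InstrumentModel, RigidTransform, project_points

__all__ = [
    "Keypoints2D",
    "render_segmentation",
    "render_vector_field",
    "filter_vectors",
    "save_mask",
    "load_mask",
    "save_vector_field",
    "load_vector_field",
]


class Keypoints2D(NamedTuple):
    """n keypoints in continuous pixel coordinates with visibility flags.

    ``visible`` marks keypoints whose projection falls inside the image
    bounds; off-image keypoints keep valid coordinates and valid vector
    fields.
    """

    xy: np.ndarray  # (n, 2) float
    visible: np.ndarray  # (n,) bool


def render_segmentation(
    model: InstrumentModel,
    pose: RigidTransform,
    K: CameraIntrinsics,
    closing_size: int = 3,
) -> np.ndarray:
    """Binary instrument silhouette by projecting the dense surface cloud.

    Projected points are rasterised to their nearest pixel and the point
    splat is morphologically closed (default 3x3) to fill sampling gaps.
    Returns an (H, W) uint8 mask. An instrument fully behind the camera or
    fully outside the frame yields an all-zero mask with a warning.
    """
    proj = project_points(model.surface_points, pose, K)
    seg = np.zeros((K.height, K.width), dtype=np.uint8)
    ok = proj.in_bounds
    if not ok.any():
        warnings.warn("instrument projects entirely outside the image")
        return seg
    cols = np.rint(proj.xy[ok, 0]).astype(int).clip(0, K.width - 1)
    rows = np.rint(proj.xy[ok, 1]).astype(int).clip(0, K.height - 1)
    seg[rows, cols] = 1
    if closing_size > 1:
        closed = _morph_closing(
            seg.astype(bool), footprint_rectangle((closing_size, closing_size))
        )
        seg = closed.astype(np.uint8)
    return seg


def render_vector_field(keypoints2d: Keypoints2D, seg: np.ndarray) -> np.ndarray:
    """Per-keypoint unit-vector maps toward each keypoint.

    For each instrument pixel p and keypoint x, v = (x - p) / ||x - p||.
    Background pixels are zero; a pixel exactly coincident with a keypoint
    gets (0, 0) (the limiting direction is undefined) and is thereby excluded
    from voting.
    """
    seg = np.asarray(seg)
    h, w = seg.shape
    kp = np.asarray(keypoints2d.xy, dtype=np.float32)
    n = kp.shape[0]
    vfield = np.zeros((n, h, w, 2), dtype=np.float32)
    rows, cols = np.nonzero(seg)
    if len(rows) == 0:
        return vfield
    px = np.stack([cols, rows], axis=1).astype(np.float32)  # (m, 2) as (x, y)
    for i in range(n):
        d = kp[i] - px
        norm = np.linalg.norm(d, axis=1)
        nz = norm > 0
        d[nz] /= norm[nz, None]
        d[~nz] = 0.0
        vfield[i, rows, cols] = d
    return vfield


def filter_vectors(seg: np.ndarray, vfield: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict the vector field to the m instrument pixels.

    Returns ``(pixels, vectors)`` where ``pixels`` is (m, 2) float pixel
    coordinates (x, y) and ``vectors`` is (n, m, 2). This is the voting
    input: background pixels are masked out by the segmentation.
    """
    seg = np.asarray(seg)
    if vfield.shape[1:3] != seg.shape:
        raise ValueError("segmentation and vector field shapes disagree")
    rows, cols = np.nonzero(seg)
    if len(rows) == 0:
        warnings.warn("empty segmentation: no vectors retained")
    pixels = np.stack([cols, rows], axis=1).astype(np.float64)
    vectors = vfield[:, rows, cols, :].astype(np.float64)
    return pixels, vectors


# ---------------------------------------------------------------------------
# I/O: 8-bit PNG masks; raw float32 arrays with a JSON header
# ---------------------------------------------------------------------------


def save_mask(seg: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as single-channel PNG (0 background, 255 instrument)."""
    Image.fromarray((np.asarray(seg) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def save_vector_field(
    vfield: np.ndarray, path: str | Path, keypoint_names: list[str] | None = None
) -> None:
    """Raw little-endian float32 dump of shape [n, H, W, 2] plus JSON header."""
    path = Path(path)
    vf = np.ascontiguousarray(vfield, dtype="<f4")
    vf.tofile(path)
    n = vf.shape[0]
    header = {
        "shape": list(vf.shape),
        "dtype": "<f4",
        "layout": "[keypoint, row, col, (dx,dy)]",
        "keypoints": keypoint_names or [f"kp{i}" for i in range(n)],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))


def load_vector_field(path: str | Path) -> np.ndarray:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    vf = np.fromfile(path, dtype=header["dtype"])
    return vf.reshape(header["shape"])
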