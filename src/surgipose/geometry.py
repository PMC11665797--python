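"""Pinhole camera model, rigid transforms, and instrument-model geometry.

Conventions used throughout the package:

* Pixel coordinates are 0-based with pixel centres at integer coordinates;
  ``x`` is the column index and ``y`` the row index.
* All 3D quantities are in millimetres, so pose-distance metrics come out
  directly in mm.
* A pose is the rigid transform from the instrument frame to the camera
  frame; the camera looks down +z, so points in front of the camera have
  positive z.
* No lens distortion is modelled: the camera is described by the calibration
  matrix K alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

__all__ = [
    "CameraIntrinsics",
    "RigidTransform",
    "InstrumentModel",
    "Projection",
    "project_points",
    "fps_sample",
    "load_instrument_model",
    "save_instrument_model",
    "load_intrinsics",
    "save_intrinsics",
    "load_pose",
    "save_pose",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera calibration: focal lengths, principal point, image size.

    All quantities in pixels. ``as_matrix`` returns the upper-triangular 3x3
    calibration matrix K with unit bottom-right entry.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("image size must be at least 1x1")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform: 3x3 rotation plus translation in mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-7):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """The transform mapping x to a(b(x))."""
    R = a.rotation @ b.rotation
    # Re-orthonormalise via SVD so long chains cannot drift.
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    if np.linalg.det(R) < 0:  # pragma: no cover - inputs are proper rotations
        u[:, -1] *= -1
        R = u @ vt
    return RigidTransform(R, a.rotation @ b.translation + a.translation)


@dataclass(frozen=True)
class InstrumentModel:
    """A rigid instrument: dense surface point cloud plus n sparse 3D keypoints.

    ``diameter`` is the largest pairwise distance between surface points and
    is the natural length scale for the ADD metric.
    """

    surface_points: np.ndarray
    keypoints3d: np.ndarray
    name: str = "instrument"
    diameter: float = field(default=0.0)

    def __post_init__(self) -> None:
        sp = np.asarray(self.surface_points, dtype=float).reshape(-1, 3)
        kp = np.asarray(self.keypoints3d, dtype=float).reshape(-1, 3)
        if kp.shape[0] < 4:
            raise ValueError("need at least 4 keypoints for PnP solvability")
        lo = sp.min(axis=0) - 1.0
        hi = sp.max(axis=0) + 1.0
        if np.any(kp < lo) or np.any(kp > hi):
            raise ValueError("keypoints fall outside the surface bounding box")
        object.__setattr__(self, "surface_points", sp)
        object.__setattr__(self, "keypoints3d", kp)
        if self.diameter <= 0:
            object.__setattr__(self, "diameter", _cloud_diameter(sp))
        if self.diameter <= 0:
            raise ValueError("degenerate model: zero diameter")

    @property
    def n_keypoints(self) -> int:
        return int(self.keypoints3d.shape[0])


def _cloud_diameter(points: np.ndarray) -> float:
    """Largest pairwise distance; computed on the convex hull for speed."""
    if len(points) <= 2:
        if len(points) < 2:
            return 0.0
        return float(np.linalg.norm(points[0] - points[1]))
    try:
        hull = points[ConvexHull(points).vertices]
    except Exception:  # degenerate (coplanar/collinear) clouds
        hull = points
    if len(hull) > 2500:  # pragma: no cover - hulls of our clouds are small
        hull = hull[:: len(hull) // 2500 + 1]
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


class Projection(NamedTuple):
    """Result of projecting 3D points: continuous pixel coords, camera depth,
    and per-point flags for in-image-bounds and behind-camera."""

    xy: np.ndarray  # (N, 2) float, NaN where behind camera
    depth: np.ndarray  # (N,) camera-frame z in mm
    in_bounds: np.ndarray  # (N,) bool
    behind: np.ndarray  # (N,) bool, True where depth <= 0


def project_points(
    points3d: np.ndarray, pose: RigidTransform, K: CameraIntrinsics
) -> Projection:
    """Perspective-project instrument-frame points through K.

    The projection chain is x = K * T_cam_instrument * z with homogeneous
    normalisation. Points behind the camera (depth <= 0) are flagged and get
    NaN pixel coordinates; points outside the image stay in the output with
    ``in_bounds`` False — downstream code decides what to do with them.
    """
    cam = pose.apply(np.asarray(points3d, dtype=float).reshape(-1, 3))
    z = cam[:, 2]
    behind = z <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = K.fx * cam[:, 0] / z + K.cx
        v = K.fy * cam[:, 1] / z + K.cy
    xy = np.stack([u, v], axis=1)
    xy[behind] = np.nan
    in_bounds = (
        ~behind
        & (xy[:, 0] >= -0.5)
        & (xy[:, 0] <= K.width - 0.5)
        & (xy[:, 1] >= -0.5)
        & (xy[:, 1] <= K.height - 0.5)
    )
    return Projection(xy=xy, depth=z, in_bounds=in_bounds, behind=behind)


def fps_sample(
    points: np.ndarray, n: int, start_index: int | None = None
) -> np.ndarray:
    """Greedy farthest-point sampling of ``n`` points.

    Each successive point maximises the minimum Euclidean distance to the
    already-selected set. Deterministic: ties break toward the lower index,
    and the default start point is the one farthest from the centroid.

    Returns the integer indices of the selected points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if n > len(pts):
        raise ValueError(f"cannot sample {n} from {len(pts)} points")
    if start_index is None:
        start_index = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    selected = [int(start_index)]
    min_d = np.linalg.norm(pts - pts[start_index], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# File formats: PLY point cloud + JSON sidecars
# ---------------------------------------------------------------------------


def save_instrument_model(model: InstrumentModel, ply_path: str | Path) -> None:
    """Write the surface cloud as PLY and keypoints as a JSON sidecar."""
    ply_path = Path(ply_path)
    cloud = trimesh.PointCloud(model.surface_points)
    cloud.export(str(ply_path))
    sidecar = ply_path.with_suffix(".keypoints.json")
    sidecar.write_text(
        json.dumps(
            {"name": model.name, "keypoints3d": model.keypoints3d.tolist()},
            indent=1,
        )
    )


def load_instrument_model(ply_path: str | Path) -> InstrumentModel:
    ply_path = Path(ply_path)
    loaded = trimesh.load(str(ply_path))
    surface = np.asarray(loaded.vertices, dtype=float)
    sidecar = ply_path.with_suffix(".keypoints.json")
    meta = json.loads(sidecar.read_text())
    return InstrumentModel(
        surface_points=surface,
        keypoints3d=np.asarray(meta["keypoints3d"], dtype=float),
        name=meta.get("name", ply_path.stem),
    )


def save_intrinsics(K: CameraIntrinsics, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "fx": K.fx,
                "fy": K.fy,
                "cx": K.cx,
                "cy": K.cy,
                "width": K.width,
                "height": K.height,
            },
            indent=1,
        )
    )


def load_intrinsics(path: str | Path) -> CameraIntrinsics:
    d = json.loads(Path(path).read_text())
    return CameraIntrinsics(
        fx=float(d["fx"]),
        fy=float(d["fy"]),
        cx=float(d["cx"]),
        cy=float(d["cy"]),
        width=int(d["width"]),
        height=int(d["height"]),
    )


def save_pose(pose: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"T_cam_instrument": pose.as_matrix().tolist()}, indent=1)
    )


def load_pose(path: str | Path) -> RigidTransform:
    d = json.loads(Path(path).read_text())
    return RigidTransform.from_matrix(np.asarray(d["T_cam_instrument"], dtype=float))
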