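"""Pose and segmentation evaluation: ADD, AUC-of-ADD, translation/rotation
error, and IoU.

ADD is the mean distance between the instrument's model points transformed by
the estimated and the ground-truth pose, in mm. The accuracy-threshold curve
reports, for each threshold tau, the fraction of frames with ADD strictly
below tau; its normalised area (trapezoidal) is the scalar AUC. Rotation
error is the geodesic angle of R_gt^T R_est in degrees; translation error is
the Euclidean norm of the translation difference in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "EvalResult",
    "add_metric",
    "auc_curve",
    "translation_rotation_error",
    "iou",
    "evaluate_poses",
    "default_thresholds",
]


def default_thresholds() -> np.ndarray:
    """0 to 10 mm in 0.1 mm steps."""
    return np.arange(0.0, 10.0 + 1e-9, 0.1)


def add_metric(
    pose_est: RigidTransform, pose_gt: RigidTransform, model_points: np.ndarray
) -> float:
    pts = np.asarray(model_points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty model point set")
    return float(np.mean(np.linalg.norm(pose_est.apply(pts) - pose_gt.apply(pts), axis=1)))


def auc_curve(
    add_values: np.ndarray, thresholds: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Fraction of frames with ADD < tau per threshold, plus scalar AUC.

    The scalar is the trapezoidal integral of the fraction curve over the
    threshold grid, normalised by the grid span so it lies in [0, 1].
    """
    vals = np.asarray(add_values, dtype=float)
    if vals.size == 0:
        raise ValueError("no ADD values")
    taus = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    if taus.size == 0 or np.any(np.diff(taus) <= 0):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    fractions = (vals[None, :] < taus[:, None]).mean(axis=1)
    if taus.size == 1:
        return fractions, float(fractions[0])
    area = np.trapezoid(fractions, taus) / (taus[-1] - taus[0])
    return fractions, float(area)


def translation_rotation_error(
    pose_est: RigidTransform, pose_gt: RigidTransform
) -> tuple[float, float]:
    """(translation error mm, rotation error degrees)."""
    t_err = float(np.linalg.norm(pose_est.translation - pose_gt.translation))
    r_rel = pose_gt.rotation.T @ pose_est.rotation
    cos = (np.trace(r_rel) - 1.0) / 2.0
    r_err = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return t_err, r_err


def iou(seg_pred: np.ndarray, seg_gt: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both empty."""
    a = np.asarray(seg_pred) > 0
    b = np.asarray(seg_gt) > 0
    if a.shape != b.shape:
        raise ValueError("mask shapes disagree")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class EvalResult:
    """Per-frame metrics plus aggregates for a set of pose estimates."""

    add: np.ndarray  # (F,) mm
    translation_error: np.ndarray  # (F,) mm
    rotation_error: np.ndarray  # (F,) degrees
    iou: np.ndarray | None = None  # (F,) optional
    thresholds: np.ndarray = field(default_factory=default_thresholds)
    auc_fractions: np.ndarray | None = None
    auc: float = float("nan")

    def summary(self) -> dict:
        out = {
            "mean_add_mm": float(np.mean(self.add)),
            "median_add_mm": float(np.median(self.add)),
            "mean_translation_error_mm": float(np.mean(self.translation_error)),
            "mean_rotation_error_deg": float(np.mean(self.rotation_error)),
            "auc_of_add": self.auc,
        }
        if self.iou is not None:
            out["mean_iou"] = float(np.mean(self.iou))
        return out


def evaluate_poses(
    poses_est: list[RigidTransform],
    poses_gt: list[RigidTransform],
    model_points: np.ndarray,
    segs_pred: list[np.ndarray] | None = None,
    segs_gt: list[np.ndarray] | None = None,
    thresholds: np.ndarray | None = None,
) -> EvalResult:
    if len(poses_est) != len(poses_gt):
        raise ValueError("pose list lengths disagree")
    adds, terrs, rerrs = [], [], []
    for est, gt in zip(poses_est, poses_gt):
        adds.append(add_metric(est, gt, model_points))
        te, re = translation_rotation_error(est, gt)
        terrs.append(te)
        rerrs.append(re)
    ious = None
    if segs_pred is not None and segs_gt is not None:
        ious = np.array([iou(p, g) for p, g in zip(segs_pred, segs_gt)])
    taus = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    fractions, area = auc_curve(np.array(adds), taus)
    return EvalResult(
        add=np.array(adds),
        translation_error=np.array(terrs),
        rotation_error=np.array(rerrs),
        iou=ious,
        thresholds=taus,
        auc_fractions=fractions,
        auc=area,
    )
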