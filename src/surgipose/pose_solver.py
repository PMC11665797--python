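"""6DoF pose recovery from 2D-3D keypoint correspondences via RANSAC-PnP.

The minimal solver is a pure-NumPy EPnP (control-point parameterisation,
nullspace betas with Gauss-Newton polishing, absolute orientation by the
Kabsch algorithm), run inside a RANSAC loop on minimal 4-point samples with
adaptive termination. The winning hypothesis is refit on all inliers and
polished by Levenberg-Marquardt on SE(3) (rotation vector + translation)
minimising reprojection error. Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import CameraIntrinsics, RigidTransform, project_points
from .labels import Keypoints2D

__all__ = ["RansacPnPConfig", "PoseEstimate", "solve_pnp", "reprojection_error"]


@dataclass(frozen=True)
class RansacPnPConfig:
    reproj_threshold: float = 3.0  # px
    max_iters: int = 200
    seed: int = 0
    confidence: float = 0.999  # adaptive-termination target


@dataclass(frozen=True)
class PoseEstimate:
    transform: RigidTransform  # instrument -> camera
    inliers: np.ndarray  # (n,) bool over the correspondences passed in
    mean_reprojection_error: float  # px, over inliers


def reprojection_error(
    pose: RigidTransform,
    keypoints2d: np.ndarray | Keypoints2D,
    keypoints3d: np.ndarray,
    K: CameraIntrinsics,
) -> np.ndarray:
    """Per-point pixel distance between observed points and the projections
    of the 3D points under ``pose``. Points behind the camera get inf."""
    obs = np.asarray(
        keypoints2d.xy if isinstance(keypoints2d, Keypoints2D) else keypoints2d,
        dtype=float,
    ).reshape(-1, 2)
    pts3d = np.asarray(keypoints3d, dtype=float).reshape(-1, 3)
    if len(obs) == 0:
        return np.zeros(0)
    proj = project_points(pts3d, pose, K)
    err = np.linalg.norm(proj.xy - obs, axis=1)
    err[proj.behind] = np.inf
    return err


# ---------------------------------------------------------------------------
# EPnP minimal/full solver
# ---------------------------------------------------------------------------


def _control_points(pw: np.ndarray) -> np.ndarray:
    """Centroid plus principal directions scaled by the singular values;
    drops to 3 control points for (near-)planar configurations."""
    c0 = pw.mean(axis=0)
    centered = pw - c0
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s / np.sqrt(len(pw))
    planar = scale[2] < 1e-6 * max(scale[0], 1e-12)
    ndir = 2 if planar else 3
    dirs = vt[:ndir] * np.maximum(scale[:ndir], 1e-9)[:, None]
    return np.vstack([c0, c0 + dirs])


def _barycentric(pw: np.ndarray, cw: np.ndarray) -> np.ndarray:
    ncp = len(cw)
    basis = (cw[1:] - cw[0]).T  # (3, ncp-1)
    coeff, *_ = np.linalg.lstsq(basis, (pw - cw[0]).T, rcond=None)
    alphas = np.empty((len(pw), ncp))
    alphas[:, 1:] = coeff.T
    alphas[:, 0] = 1.0 - coeff.sum(axis=0)
    return alphas


def _rho(cw: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    pairs = [(i, j) for i in range(len(cw)) for j in range(i + 1, len(cw))]
    rho = np.array([np.sum((cw[i] - cw[j]) ** 2) for i, j in pairs])
    return rho, pairs


def _betas_gauss_newton(
    vs: np.ndarray, betas: np.ndarray, rho: np.ndarray, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Polish betas so camera control-point distances match the world ones."""
    nb = len(betas)
    for _ in range(10):
        cc = np.tensordot(betas, vs, axes=1)  # (ncp, 3)
        res = np.empty(len(pairs))
        jac = np.empty((len(pairs), nb))
        for r, (i, j) in enumerate(pairs):
            d = cc[i] - cc[j]
            res[r] = d @ d - rho[r]
            for b in range(nb):
                dv = vs[b, i] - vs[b, j]
                jac[r, b] = 2.0 * d @ dv
        try:
            step = np.linalg.lstsq(jac, -res, rcond=None)[0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        betas = betas + step
        if np.linalg.norm(step) < 1e-12:
            break
    return betas


def _kabsch(pw: np.ndarray, pc: np.ndarray) -> RigidTransform:
    cw = pw.mean(axis=0)
    cc = pc.mean(axis=0)
    h = (pw - cw).T @ (pc - cc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(R, cc - R @ cw)


def _pose_from_betas(
    betas: np.ndarray, vs: np.ndarray, alphas: np.ndarray, pw: np.ndarray
) -> RigidTransform | None:
    cc = np.tensordot(betas, vs, axes=1)
    pc = alphas @ cc
    if pc[:, 2].mean() < 0:
        pc = -pc
    if np.any(pc[:, 2] <= 0):
        return None
    try:
        return _kabsch(pw, pc)
    except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
        return None


def _epnp(pw: np.ndarray, uv: np.ndarray, K: CameraIntrinsics) -> list[RigidTransform]:
    """EPnP candidate poses (beta cases N=1 and N=2, each Gauss-Newton
    polished); the caller ranks candidates by reprojection error."""
    cw = _control_points(pw)
    ncp = len(cw)
    alphas = _barycentric(pw, cw)
    n = len(pw)
    M = np.zeros((2 * n, 3 * ncp))
    for j in range(ncp):
        a = alphas[:, j]
        M[0::2, 3 * j] = a * K.fx
        M[0::2, 3 * j + 2] = a * (K.cx - uv[:, 0])
        M[1::2, 3 * j + 1] = a * K.fy
        M[1::2, 3 * j + 2] = a * (K.cy - uv[:, 1])
    _, _, vt = np.linalg.svd(M, full_matrices=True)
    nkernel = min(4, 3 * ncp)
    vs = vt[-nkernel:][::-1].reshape(nkernel, ncp, 3)  # vs[0] = smallest
    rho, pairs = _rho(cw)

    seeds = []
    # N = 1: closed-form scale on the last singular vector
    dv = np.array([vs[0, i] - vs[0, j] for i, j in pairs])
    denom = np.sum(dv * dv)
    if denom > 1e-12:
        b1 = np.sqrt(np.sum(rho) / denom) if denom else 0.0
        seeds.append(np.array([b1] + [0.0] * (nkernel - 1)))
    # N = 2: linear solve for (b1^2, b1 b2, b2^2)
    if nkernel >= 2:
        dv2 = np.array([vs[1, i] - vs[1, j] for i, j in pairs])
        L = np.stack(
            [np.sum(dv * dv, axis=1), 2 * np.sum(dv * dv2, axis=1), np.sum(dv2 * dv2, axis=1)],
            axis=1,
        )
        sol, *_ = np.linalg.lstsq(L, rho, rcond=None)
        b11, b12, b22 = sol
        b1 = np.sqrt(abs(b11))
        b2 = np.sqrt(abs(b22)) * (1.0 if b12 >= 0 else -1.0)
        if b11 < 0:  # pragma: no cover - sign-degenerate fit
            b1, b2 = abs(b2), abs(b1) * (1.0 if b12 >= 0 else -1.0)
        seeds.append(np.array([b1, b2] + [0.0] * (nkernel - 2)))

    poses = []
    for beta0 in seeds:
        beta = _betas_gauss_newton(vs, beta0, rho, pairs)
        pose = _pose_from_betas(beta, vs, alphas, pw)
        if pose is not None:
            poses.append(pose)
    return poses


# ---------------------------------------------------------------------------
# Nonlinear refinement and RANSAC
# ---------------------------------------------------------------------------


def _refine(
    pose: RigidTransform, pw: np.ndarray, uv: np.ndarray, K: CameraIntrinsics
) -> RigidTransform:
    """Levenberg-Marquardt on (rotation vector, translation)."""

    def residual(x: np.ndarray) -> np.ndarray:
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        cam = pw @ R.T + x[3:]
        z = np.where(np.abs(cam[:, 2]) < 1e-9, 1e-9, cam[:, 2])
        u = K.fx * cam[:, 0] / z + K.cx
        v = K.fy * cam[:, 1] / z + K.cy
        return np.concatenate([u - uv[:, 0], v - uv[:, 1]])

    x0 = np.concatenate([Rotation.from_matrix(pose.rotation).as_rotvec(), pose.translation])
    sol = least_squares(residual, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return RigidTransform(Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:])


def _best_epnp_refined(
    pw: np.ndarray, uv: np.ndarray, K: CameraIntrinsics
) -> RigidTransform | None:
    best, best_err = None, np.inf
    for cand in _epnp(pw, uv, K):
        refined = _refine(cand, pw, uv, K)
        err = reprojection_error(refined, uv, pw, K)
        e = float(np.mean(np.minimum(err, 1e6)))
        if e < best_err:
            best, best_err = refined, e
    return best


def solve_pnp(
    keypoints2d: Keypoints2D | np.ndarray,
    keypoints3d: np.ndarray,
    K: CameraIntrinsics,
    ransac: RansacPnPConfig | None = None,
) -> PoseEstimate:
    """RANSAC-PnP over the visible 2D-3D correspondences.

    Keypoints flagged invisible / not localizable (NaN coordinates or a False
    visibility flag) are excluded up front, which is what lets the pipeline
    tolerate partially visible instruments. Raises ``ValueError`` with fewer
    than 4 usable correspondences or a collinear 3D configuration.
    """
    ransac = ransac or RansacPnPConfig()
    if isinstance(keypoints2d, Keypoints2D):
        uv_all = np.asarray(keypoints2d.xy, dtype=float)
        usable = np.isfinite(uv_all).all(axis=1)
    else:
        uv_all = np.asarray(keypoints2d, dtype=float).reshape(-1, 2)
        usable = np.isfinite(uv_all).all(axis=1)
    pw_all = np.asarray(keypoints3d, dtype=float).reshape(-1, 3)
    if len(pw_all) != len(uv_all):
        raise ValueError("2D and 3D keypoint counts disagree")
    idx = np.nonzero(usable)[0]
    pw, uv = pw_all[idx], uv_all[idx]
    n = len(idx)
    if n < 4:
        raise ValueError(f"need at least 4 correspondences, have {n}")
    centered = pw - pw.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate 3D configuration: points are collinear")

    rng = np.random.default_rng(ransac.seed)
    best_pose: RigidTransform | None = None
    best_inl = np.zeros(n, dtype=bool)
    best_score = -1.0
    needed = ransac.max_iters
    it = 0
    while it < min(needed, ransac.max_iters):
        it += 1
        sample = rng.choice(n, size=4, replace=False)
        pose = _best_epnp_refined(pw[sample], uv[sample], K)
        if pose is None:
            continue
        err = reprojection_error(pose, uv, pw, K)
        inl = err < ransac.reproj_threshold
        score = int(inl.sum()) - float(np.mean(err[inl])) / 1e6 if inl.any() else 0
        if score > best_score:
            best_score = score
            best_pose, best_inl = pose, inl
            w = max(inl.mean(), 1e-3)
            if w >= 1.0:
                break
            denom = np.log1p(-min(w**4, 1.0 - 1e-12))
            if denom < 0:
                needed = int(min(np.ceil(np.log(1 - ransac.confidence) / denom),
                                 ransac.max_iters))
    if best_pose is None or best_inl.sum() < 4:
        raise ValueError("RANSAC-PnP failed: no hypothesis with >= 4 inliers")

    # final refit on the consensus set
    refit = _best_epnp_refined(pw[best_inl], uv[best_inl], K)
    if refit is not None:
        err = reprojection_error(refit, uv, pw, K)
        inl = err < ransac.reproj_threshold
        if inl.sum() >= best_inl.sum():
            best_pose, best_inl = refit, inl
    err = reprojection_error(best_pose, uv, pw, K)

    inliers_full = np.zeros(len(pw_all), dtype=bool)
    inliers_full[idx[best_inl]] = True
    return PoseEstimate(
        transform=best_pose,
        inliers=inliers_full,
        mean_reprojection_error=float(np.mean(err[best_inl])),
    )
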