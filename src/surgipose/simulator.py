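"""Synthetic endoscopic-scene generator.

Emulates the structure of a surgical pose-estimation dataset: a rigid
cylindrical instrument with a tapered distal tip, posed in front of a
procedurally textured tissue-coloured background under a pinhole camera,
with variable light-source intensity and optional opaque foreground
occluders (bar / disk / polygon). Every frame carries full ground truth:
binary segmentation, per-keypoint unit-vector maps, 2D keypoints, the rigid
pose, and the intrinsics.

Rendering is point-splat with a depth buffer plus morphological closing —
the pose-estimation method consumes labels and pixel statistics, not
photorealism, so no ray tracing is attempted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from .geometry import (
    CameraIntrinsics,
    InstrumentModel,
    RigidTransform,
    fps_sample,
    project_points,
    save_instrument_model,
    save_intrinsics,
)
from .labels import (
    Keypoints2D,
    render_segmentation,
    render_vector_field,
    save_mask,
    save_vector_field,
)

__all__ = [
    "Sample",
    "SceneConfig",
    "build_instrument",
    "sample_pose",
    "render_scene",
    "add_occluder",
    "generate_sample",
    "generate_dataset",
    "tip_visibility",
    "default_intrinsics",
]


@dataclass
class Sample:
    """One labelled frame.

    ``seg``/``vfield`` are the effective-visibility labels (occluded
    instrument pixels count as background); the pose and 2D keypoints are the
    full-instrument ground truth and are never altered by occluders.
    ``meta`` holds the frame id, the light scale, the occluder descriptor and
    — after occlusion — the pre-occlusion mask under ``seg_full``.
    """

    image: np.ndarray  # (H, W, 3) uint8
    seg: np.ndarray  # (H, W) uint8
    vfield: np.ndarray  # (n, H, W, 2) float32
    keypoints2d: Keypoints2D
    pose: RigidTransform
    intrinsics: CameraIntrinsics
    keypoints3d: np.ndarray  # (n, 3) mm
    meta: dict = field(default_factory=dict)


def default_intrinsics(width: int = 960, height: int = 540) -> CameraIntrinsics:
    """A laparoscope-like pinhole camera; focal length scales with width."""
    f = 0.75 * width
    return CameraIntrinsics(
        fx=f, fy=f, cx=(width - 1) / 2.0, cy=(height - 1) / 2.0, width=width, height=height
    )


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for the generated scenes.

    Light intensity spans the 40%-100% range used for the real recordings;
    frames showing less than ``visibility_threshold`` of the instrument tip
    (distal 20% of its length) are excluded from generated datasets.
    """

    shaft_length: float = 80.0  # mm
    radius: float = 4.0  # mm
    tip_length: float = 12.0  # mm
    surface_density: int = 20000
    n_keypoints: int = 10
    depth_range: tuple[float, float] = (90.0, 160.0)  # mm, camera z of centre
    tilt_range: tuple[float, float] = (-60.0, 60.0)  # deg from image plane
    roll_range: tuple[float, float] = (0.0, 360.0)  # deg about the shaft axis
    lateral_fraction: float = 0.25  # centre offset as fraction of frustum
    light_range: tuple[float, float] = (0.4, 1.0)
    background: str | Path = "procedural"
    occluders: tuple[str, ...] = ()  # subset of {"bar", "disk", "polygon"}
    occluder_coverage: tuple[float, float] = (0.2, 0.5)
    visibility_threshold: float = 0.2
    n_frames: int = 50
    seed: int = 0
    width: int = 960
    height: int = 540


def build_instrument(
    shaft_length: float = 80.0,
    radius: float = 4.0,
    tip_length: float = 12.0,
    surface_density: int = 20000,
    n_keypoints: int = 10,
    name: str = "cylindrical-instrument",
) -> InstrumentModel:
    """Cylinder-plus-tapered-tip surface cloud with FPS-sampled keypoints.

    The shaft runs along +z from 0 to ``shaft_length``; the tip tapers to a
    point over ``tip_length``. The surface grid is deterministic (a helical
    lattice), so the same parameters always give the same model.
    """
    if shaft_length <= 0 or radius <= 0 or tip_length < 0:
        raise ValueError("instrument dimensions must be positive")
    if n_keypoints < 4:
        raise ValueError("need at least 4 keypoints")
    total = shaft_length + tip_length
    shaft_area = 2 * np.pi * radius * shaft_length
    tip_area = np.pi * radius * np.hypot(tip_length, radius) if tip_length > 0 else 0.0
    n_shaft = max(16, int(round(surface_density * shaft_area / (shaft_area + tip_area))))
    n_tip = max(0, surface_density - n_shaft) if tip_length > 0 else 0

    aspect = shaft_length / (2 * np.pi * radius)
    n_rings = max(2, int(round(np.sqrt(n_shaft * aspect))))
    n_theta = max(8, n_shaft // n_rings)
    z = np.repeat(np.linspace(0.0, shaft_length, n_rings), n_theta)
    theta = np.tile(np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False), n_rings)
    # helical twist avoids aligned rings without randomness
    theta = theta + np.repeat(np.arange(n_rings) * 0.5, n_theta)
    shaft = np.stack([radius * np.cos(theta), radius * np.sin(theta), z], axis=1)

    pts = [shaft]
    if n_tip > 0:
        n_rings_t = max(2, int(round(np.sqrt(n_tip / 4))))
        n_theta_t = max(8, n_tip // n_rings_t)
        zt = np.repeat(np.linspace(shaft_length, total, n_rings_t), n_theta_t)
        rt = radius * (total - zt) / tip_length
        th = np.tile(np.linspace(0.0, 2 * np.pi, n_theta_t, endpoint=False), n_rings_t)
        th = th + np.repeat(np.arange(n_rings_t) * 0.5, n_theta_t)
        pts.append(np.stack([rt * np.cos(th), rt * np.sin(th), zt], axis=1))
    surface = np.concatenate(pts, axis=0)

    kp_idx = fps_sample(surface, n_keypoints)
    return InstrumentModel(
        surface_points=surface, keypoints3d=surface[kp_idx], name=name
    )


def sample_pose(config: SceneConfig, rng: np.random.Generator) -> RigidTransform:
    """Uniform random pose within the configured ranges.

    The instrument centre lands at a depth in ``depth_range`` with a bounded
    lateral offset; orientation combines a tilt out of the image plane, a
    roll about the shaft axis, and a uniform in-plane spin.
    """
    from scipy.spatial.transform import Rotation

    depth = rng.uniform(*config.depth_range)
    tilt = np.radians(rng.uniform(*config.tilt_range))
    roll = np.radians(rng.uniform(*config.roll_range))
    spin = rng.uniform(0.0, 2 * np.pi)
    # shaft axis starts along camera x (lying in the image plane)
    R = (
        Rotation.from_euler("z", spin)
        * Rotation.from_euler("y", tilt)
        * Rotation.from_euler("x", roll)
        * Rotation.from_euler("y", np.pi / 2)
    ).as_matrix()
    K = default_intrinsics(config.width, config.height)
    half_w = depth * config.width / (2 * K.fx)
    half_h = depth * config.height / (2 * K.fy)
    centre = np.array(
        [
            rng.uniform(-1, 1) * config.lateral_fraction * half_w,
            rng.uniform(-1, 1) * config.lateral_fraction * half_h,
            depth,
        ]
    )
    model_centre = np.array([0.0, 0.0, (config.shaft_length + config.tip_length) / 2])
    t = centre - R @ model_centre
    return RigidTransform(R, t)


def _procedural_background(
    height: int, width: int, rng: np.random.Generator
) -> np.ndarray:
    """Tissue-hued blotchy texture: random blobs smoothed into soft shapes."""
    base = np.array([148.0, 62.0, 58.0])
    img = np.ones((height, width, 3)) * base
    field_ = rng.normal(0.0, 1.0, size=(height // 8 + 1, width // 8 + 1))
    field_ = np.kron(field_, np.ones((8, 8)))[:height, :width]
    field_ = gaussian(field_, sigma=6.0)
    field_ /= max(np.abs(field_).max(), 1e-9)
    img += field_[..., None] * np.array([55.0, 30.0, 28.0])
    # a few glossy highlights
    for _ in range(4):
        cy, cx = rng.integers(0, height), rng.integers(0, width)
        yy, xx = np.mgrid[0:height, 0:width]
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (width / 14) ** 2))
        img += blob[..., None] * rng.uniform(10, 35)
    return img


def render_scene(
    model: InstrumentModel,
    pose: RigidTransform,
    K: CameraIntrinsics,
    config: SceneConfig,
    rng: np.random.Generator,
) -> Sample:
    """Render one labelled frame at the given pose.

    The instrument is flat-shaded with depth attenuation and a specular
    streak along the shaft; the whole image is scaled by a light intensity
    drawn from ``light_range``. Deterministic given the generator state.
    """
    light = rng.uniform(*config.light_range)
    if isinstance(config.background, (str, Path)) and str(config.background) != "procedural":
        from PIL import Image

        bg = np.asarray(
            Image.open(config.background).convert("RGB").resize((K.width, K.height)),
            dtype=float,
        )
    else:
        bg = _procedural_background(K.height, K.width, rng)
    img = bg.copy()

    proj = project_points(model.surface_points, pose, K)
    ok = proj.in_bounds
    seg = render_segmentation(model, pose, K)
    if seg.any() and ok.any():
        pts = model.surface_points[ok]
        xy = proj.xy[ok]
        depth = proj.depth[ok]
        # shading: radial distance from the principal axis approximates the
        # surface normal's angle to the view direction on a cylinder
        axis_dir = _principal_axis(model.surface_points)
        axial = (pts - model.surface_points.mean(axis=0)) @ axis_dir
        radial = pts - model.surface_points.mean(axis=0) - axial[:, None] * axis_dir
        rnorm = np.linalg.norm(radial, axis=1)
        facing = np.zeros(len(pts))
        nz = rnorm > 1e-9
        cam_radial = (pose.rotation @ (radial[nz] / rnorm[nz, None]).T).T
        facing[nz] = np.clip(-cam_radial[:, 2], 0.0, 1.0)
        d0, d1 = depth.min(), max(depth.max(), depth.min() + 1e-6)
        shade = 0.55 + 0.25 * (1.0 - (depth - d0) / (d1 - d0)) + 0.5 * facing**8
        colour = np.clip(shade, 0, 1.6)[:, None] * np.array([165.0, 168.0, 178.0])

        order = np.argsort(-depth)  # paint far first so near overwrites
        rows = np.rint(xy[order, 1]).astype(int)
        cols = np.rint(xy[order, 0]).astype(int)
        colour = colour[order]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                r = np.clip(rows + dr, 0, K.height - 1)
                c = np.clip(cols + dc, 0, K.width - 1)
                img[r, c] = colour
        img[seg == 0] = bg[seg == 0]
    else:
        warnings.warn("instrument not visible in rendered frame")

    img = np.clip(img * light, 0, 255).astype(np.uint8)

    kp_proj = project_points(model.keypoints3d, pose, K)
    kp2d = Keypoints2D(xy=kp_proj.xy.copy(), visible=kp_proj.in_bounds.copy())
    vfield = render_vector_field(kp2d, seg)
    return Sample(
        image=img,
        seg=seg,
        vfield=vfield,
        keypoints2d=kp2d,
        pose=pose,
        intrinsics=K,
        keypoints3d=model.keypoints3d.copy(),
        meta={"light": float(light)},
    )


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


# ---------------------------------------------------------------------------
# Occluders
# ---------------------------------------------------------------------------


def _occluder_mask(
    shape: str, centre: np.ndarray, size: float, angle: float, hw: tuple[int, int],
    vertices: np.ndarray | None = None,
) -> np.ndarray:
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w]
    if shape == "disk":
        return (yy - centre[1]) ** 2 + (xx - centre[0]) ** 2 <= size**2
    if shape == "bar":
        nx, ny = np.cos(angle), np.sin(angle)
        return np.abs((xx - centre[0]) * nx + (yy - centre[1]) * ny) <= size
    if shape == "polygon":
        assert vertices is not None
        vx = centre[0] + size * vertices[:, 0]
        vy = centre[1] + size * vertices[:, 1]
        mask = np.zeros(hw, dtype=bool)
        rr, cc = draw_polygon(vy, vx, shape=hw)
        mask[rr, cc] = True
        return mask
    raise ValueError(f"unknown occluder shape {shape!r}")


def add_occluder(
    sample: Sample,
    shape: str,
    coverage_target: float,
    rng: np.random.Generator,
) -> Sample:
    """Composite an opaque occluder over the frame.

    ``coverage_target`` is the fraction of instrument pixels to cover; the
    occluder size is bisected until the achieved coverage is within 1% of the
    target (or the closest achievable, which is logged in the meta). The
    effective-visibility labels (seg, vfield) lose the occluded pixels; the
    keypoints and pose ground truth are untouched — the true pose does not
    depend on what happens to be in front of the instrument.
    """
    if not 0 <= coverage_target < 1:
        raise ValueError("coverage_target must be in [0, 1)")
    out = replace(
        sample,
        image=sample.image.copy(),
        seg=sample.seg.copy(),
        vfield=sample.vfield.copy(),
        meta=dict(sample.meta),
    )
    out.meta.setdefault("seg_full", sample.seg.copy())
    if coverage_target == 0:
        out.meta["occluder"] = {"shape": "none", "coverage": 0.0, "target": 0.0}
        return out
    inst = np.argwhere(sample.seg > 0)
    if len(inst) == 0:
        out.meta["occluder"] = {"shape": shape, "coverage": 0.0, "target": coverage_target}
        return out
    centre_rc = inst[rng.integers(len(inst))]
    centre = np.array([centre_rc[1], centre_rc[0]], dtype=float)
    centre += rng.uniform(-3, 3, size=2)
    angle = rng.uniform(0, np.pi)
    vertices = None
    if shape == "polygon":
        k = int(rng.integers(5, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=k))
        rad = rng.uniform(0.6, 1.0, size=k)
        vertices = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)

    hw = sample.seg.shape
    n_inst = len(inst)
    lo, hi = 0.0, float(max(hw))
    best_mask, best_cov = None, -1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        mask = _occluder_mask(shape, centre, mid, angle, hw, vertices)
        cov = (mask & (sample.seg > 0)).sum() / n_inst
        if best_mask is None or abs(cov - coverage_target) < abs(best_cov - coverage_target):
            best_mask, best_cov = mask, cov
        if abs(cov - coverage_target) < 0.01:
            break
        if cov < coverage_target:
            lo = mid
        else:
            hi = mid
    mask = best_mask
    if abs(best_cov - coverage_target) >= 0.02:
        warnings.warn(
            f"occluder coverage {best_cov:.3f} misses target {coverage_target:.3f}"
        )

    tone = rng.uniform(45, 90)
    noise = rng.normal(0, 6, size=(int(mask.sum()), 3))
    out.image[mask] = np.clip(tone + noise, 0, 255).astype(np.uint8)
    out.seg[mask] = 0
    out.vfield[:, mask] = 0.0
    out.meta["occluder"] = {
        "shape": shape,
        "coverage": float(best_cov),
        "target": float(coverage_target),
    }
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _tip_mask(model: InstrumentModel, pose: RigidTransform, K: CameraIntrinsics) -> np.ndarray:
    """Pixels of the distal 20% of the instrument's length."""
    from skimage.morphology import closing, footprint_rectangle

    z = model.surface_points[:, 2]
    cut = z.min() + 0.8 * (z.max() - z.min())
    proj = project_points(model.surface_points[z >= cut], pose, K)
    mask = np.zeros((K.height, K.width), dtype=np.uint8)
    ok = proj.in_bounds
    if ok.any():
        cols = np.rint(proj.xy[ok, 0]).astype(int).clip(0, K.width - 1)
        rows = np.rint(proj.xy[ok, 1]).astype(int).clip(0, K.height - 1)
        mask[rows, cols] = 1
        mask = closing(mask.astype(bool), footprint_rectangle((3, 3))).astype(np.uint8)
    return mask


def tip_visibility(sample: Sample, model: InstrumentModel) -> float:
    """(visible tip pixels) / (unoccluded tip pixels); 0 when the tip never
    entered the frame."""
    tip = _tip_mask(model, sample.pose, sample.intrinsics) > 0
    full = sample.meta.get("seg_full", sample.seg) > 0
    denom = (tip & full).sum()
    if denom == 0:
        return 0.0
    return float((tip & (sample.seg > 0)).sum() / denom)


def generate_sample(
    model: InstrumentModel,
    config: SceneConfig,
    rng: np.random.Generator,
    frame_id: int = 0,
    max_retries: int = 20,
) -> Sample:
    """Sample a pose (re-drawn until the instrument is visible), render, and
    optionally add an occluder drawn from the configured set."""
    K = default_intrinsics(config.width, config.height)
    for _ in range(max_retries):
        pose = sample_pose(config, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = render_scene(model, pose, K, config, rng)
        if sample.seg.sum() >= 50:
            break
    else:
        raise RuntimeError("could not sample a visible pose")
    if config.occluders:
        shape = config.occluders[int(rng.integers(len(config.occluders)))]
        coverage = rng.uniform(*config.occluder_coverage)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sample = add_occluder(sample, shape, coverage, rng)
    sample.meta["frame_id"] = frame_id
    return sample


def generate_dataset(
    config: SceneConfig, out_dir: str | Path, model: InstrumentModel | None = None
) -> dict:
    """Write a complete labelled dataset directory.

    Layout: ``frames/NNNNNN.png``, ``masks/NNNNNN.png``, ``vfields/NNNNNN.bin``
    (+ JSON headers), ``poses/NNNNNN.json``, ``manifest.jsonl``,
    ``intrinsics.json``, ``model.ply`` with a keypoint sidecar. Frames whose
    tip visibility falls below ``config.visibility_threshold`` are excluded
    and logged in the returned summary. Deterministic given ``config.seed``.
    """
    from PIL import Image

    out = Path(out_dir)
    for sub in ("frames", "masks", "vfields", "poses"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    if model is None:
        model = build_instrument(
            config.shaft_length,
            config.radius,
            config.tip_length,
            config.surface_density,
            config.n_keypoints,
        )
    K = default_intrinsics(config.width, config.height)
    save_intrinsics(K, out / "intrinsics.json")
    save_instrument_model(model, out / "model.ply")

    rng = np.random.default_rng(config.seed)
    retained, excluded = [], []
    for fid in range(config.n_frames):
        sample = generate_sample(model, config, rng, frame_id=fid)
        vis = tip_visibility(sample, model)
        if vis < config.visibility_threshold:
            excluded.append({"frame": fid, "tip_visibility": vis})
            continue
        stem = f"{fid:06d}"
        Image.fromarray(sample.image).save(out / "frames" / f"{stem}.png")
        save_mask(sample.seg, out / "masks" / f"{stem}.png")
        save_vector_field(sample.vfield, out / "vfields" / f"{stem}.bin")
        (out / "poses" / f"{stem}.json").write_text(
            json.dumps({"T_cam_instrument": sample.pose.as_matrix().tolist()})
        )
        retained.append(
            {
                "frame": fid,
                "image": f"frames/{stem}.png",
                "mask": f"masks/{stem}.png",
                "vfield": f"vfields/{stem}.bin",
                "pose": f"poses/{stem}.json",
                "keypoints2d": np.asarray(sample.keypoints2d.xy).tolist(),
                "tip_visibility": vis,
                "light": sample.meta.get("light"),
                "occluder": sample.meta.get("occluder", {"shape": "none"}),
            }
        )
    if not retained:
        raise RuntimeError("zero frames retained: visibility threshold too strict")
    with open(out / "manifest.jsonl", "w") as fh:
        for rec in retained:
            fh.write(json.dumps(rec) + "\n")
    summary = {
        "retained": len(retained),
        "excluded": len(excluded),
        "exclusions": excluded,
        "out_dir": str(out),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
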