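"""RANSAC-based pixel voting: from a filtered unit-vector field to 2D keypoints.

For each keypoint, candidate locations are generated at the intersections of
rays cast from random pairs of instrument pixels along their stored unit
vectors. Each candidate h is scored by the consensus weight

    w = sum_j  [ cos(angle((h - p_j), v_j)) >= theta ] * cos(angle)

over all filtered pixels j, with theta = 0.99. The keypoint estimate is the
weight-weighted average of the candidates. Because every instrument pixel
votes independently, the scheme degrades gracefully under occlusion: any
remaining subset of pixels still votes for the same point.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .labels import Keypoints2D, filter_vectors

__all__ = [
    "VotingConfig",
    "KeypointHypothesis",
    "VotingResult",
    "intersect_rays",
    "weight_hypothesis",
    "weight_hypotheses",
    "aggregate_keypoint",
    "localize_keypoints",
]

_PARALLEL_EPS = 1e-8
DEFAULT_THETA = 0.99


@dataclass(frozen=True)
class VotingConfig:
    """theta: cosine inlier threshold of the consensus weight (0.99);
    num_hypotheses: RANSAC pixel pairs per keypoint; exhaustive_below:
    enumerate all pairs when the instrument has at most this many pixels."""

    theta: float = DEFAULT_THETA
    num_hypotheses: int = 128
    seed: int = 0
    exhaustive_below: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.num_hypotheses < 1:
            raise ValueError("need at least one hypothesis")


@dataclass(frozen=True)
class KeypointHypothesis:
    position: np.ndarray  # (2,) pixel coordinates
    weight: float


@dataclass(frozen=True)
class VotingResult:
    """Keypoints plus diagnostics: per-keypoint confidence (sum of consensus
    weights), a localized flag, and the unweighted candidate mean kept for
    comparison with the weighted aggregate."""

    keypoints: Keypoints2D
    confidence: np.ndarray  # (n,) sum of hypothesis weights
    localized: np.ndarray  # (n,) bool
    unweighted_mean: np.ndarray  # (n, 2) plain mean of candidates (debug)


def intersect_rays(
    p1: np.ndarray, v1: np.ndarray, p2: np.ndarray, v2: np.ndarray
) -> np.ndarray | None:
    """Intersection of the two lines p + t v (t unconstrained), or None when
    the directions are parallel within 1e-8."""
    p1 = np.asarray(p1, dtype=float)
    v1 = np.asarray(v1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    if abs(cross) < _PARALLEL_EPS:
        return None
    d = p2 - p1
    t = (d[0] * v2[1] - d[1] * v2[0]) / cross
    return p1 + t * v1


def _intersect_many(
    pa: np.ndarray, va: np.ndarray, pb: np.ndarray, vb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pairwise line intersection; returns (points, valid mask)."""
    cross = va[:, 0] * vb[:, 1] - va[:, 1] * vb[:, 0]
    valid = np.abs(cross) >= _PARALLEL_EPS
    d = pb - pa
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (d[:, 0] * vb[:, 1] - d[:, 1] * vb[:, 0]) / cross
    pts = pa + t[:, None] * va
    valid &= np.isfinite(pts).all(axis=1)
    return pts, valid


def weight_hypotheses(
    candidates: np.ndarray,
    pixels: np.ndarray,
    vectors: np.ndarray,
    theta: float = DEFAULT_THETA,
) -> np.ndarray:
    """Consensus weight of each candidate (K, 2) over all pixels (m, 2)/(m, 2).

    Each pixel whose stored vector points at the candidate to within the
    cosine threshold contributes its cosine; pixels coincident with the
    candidate are skipped (undefined direction).
    """
    d = candidates[:, None, :] - pixels[None, :, :]  # (K, m, 2)
    norm = np.linalg.norm(d, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (d * vectors[None, :, :]).sum(axis=2) / norm
    cos = np.where(norm > 0, cos, -np.inf)
    contrib = np.where(cos >= theta, cos, 0.0)
    return contrib.sum(axis=1)


def weight_hypothesis(
    h: np.ndarray,
    pixels: list | np.ndarray,
    vectors: list | np.ndarray | None = None,
    theta: float = DEFAULT_THETA,
) -> float:
    """Scalar consensus weight of one candidate.

    ``pixels`` may be an (m, 2) array paired with ``vectors`` (m, 2), or a
    sequence of (pixel, vector) tuples.
    """
    if vectors is None:
        pv = list(pixels)
        pixels = np.array([p for p, _ in pv], dtype=float)
        vectors = np.array([v for _, v in pv], dtype=float)
    h = np.asarray(h, dtype=float).reshape(1, 2)
    return float(
        weight_hypotheses(h, np.asarray(pixels, float), np.asarray(vectors, float), theta)[0]
    )


def aggregate_keypoint(hypotheses: list[KeypointHypothesis]) -> np.ndarray:
    """Weighted average of candidate locations; raises if no weight > 0."""
    if not hypotheses:
        raise ValueError("no hypotheses to aggregate")
    w = np.array([h.weight for h in hypotheses], dtype=float)
    pos = np.array([h.position for h in hypotheses], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("keypoint not localizable: all hypothesis weights are zero")
    return (w[:, None] * pos).sum(axis=0) / total


def _sample_pairs(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct unordered pixel-index pairs (without replacement)."""
    total = m * (m - 1) // 2
    if k >= total:
        return np.array(list(combinations(range(m), 2)), dtype=int)
    flat = rng.choice(total, size=k, replace=False)
    # invert the pair index: row a such that offsets of pairs (a, b>a)
    a = (m - 2 - np.floor(np.sqrt(-8 * flat + 4 * m * (m - 1) - 7) / 2 - 0.5)).astype(int)
    b = (flat + a + 1 - m * (m - 1) // 2 + (m - a) * (m - a - 1) // 2).astype(int)
    return np.stack([a, b], axis=1)


def localize_keypoints(
    seg: np.ndarray, vfield: np.ndarray, config: VotingConfig | None = None
) -> VotingResult:
    """Vote every keypoint's 2D location from the filtered vector field.

    For each keypoint: draw ``num_hypotheses`` random pixel pairs (exhaustive
    enumeration when the instrument is small), intersect their rays, weight
    each intersection by pixel consensus, and return the weighted average.
    The per-keypoint RNG is seeded with ``seed + keypoint index`` so results
    are reproducible and independent of keypoint order.
    """
    config = config or VotingConfig()
    pixels, vectors = filter_vectors(seg, vfield)
    m = len(pixels)
    if m < 2:
        raise ValueError("need at least 2 instrument pixels to vote")
    n = vectors.shape[0]
    h, w = seg.shape[:2]

    xy = np.full((n, 2), np.nan)
    unweighted = np.full((n, 2), np.nan)
    confidence = np.zeros(n)
    localized = np.zeros(n, dtype=bool)

    exhaustive = m <= config.exhaustive_below
    for i in range(n):
        rng = np.random.default_rng(config.seed + i)
        vi = vectors[i]
        # pixels with zero vectors (keypoint-coincident) cannot cast rays
        caster = np.linalg.norm(vi, axis=1) > 0.5
        idx = np.nonzero(caster)[0]
        if len(idx) < 2:
            continue
        if exhaustive:
            pairs = np.array(list(combinations(idx, 2)), dtype=int)
        else:
            local = _sample_pairs(len(idx), config.num_hypotheses, rng)
            pairs = idx[local]
        cand, valid = _intersect_many(
            pixels[pairs[:, 0]], vi[pairs[:, 0]], pixels[pairs[:, 1]], vi[pairs[:, 1]]
        )
        cand = cand[valid]
        if len(cand) == 0:
            continue
        weights = _chunked_weights(cand, pixels[idx], vi[idx], config.theta)
        total = weights.sum()
        if total <= 0:
            continue
        xy[i] = (weights[:, None] * cand).sum(axis=0) / total
        unweighted[i] = cand.mean(axis=0)
        confidence[i] = total
        localized[i] = True

    visible = (
        localized
        & (xy[:, 0] >= -0.5)
        & (xy[:, 0] <= w - 0.5)
        & (xy[:, 1] >= -0.5)
        & (xy[:, 1] <= h - 0.5)
    )
    return VotingResult(
        keypoints=Keypoints2D(xy=xy, visible=visible),
        confidence=confidence,
        localized=localized,
        unweighted_mean=unweighted,
    )


def _chunked_weights(
    cand: np.ndarray, pixels: np.ndarray, vectors: np.ndarray, theta: float
) -> np.ndarray:
    """Weight candidates in chunks to bound peak memory at K x m."""
    budget = 4_000_000
    step = max(1, budget // max(1, len(pixels)))
    out = np.empty(len(cand))
    for s in range(0, len(cand), step):
        out[s : s + step] = weight_hypotheses(cand[s : s + step], pixels, vectors, theta)
    return out
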