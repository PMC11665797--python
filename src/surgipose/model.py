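"""Training losses, multi-scale feature fusion, and a small trainable
encoder-decoder for desk-scale end-to-end checks.

The dense-prediction network has two output branches: per-pixel instrument
segmentation (binary cross-entropy, Eq.-style sum convention with a
mean-per-pixel option) and per-pixel, per-keypoint 2D vectors (Smooth-L1 on
instrument pixels only). Keypoint loss (Smooth-L1 on voted 2D keypoints) is
reported as a monitored metric: the RANSAC voting between vector maps and
keypoints is not differentiable, so gradients flow through the dense maps.

The network itself is a deliberately small (< 10k parameter) pure-NumPy CNN
with manual backpropagation and a hand-written Adam optimiser. It mirrors
the multi-resolution design of the full-scale backbone at toy scale: four
branches at scales 1, 1/2, 1/4, 1/8 whose feature maps are bilinearly
upsampled to full resolution, concatenated, and fused by two pointwise (1x1)
convolutions before the branch heads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import Keypoints2D

__all__ = [
    "smooth_l1",
    "keypoint_loss",
    "seg_loss",
    "vector_loss",
    "FusionSpec",
    "fuse_features",
    "TinyPoseNet",
    "learning_rate_at",
    "train_toy",
    "predict_maps",
]

_CLAMP = 1e-7


def smooth_l1(x: np.ndarray) -> np.ndarray:
    """Elementwise Smooth-L1: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise.

    Continuous and once-differentiable at |x| = 1 (both pieces give 0.5
    with unit slope).
    """
    x = np.abs(np.asarray(x, dtype=float))
    return np.where(x < 1.0, 0.5 * x * x, x - 0.5)


def keypoint_loss(pred: Keypoints2D | np.ndarray, gt: Keypoints2D | np.ndarray) -> float:
    """Mean over keypoints of per-coordinate Smooth-L1 error."""
    p = np.asarray(pred.xy if isinstance(pred, Keypoints2D) else pred, dtype=float)
    g = np.asarray(gt.xy if isinstance(gt, Keypoints2D) else gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError("keypoint counts disagree")
    n = p.shape[0]
    return float(smooth_l1(p - g).sum() / n)


def seg_loss(
    seg_pred: np.ndarray, seg_gt: np.ndarray, reduction: str = "sum"
) -> float:
    """Binary cross-entropy between predicted probabilities and the binary
    ground truth. ``reduction='sum'`` sums over pixels (the formal
    convention); ``'mean'`` divides by the pixel count for scale-stable
    training."""
    p = np.asarray(seg_pred, dtype=float)
    g = np.asarray(seg_gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError("shapes disagree")
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    bce = -(g * np.log(p) + (1.0 - g) * np.log(1.0 - p))
    if reduction == "sum":
        return float(bce.sum())
    if reduction == "mean":
        return float(bce.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def vector_loss(
    vfield_pred: np.ndarray,
    vfield_gt: np.ndarray,
    seg_gt: np.ndarray,
    reduction: str = "sum",
) -> float:
    """Smooth-L1 between predicted and ground-truth vectors on instrument
    pixels only, averaged over keypoints. ``'mean'`` additionally divides by
    the instrument pixel count."""
    vp = np.asarray(vfield_pred, dtype=float)
    vg = np.asarray(vfield_gt, dtype=float)
    if vp.shape != vg.shape:
        raise ValueError("shapes disagree")
    mask = np.asarray(seg_gt) > 0
    n = vp.shape[0]
    diff = smooth_l1(vp[:, mask] - vg[:, mask]) if mask.any() else np.zeros((n, 0, 2))
    per_kp = diff.sum(axis=(1, 2))
    if reduction == "mean":
        m = max(int(mask.sum()), 1)
        return float(per_kp.mean() / m)
    return float(per_kp.mean())


# ---------------------------------------------------------------------------
# Bilinear resampling (shared by fusion and the network)
# ---------------------------------------------------------------------------


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic interpolation matrix mapping length-n_in signals to
    length n_out (half-pixel-centre convention)."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    A[np.arange(n_out), lo] += 1.0 - w
    A[np.arange(n_out), hi] += w
    return A


def _upsample(x: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
    """Bilinear upsample (B, C, H, W) -> (B, C, h_out, w_out)."""
    Ah = _bilinear_matrix(h_out, x.shape[2])
    Aw = _bilinear_matrix(w_out, x.shape[3])
    return np.einsum("ij,bcjk,lk->bcil", Ah, x, Aw, optimize=True)


@dataclass(frozen=True)
class FusionSpec:
    """Contract of the multi-scale fusion: branch downscale factors (the
    largest map has factor 1) and the channel count after the two pointwise
    mixing stages."""

    branch_scales: tuple[int, ...] = (1, 2, 4, 8)
    fused_channels: int = 24

    def __post_init__(self) -> None:
        if len(self.branch_scales) < 1:
            raise ValueError("need at least one branch")
        if min(self.branch_scales) != 1:
            raise ValueError("largest branch must be at scale 1 after upsampling")


def fuse_features(
    branch_maps: list[np.ndarray],
    spec: FusionSpec,
    mix1: np.ndarray | None = None,
    mix2: np.ndarray | None = None,
) -> np.ndarray:
    """Upsample every branch to the largest spatial size, concatenate the
    channels, and apply two pointwise (1x1) mixing stages.

    ``branch_maps`` are (C_i, H_i, W_i) grids ordered as ``spec.branch_scales``.
    ``mix1``/``mix2`` are the 1x1 kernels as (C_in, C_out) matrices; ``None``
    means identity mixing (the op itself is linear — nonlinearities belong to
    the surrounding network).
    """
    if len(branch_maps) != len(spec.branch_scales):
        raise ValueError("branch count does not match the fusion spec")
    ref = branch_maps[int(np.argmin(spec.branch_scales))]
    h, w = ref.shape[1:]
    for bm, s in zip(branch_maps, spec.branch_scales):
        eh, ew = -(-h // s), -(-w // s)  # ceil division
        if bm.shape[1:] != (eh, ew):
            raise ValueError(
                f"branch at scale {s} has shape {bm.shape[1:]}, expected {(eh, ew)}"
            )
    ups = [
        _upsample(bm[None], h, w)[0] if bm.shape[1:] != (h, w) else bm
        for bm in branch_maps
    ]
    fused = np.concatenate(ups, axis=0)
    for mix in (mix1, mix2):
        if mix is not None:
            fused = np.einsum("chw,cd->dhw", fused, mix)
    return fused


# ---------------------------------------------------------------------------
# Pure-NumPy layers with manual backprop
# ---------------------------------------------------------------------------


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Conv3x3:
    """3x3 convolution, padding 1, stride 1 or 2, via im2col."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = _Param(rng.normal(0.0, scale, size=(9 * c_in, c_out)).astype(np.float32))
        self.b = _Param(np.zeros(c_out, dtype=np.float32))
        self.stride = stride
        self.c_in = c_in
        self._cache: tuple | None = None

    @property
    def params(self) -> list[_Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]  # (B, C, Ho, Wo, 3, 3)
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * 9)
        out = cols @ self.w.value + self.b.value
        self._cache = (cols, (B, C, H, W), (Ho, Wo))
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W), (Ho, Wo) = self._cache
        d = dout.transpose(0, 2, 3, 1)  # (B, Ho, Wo, c_out)
        self.w.grad += cols.reshape(-1, C * 9).T @ d.reshape(-1, d.shape[-1])
        self.b.grad += d.sum(axis=(0, 1, 2))
        dcols = d @ self.w.value.T  # (B, Ho, Wo, C*9)
        dcols = dcols.reshape(B, Ho, Wo, C, 3, 3)
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=np.float32)
        ys = np.arange(Ho) * self.stride
        xs = np.arange(Wo) * self.stride
        for ky in range(3):
            for kx in range(3):
                dxp[:, :, ys[:, None] + ky, xs[None, :] + kx] += dcols[
                    :, :, :, :, ky, kx
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class _ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Upsample:
    """Bilinear upsampling to a fixed output size; linear, so the backward
    pass is the transposed interpolation."""

    def __init__(self, h_out: int, w_out: int):
        self.h_out, self.w_out = h_out, w_out
        self._Ah: np.ndarray | None = None
        self._Aw: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._Ah = _bilinear_matrix(self.h_out, x.shape[2])
        self._Aw = _bilinear_matrix(self.w_out, x.shape[3])
        return np.einsum("ij,bcjk,lk->bcil", self._Ah, x, self._Aw, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.einsum("ij,bcik,kl->bcjl", self._Ah, dout, self._Aw, optimize=True)


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = _Param(rng.normal(0.0, scale, size=(c_in, c_out)).astype(np.float32))
        self.b = _Param(np.zeros(c_out, dtype=np.float32))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[_Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("bchw,cd->bdhw", x, self.w.value) + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("bchw,bdhw->cd", self._x, dout)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("bdhw,cd->bchw", dout, self.w.value)


class TinyPoseNet:
    """Four-branch multi-resolution CNN with fused 1x1 mixing and two heads.

    Input: (B, 3, H, W) images in [0, 1]; two normalised coordinate channels
    are appended so the vector branch can express position-dependent fields.
    Outputs: seg logits (B, 1, H, W) and raw vectors (B, 2n, H, W).
    """

    def __init__(self, n_keypoints: int = 10, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_keypoints = n_keypoints
        c = (8, 12, 16, 16)
        self.conv1 = _Conv3x3(5, c[0], 1, rng)
        self.conv2 = _Conv3x3(c[0], c[1], 2, rng)
        self.conv3 = _Conv3x3(c[1], c[2], 2, rng)
        self.conv4 = _Conv3x3(c[2], c[3], 2, rng)
        self.relu = [_ReLU() for _ in range(6)]
        fused_in = sum(c)
        self.fusion_spec = FusionSpec(branch_scales=(1, 2, 4, 8), fused_channels=24)
        self.mix1 = _Conv1x1(fused_in, self.fusion_spec.fused_channels, rng)
        self.mix2 = _Conv1x1(self.fusion_spec.fused_channels, self.fusion_spec.fused_channels, rng)
        self.head_seg = _Conv1x1(self.fusion_spec.fused_channels, 1, rng)
        self.head_vec = _Conv1x1(self.fusion_spec.fused_channels, 2 * n_keypoints, rng)
        self._ups: list[_Upsample] = []
        self._split: list[int] = list(c)

    @property
    def params(self) -> list[_Param]:
        ps: list[_Param] = []
        for layer in (
            self.conv1, self.conv2, self.conv3, self.conv4,
            self.mix1, self.mix2, self.head_seg, self.head_vec,
        ):
            ps.extend(layer.params)
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    @staticmethod
    def _with_coords(images: np.ndarray) -> np.ndarray:
        B, _, H, W = images.shape
        ys = np.linspace(-1, 1, H, dtype=np.float32)
        xs = np.linspace(-1, 1, W, dtype=np.float32)
        cy = np.broadcast_to(ys[None, None, :, None], (B, 1, H, W))
        cx = np.broadcast_to(xs[None, None, None, :], (B, 1, H, W))
        return np.concatenate([images, cy, cx], axis=1)

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self._with_coords(images.astype(np.float32))
        H, W = x.shape[2], x.shape[3]
        b1 = self.relu[0].forward(self.conv1.forward(x))
        b2 = self.relu[1].forward(self.conv2.forward(b1))
        b3 = self.relu[2].forward(self.conv3.forward(b2))
        b4 = self.relu[3].forward(self.conv4.forward(b3))
        self._ups = [_Upsample(H, W) for _ in range(3)]
        cat = np.concatenate(
            [b1, self._ups[0].forward(b2), self._ups[1].forward(b3), self._ups[2].forward(b4)],
            axis=1,
        )
        f = self.relu[4].forward(self.mix1.forward(cat))
        f = self.relu[5].forward(self.mix2.forward(f))
        return self.head_seg.forward(f), self.head_vec.forward(f)

    def backward(self, dseg: np.ndarray, dvec: np.ndarray) -> None:
        df = self.head_seg.backward(dseg) + self.head_vec.backward(dvec)
        df = self.mix2.backward(self.relu[5].backward(df))
        dcat = self.mix1.backward(self.relu[4].backward(df))
        c = np.cumsum(self._split)
        d1 = dcat[:, : c[0]]
        d2 = self._ups[0].backward(dcat[:, c[0] : c[1]])
        d3 = self._ups[1].backward(dcat[:, c[1] : c[2]])
        d4 = self._ups[2].backward(dcat[:, c[2] : c[3]])
        d3 = d3 + self.conv4.backward(self.relu[3].backward(d4))
        d2 = d2 + self.conv3.backward(self.relu[2].backward(d3))
        d1 = d1 + self.conv2.backward(self.relu[1].backward(d2))
        self.conv1.backward(self.relu[0].backward(d1))

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class _Adam:
    """Adam with first-moment decay 0.9 (the configured momentum) and
    second-moment decay 0.999."""

    def __init__(self, params: list[_Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p in self.params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def learning_rate_at(epoch: int, initial_lr: float = 1e-3, halve_every: int = 20) -> float:
    """Step schedule: the rate halves at every ``halve_every``-epoch boundary."""
    return initial_lr * 0.5 ** (epoch // halve_every)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _batch_losses_and_grads(
    seg_logits: np.ndarray, vec_pred: np.ndarray, segs: np.ndarray, vfields: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Mean-per-pixel BCE-with-logits and masked Smooth-L1, with gradients."""
    B = seg_logits.shape[0]
    probs = _sigmoid(seg_logits[:, 0])
    probs_c = np.clip(probs, _CLAMP, 1 - _CLAMP)
    g = segs.astype(np.float32)
    bce = float(-(g * np.log(probs_c) + (1 - g) * np.log(1 - probs_c)).mean())
    dseg = ((probs - g) / g[0].size / B)[:, None].astype(np.float32)

    n2 = vec_pred.shape[1]
    mask = segs > 0  # (B, H, W)
    m = max(int(mask.sum()), 1)
    gt = vfields.transpose(0, 1, 4, 2, 3).reshape(B, n2, *segs.shape[1:])
    diff = (vec_pred - gt) * mask[:, None]
    vec = float(smooth_l1(diff).sum() / (m * n2))
    dvec = (np.clip(diff, -1.0, 1.0) * mask[:, None] / (m * n2)).astype(np.float32)
    return bce, vec, dseg, dvec


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(e) for e in self.epochs)


def train_toy(
    dataset: list,
    epochs: int = 20,
    initial_lr: float = 1e-3,
    halve_every: int = 20,
    seed: int = 0,
    batch_size: int = 8,
    val_fraction: float = 0.15,
    augment_config=None,
) -> tuple[TinyPoseNet, TrainHistory]:
    """Train the stand-in network on simulator samples.

    ``dataset`` is a list of ``Sample`` objects (at least 50). Training uses
    mean-convention seg + vector losses; validation tracks the combined loss
    on a held-out split without augmentation. Adam with beta1 = 0.9; the
    learning rate halves every ``halve_every`` epochs. Deterministic given
    the seed up to floating-point reduction order. Raises on divergence.
    """
    from .augmentation import AugmentationConfig, augment_sample

    if len(dataset) < 50:
        raise ValueError("need at least 50 frames to train")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(len(dataset) * val_fraction))
    order = rng.permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]
    n_kp = dataset[0].vfield.shape[0]
    net = TinyPoseNet(n_keypoints=n_kp, seed=seed)
    opt = _Adam(net.params, lr=initial_lr)
    aug = augment_config if augment_config is not None else AugmentationConfig()
    history = TrainHistory()

    def eval_val() -> tuple[float, float, float]:
        seg_tot = vec_tot = 0.0
        for s in val_set:
            logits, vec = net.forward(_to_input(s.image)[None])
            bce, vl, _, _ = _batch_losses_and_grads(
                logits, vec, s.seg[None], s.vfield[None]
            )
            seg_tot += bce
            vec_tot += vl
        return seg_tot / n_val, vec_tot / n_val, (seg_tot + vec_tot) / n_val

    vs0, vv0, v0 = eval_val()
    history.epochs.append(
        {"epoch": 0, "lr": learning_rate_at(0, initial_lr, halve_every),
         "val_seg": vs0, "val_vec": vv0, "val_loss": v0, "train_loss": None}
    )
    for epoch in range(epochs):
        opt.lr = learning_rate_at(epoch, initial_lr, halve_every)
        perm = rng.permutation(len(train_set))
        running = 0.0
        steps = 0
        for s0 in range(0, len(perm), batch_size):
            batch_idx = perm[s0 : s0 + batch_size]
            imgs, segs, vfs = [], [], []
            for bi in batch_idx:
                s = augment_sample(train_set[bi], aug, rng)
                imgs.append(_to_input(s.image))
                segs.append(s.seg)
                vfs.append(s.vfield)
            images = np.stack(imgs)
            segs_a = np.stack(segs)
            vfs_a = np.stack(vfs)
            logits, vec = net.forward(images)
            bce, vl, dseg, dvec = _batch_losses_and_grads(logits, vec, segs_a, vfs_a)
            loss = bce + vl
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch} step {steps}: {loss}"
                )
            net.zero_grad()
            net.backward(dseg, dvec)
            opt.step()
            running += loss
            steps += 1
        vs, vv, v = eval_val()
        history.epochs.append(
            {"epoch": epoch + 1, "lr": opt.lr, "train_loss": running / max(steps, 1),
             "val_seg": vs, "val_vec": vv, "val_loss": v}
        )
    return net, history


def _to_input(image: np.ndarray) -> np.ndarray:
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)


def predict_maps(net: TinyPoseNet, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run the network on one image and return voting-ready maps.

    Returns ``(seg, vfield)`` where seg is the thresholded (0.5) binary mask
    and vfield is (n, H, W, 2) with predicted vectors normalised to unit
    length on instrument pixels and zero elsewhere.
    """
    logits, vec = net.forward(_to_input(image)[None])
    seg = (_sigmoid(logits[0, 0]) > 0.5).astype(np.uint8)
    n = net.n_keypoints
    h, w = seg.shape
    vf = vec[0].reshape(n, 2, h, w).transpose(0, 2, 3, 1).astype(np.float32)
    norm = np.linalg.norm(vf, axis=3, keepdims=True)
    vf = np.divide(vf, norm, out=np.zeros_like(vf), where=norm > 1e-9)
    vf[:, seg == 0] = 0.0
    return seg, vf
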