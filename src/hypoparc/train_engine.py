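"""Losses, class weighting, augmentation, modality dropout and the optimizer.

The training loop optimizes a combined loss (median-frequency-weighted
cross-entropy plus soft Dice) with AdamW, a step learning-rate schedule
(0.05 -> 0.005 after 70 of 100 epochs at full scale), per-example modality
dropout after a 10-epoch warm-up, and per-batch internal scale jitter fed to
the network's resolution-normalization.  All randomness flows from one master
seed through independent named streams, so a run is reproducible from
(seed, config, dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .lut_io import (
    HypoparcError,
    ParameterError,
    SliceStack,
    Volume,
)
from .network.model import FCNN

MODALITY_MODES = ("t1t2", "t1_only", "t2_only")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr_initial: float = 0.05
    lr_late: float = 0.005
    lr_switch_epoch: int = 70
    weight_decay: float = 1e-4
    modality_dropout_start_epoch: int = 10
    affine_translation_mm: Tuple[float, float] = (-15.0, 15.0)
    affine_rotation_deg: Tuple[float, float] = (-10.0, 10.0)
    affine_scale: Tuple[float, float] = (0.85, 1.15)
    bias_coeff_range: Tuple[float, float] = (-0.5, 0.5)
    internal_scale_range: Tuple[float, float] = (0.85, 1.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_late < self.lr_initial):
            raise ParameterError("need 0 < lr_late < lr_initial")
        if not (0 <= self.lr_switch_epoch < self.epochs):
            raise ParameterError("lr_switch_epoch must precede epochs")
        for r in (
            self.affine_translation_mm,
            self.affine_rotation_deg,
            self.affine_scale,
            self.bias_coeff_range,
            self.internal_scale_range,
        ):
            if r[0] > r[1]:
                raise ParameterError(f"range {r} is not ordered")

    def lr_at(self, epoch: int) -> float:
        return self.lr_initial if epoch < self.lr_switch_epoch else self.lr_late


def rng_streams(seed: int, names: Sequence[str]) -> Dict[str, np.random.Generator]:
    """One independent generator per concern, all derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# Class weighting and loss
# ---------------------------------------------------------------------------

def median_frequency_weights(label_histogram: Dict[int, int]) -> Dict[int, float]:
    """w_c = median(f) / f_c over classes with nonzero count (else weight 0)."""
    if not label_histogram:
        raise HypoparcError("empty label histogram")
    counts = {c: int(n) for c, n in label_histogram.items()}
    total = sum(counts.values())
    if total <= 0:
        raise HypoparcError("label histogram has no voxels")
    freqs = {c: n / total for c, n in counts.items() if n > 0}
    med = float(np.median(list(freqs.values())))
    return {c: (med / freqs[c] if c in freqs else 0.0) for c in counts}


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def combined_loss(
    logits: np.ndarray,
    target: np.ndarray,
    class_weights: Optional[np.ndarray] = None,
    eps: float = 1e-6,
) -> Tuple[float, np.ndarray, Dict[str, float]]:
    """Weighted cross-entropy plus soft Dice; returns (loss, dlogits, parts).

    ``logits``: (N, C, H, W); ``target``: (N, H, W) integer labels < C.
    The Dice term uses the squared-denominator soft form
    (2*sum(p*g)+eps)/(sum(p^2)+sum(g^2)+eps) averaged over foreground
    classes, so a class absent from both prediction and target scores a
    perfect 1 and self-agreement is exact.
    """
    n, c, h, w = logits.shape
    if target.shape != (n, h, w):
        raise HypoparcError("target shape must be (N, H, W)")
    if target.min() < 0 or target.max() >= c:
        raise HypoparcError("label id out of range for the class axis")
    if class_weights is None:
        class_weights = np.ones(c)
    class_weights = np.asarray(class_weights, dtype=np.float64)

    p = softmax(logits)
    onehot = np.zeros_like(p)
    nn, hh, ww = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    onehot[nn, target, hh, ww] = 1.0

    # cross-entropy, mean over pixels of w[y] * (-log p_y)
    wmap = class_weights[target]
    npix = n * h * w
    logp = np.log(np.clip(p, 1e-12, None))
    ce = float(-(wmap * np.take_along_axis(logp, target[:, None], axis=1)[:, 0]).sum() / npix)
    dlog_ce = wmap[:, None] * (p - onehot) / npix

    # soft Dice over foreground classes
    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    denom = (p**2).sum(axis=axes) + (onehot).sum(axis=axes)
    dice_c = (2.0 * inter + eps) / (denom + eps)
    fg = slice(1, c)
    n_fg = c - 1
    dice_loss = float(1.0 - dice_c[fg].mean()) if n_fg > 0 else 0.0

    dldp = np.zeros_like(p)
    if n_fg > 0:
        num = (2.0 * inter + eps)[fg]
        den = (denom + eps)[fg]
        # d dice_c / d p = (2g*den - num*2p) / den^2 ; loss derivative is -mean
        dldp[:, fg] = -(2.0 * onehot[:, fg] * den[None, :, None, None]
                        - num[None, :, None, None] * 2.0 * p[:, fg]) / (
            den[None, :, None, None] ** 2
        ) / n_fg
    # chain through softmax
    dlog_dice = p * (dldp - (dldp * p).sum(axis=1, keepdims=True))

    loss = ce + dice_loss
    return loss, dlog_ce + dlog_dice, {"ce": ce, "dice": dice_loss}


# ---------------------------------------------------------------------------
# Modality dropout
# ---------------------------------------------------------------------------

def sample_modality_mode(
    epoch: int, rng: np.random.Generator, start_epoch: int = 10
) -> str:
    """Uniform over {t1t2, t1_only, t2_only} after warm-up, else always t1t2."""
    if epoch < 0:
        raise ParameterError("epoch must be >= 0")
    if epoch < start_epoch:
        return "t1t2"
    return MODALITY_MODES[rng.integers(0, 3)]


# ---------------------------------------------------------------------------
# Augmentations (volume level)
# ---------------------------------------------------------------------------

def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    return rz @ ry @ rx


def sample_affine(rng: np.random.Generator, cfg: TrainConfig) -> Tuple[np.ndarray, np.ndarray, float]:
    trans = rng.uniform(*cfg.affine_translation_mm, size=3)
    rot = rng.uniform(*cfg.affine_rotation_deg, size=3)
    scale = rng.uniform(*cfg.affine_scale)
    return trans, rot, scale


def _apply_affine(vol: Volume, trans_mm, rot_deg, scale, order: int) -> Volume:
    r = _rotation_matrix(np.asarray(rot_deg)) * scale
    vs = np.asarray(vol.voxel_size)
    # matrix in voxel space: diag(1/vs) R diag(vs); rotate about the center
    m = np.diag(1.0 / vs) @ r @ np.diag(vs)
    center = (np.asarray(vol.shape) - 1) / 2.0
    inv = np.linalg.inv(m)
    offset = center - inv @ (center + np.asarray(trans_mm) / vs)
    data = ndimage.affine_transform(
        vol.data.astype(np.float64), inv, offset=offset, order=order, mode="nearest"
    )
    if order == 0:
        data = data.astype(vol.data.dtype)
    return Volume(data, vol.voxel_size, vol.affine, vol.modality)


def augment_affine(
    vols: Dict[str, Volume], rng: np.random.Generator, cfg: TrainConfig
) -> Dict[str, Volume]:
    """One sampled transform applied identically to all modalities (+NN labels)."""
    trans, rot, scale = sample_affine(rng, cfg)
    out = {}
    for key, v in vols.items():
        order = 0 if v.modality == "LABEL" else 1
        out[key] = _apply_affine(v, trans, rot, scale, order)
    return out


def polynomial_bias_field(
    shape: Tuple[int, int, int], coeffs: np.ndarray, order: int = 3
) -> np.ndarray:
    """exp(P(x)) for an order-3 polynomial over [-1,1]^3 normalized coordinates."""
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) if s > 1 else np.zeros(s) for s in shape], indexing="ij"
    )
    exponents = [
        (i, j, k)
        for i in range(order + 1)
        for j in range(order + 1)
        for k in range(order + 1)
        if i + j + k <= order
    ]
    if len(coeffs) != len(exponents):
        raise ParameterError(f"bias field needs {len(exponents)} coefficients")
    p = np.zeros(shape)
    for c, (i, j, k) in zip(coeffs, exponents):
        p += c * grids[0] ** i * grids[1] ** j * grids[2] ** k
    return np.exp(p)


N_BIAS_COEFFS = 20  # monomials x^i y^j z^k with i+j+k <= 3


def augment_bias_field(
    v: Volume, rng: np.random.Generator, coeff_range: Tuple[float, float] = (-0.5, 0.5)
) -> Volume:
    """Multiply an intensity volume by a smooth, strictly positive bias field."""
    if v.modality == "LABEL":
        raise HypoparcError("bias-field augmentation must never touch label volumes")
    coeffs = rng.uniform(*coeff_range, size=N_BIAS_COEFFS)
    field_ = polynomial_bias_field(v.shape, coeffs)
    return Volume(v.data * field_, v.voxel_size, v.affine, v.modality)


def external_scale_augment(
    vols: Dict[str, Volume],
    rng: np.random.Generator,
    res_range: Tuple[float, float],
) -> Dict[str, Volume]:
    """Resample to a voxel size drawn from ``res_range`` (simulated acquisition)."""
    if res_range[0] <= 0:
        raise ParameterError("resolution range must be positive")
    target = float(rng.uniform(*res_range))
    out = {}
    for key, v in vols.items():
        zoom = np.asarray(v.voxel_size) / target
        order = 0 if v.modality == "LABEL" else 1
        data = ndimage.zoom(v.data.astype(np.float64), zoom, order=order, mode="nearest")
        if order == 0:
            data = data.astype(v.data.dtype)
        scale = np.diag([target / s for s in v.voxel_size] + [1.0])
        affine = v.affine @ scale
        out[key] = Volume(data, (target, target, target), affine, v.modality)
    return out


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay (applied to conv kernels only)."""

    def __init__(self, params, lr: float, weight_decay: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if p.decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def dataset_histogram(stacks: Sequence[SliceStack], n_classes: int) -> Dict[int, int]:
    hist = {c: 0 for c in range(n_classes)}
    for s in stacks:
        ids, counts = np.unique(s.label, return_counts=True)
        for i, n in zip(ids, counts):
            hist[int(i)] += int(n)
    return hist


def train(
    net: FCNN,
    stacks: Sequence[SliceStack],
    cfg: TrainConfig,
) -> Dict[str, List]:
    """Run the optimization loop over labeled slice stacks; returns the history.

    Each stack must carry a center-slice label map and per-modality arrays.
    Modality dropout is sampled per training example; the internal scale
    jitter of the resolution-normalization is sampled once per batch.
    """
    stacks = list(stacks)
    if not stacks:
        raise HypoparcError("empty dataset")
    n_classes = net.cfg.n_classes
    hist = dataset_histogram(stacks, n_classes)
    wdict = median_frequency_weights(hist)
    weights = np.array([wdict.get(c, 0.0) for c in range(n_classes)])

    streams = rng_streams(cfg.seed, ["dropout", "scale", "shuffle"])
    opt = AdamW(net.parameters(), lr=cfg.lr_initial, weight_decay=cfg.weight_decay)
    history: Dict[str, List] = {"epoch": [], "loss": [], "lr": [], "mode_counts": []}

    hetero = net.cfg.hetero_modal
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        order = streams["shuffle"].permutation(len(stacks))
        mode_counts = {m: 0 for m in MODALITY_MODES}
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [stacks[i] for i in idx]
            jitter = float(streams["scale"].uniform(*cfg.internal_scale_range))
            has_t2 = "T2" in batch[0].arrays
            # modality dropout is sampled per training example ...
            if hetero and has_t2:
                modes = [
                    sample_modality_mode(
                        epoch, streams["dropout"], cfg.modality_dropout_start_epoch
                    )
                    for _ in batch
                ]
            else:
                modes = ["t1t2" if has_t2 else "t1_only"] * len(batch)
            res = batch[0].in_plane_resolution
            net.zero_grad()
            batch_loss = 0.0
            # ... then examples sharing a mode run as one sub-batch forward
            for mode in MODALITY_MODES:
                sel = [b for b, m in zip(batch, modes) if m == mode]
                if not sel:
                    continue
                mode_counts[mode] += len(sel)
                inputs = {}
                if mode in ("t1t2", "t1_only"):
                    inputs["T1"] = np.stack([b.arrays["T1"] for b in sel])
                if mode in ("t1t2", "t2_only"):
                    inputs["T2"] = np.stack([b.arrays["T2"] for b in sel])
                y = np.stack([b.label for b in sel])
                frac = len(sel) / len(batch)
                logits = net.forward(inputs, res, scale_jitter=jitter, train=True)
                loss, dlogits, _ = combined_loss(logits, y, weights)
                net.backward(dlogits * frac)
                batch_loss += loss * frac
            opt.step()
            losses.append(batch_loss)
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
        history["mode_counts"].append(mode_counts)
    return history
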