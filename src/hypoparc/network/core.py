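"""Architecture primitives: fusion module, resolution-normalization, CDB.

The fusion module merges modality-specific feature maps by a normalized
learnable weighted sum

    F_fused = |W_T1| / (|W_T1| + |W_T2|) * F_T1 + |W_T2| / (|W_T1| + |W_T2|) * F_T2

with both global scalar weights initialized at 0.5.  Zeroing one weight makes
the output identical (to machine precision) to the remaining branch, which is
how a missing modality is handled at inference time.

Resolution-normalization interpolates feature maps from the native in-plane
voxel size to a fixed internal base resolution (default 1.0 mm) and back,
making the inner network voxel-size independent.  Because downscaling is not
injective on integer grid sizes, the op records the source grid size so that
the ``to_native`` direction restores it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ..lut_io import HypoparcError, ParameterError, ShapeError
from .layers import BatchNorm2d, Conv2d, Param, PReLU, bilinear_resize, maxout, maxout_backward


@dataclass
class FeatureMap:
    """A (C, H, W) activation array annotated with its in-plane resolution (mm)."""

    data: np.ndarray
    resolution: Tuple[float, float]
    source_shape: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError("FeatureMap data must be (C, H, W)")
        if not np.all(np.isfinite(self.data)):
            raise HypoparcError("FeatureMap contains non-finite values")
        if isinstance(self.resolution, (int, float)):
            self.resolution = (float(self.resolution), float(self.resolution))
        self.resolution = tuple(float(r) for r in self.resolution)


@dataclass
class FusionWeights:
    w_t1: float = 0.5
    w_t2: float = 0.5


@dataclass
class NetworkConfig:
    n_classes: int
    inner_channels: int = 80
    outer_channels: int = 64
    stack_thickness: int = 7
    base_resolution: float = 1.0
    n_scales: int = 5
    convs_per_block: int = 4
    kernel: Tuple[int, int] = (3, 3)
    hetero_modal: bool = True

    def __post_init__(self) -> None:
        if self.inner_channels < self.outer_channels or self.outer_channels < 1:
            raise ParameterError("need inner_channels >= outer_channels >= 1")
        if self.base_resolution <= 0:
            raise ParameterError("base_resolution must be positive")
        if self.stack_thickness % 2 != 1:
            raise ParameterError("stack_thickness must be odd")


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fusion_coefficients(w_t1: float, w_t2: float) -> Tuple[float, float]:
    s = abs(w_t1) + abs(w_t2)
    if s == 0:
        raise HypoparcError("degenerate fusion weights: |W_T1| + |W_T2| = 0")
    return abs(w_t1) / s, abs(w_t2) / s


def fuse(
    f_t1: Optional[FeatureMap],
    f_t2: Optional[FeatureMap],
    w: FusionWeights,
) -> FeatureMap:
    """Normalized weighted sum of modality feature maps (absent branch -> weight 0)."""
    if f_t1 is None and f_t2 is None:
        raise HypoparcError("fusion requires at least one modality")
    if f_t1 is None:
        return FeatureMap(f_t2.data.copy(), f_t2.resolution, f_t2.source_shape)
    if f_t2 is None:
        return FeatureMap(f_t1.data.copy(), f_t1.resolution, f_t1.source_shape)
    if f_t1.data.shape != f_t2.data.shape:
        raise ShapeError("fusion inputs must share (C, H, W)")
    a1, a2 = fusion_coefficients(w.w_t1, w.w_t2)
    return FeatureMap(a1 * f_t1.data + a2 * f_t2.data, f_t1.resolution, f_t1.source_shape)


class FusionModule:
    """Trainable fusion with two global scalar weights (init 0.5 each)."""

    def __init__(self, name: str = "fusion"):
        self.w_t1 = Param(np.array(0.5), name=f"{name}.w_t1")
        self.w_t2 = Param(np.array(0.5), name=f"{name}.w_t2")
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w_t1, self.w_t2]

    def forward(self, x1: Optional[np.ndarray], x2: Optional[np.ndarray]) -> np.ndarray:
        if x1 is None and x2 is None:
            raise HypoparcError("fusion requires at least one modality")
        if x1 is None or x2 is None:
            # absent modality: its weight is forced to zero -> exact passthrough
            self._cache = ("pass", x1 is not None)
            return x1 if x1 is not None else x2
        a1, a2 = fusion_coefficients(float(self.w_t1.value), float(self.w_t2.value))
        self._cache = ("both", x1, x2, a1, a2)
        return a1 * x1 + a2 * x2

    def backward(self, dout: np.ndarray):
        kind = self._cache[0]
        if kind == "pass":
            t1_present = self._cache[1]
            self._cache = None
            return (dout, None) if t1_present else (None, dout)
        _, x1, x2, a1, a2 = self._cache
        w1, w2 = float(self.w_t1.value), float(self.w_t2.value)
        s = abs(w1) + abs(w2)
        g1 = float((dout * x1).sum())
        g2 = float((dout * x2).sum())
        # d a1 / d w1 = sign(w1) |w2| / s^2 ; d a2 / d w1 = -sign(w1) |w2| / s^2
        sg1, sg2 = np.sign(w1) if w1 != 0 else 0.0, np.sign(w2) if w2 != 0 else 0.0
        self.w_t1.grad += (g1 - g2) * sg1 * abs(w2) / s**2
        self.w_t2.grad += (g2 - g1) * sg2 * abs(w1) / s**2
        self._cache = None
        return a1 * dout, a2 * dout


# ---------------------------------------------------------------------------
# Resolution-normalization
# ---------------------------------------------------------------------------

def normalized_size(n: int, scale: float) -> int:
    if scale <= 0:
        raise ParameterError("scale factor must be positive")
    return max(1, int(np.floor(n * scale + 0.5)))


def resolution_normalize(
    f: FeatureMap,
    native_res: float | Tuple[float, float],
    base_res: float,
    direction: str,
    scale_jitter: float = 1.0,
) -> FeatureMap:
    """Interpolate a feature map between native and internal base resolution.

    ``to_base`` scales each in-plane axis by s_i = (native_i / base) * jitter;
    ``to_native`` inverts, restoring the recorded source grid size exactly
    when available.
    """
    if isinstance(native_res, (int, float)):
        native_res = (float(native_res), float(native_res))
    if any(r <= 0 for r in native_res) or base_res <= 0 or scale_jitter <= 0:
        raise ParameterError("resolutions and scale jitter must be positive")
    c, h, w = f.data.shape
    if direction == "to_base":
        sh = native_res[0] / base_res * scale_jitter
        sw = native_res[1] / base_res * scale_jitter
        out_hw = (normalized_size(h, sh), normalized_size(w, sw))
        y, _ = bilinear_resize(f.data, out_hw)
        return FeatureMap(y, (base_res, base_res), source_shape=(h, w))
    if direction == "to_native":
        sh = base_res / (native_res[0] * scale_jitter)
        sw = base_res / (native_res[1] * scale_jitter)
        out_hw = f.source_shape or (normalized_size(h, sh), normalized_size(w, sw))
        y, _ = bilinear_resize(f.data, out_hw)
        return FeatureMap(y, native_res, source_shape=None)
    raise ParameterError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Competitive dense block
# ---------------------------------------------------------------------------

class CompetitiveDenseBlock:
    """Four PReLU -> Conv(3x3) -> BN sequences with competitive (max) connections.

    ``input_variant`` replaces the first PReLU with a BN over the raw inputs
    (used for the modality-specific blocks and the second encoder block).
    After each layer the output competes (elementwise max) with the running
    representation whenever the channel counts agree.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        variant: str = "standard",
        n_convs: int = 4,
        name: str = "cdb",
    ):
        if variant not in ("standard", "input_variant"):
            raise ParameterError(f"unknown CDB variant {variant!r}")
        self.cin, self.cout, self.variant = cin, cout, variant
        self.bn_in = BatchNorm2d(cin, name=f"{name}.bn_in") if variant == "input_variant" else None
        self.acts: List[Optional[PReLU]] = []
        self.convs: List[Conv2d] = []
        self.bns: List[BatchNorm2d] = []
        c_prev = cin
        for i in range(n_convs):
            if i == 0 and variant == "input_variant":
                self.acts.append(None)  # BN over inputs replaces the first PReLU
            else:
                self.acts.append(PReLU(name=f"{name}.prelu{i}"))
            self.convs.append(Conv2d(c_prev, cout, 3, rng, name=f"{name}.conv{i}"))
            self.bns.append(BatchNorm2d(cout, name=f"{name}.bn{i}"))
            c_prev = cout
        self._trace = None

    def params(self) -> List[Param]:
        ps: List[Param] = []
        if self.bn_in is not None:
            ps += self.bn_in.params()
        for act, conv, bn in zip(self.acts, self.convs, self.bns):
            if act is not None:
                ps += act.params()
            ps += conv.params()
            ps += bn.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not np.all(np.isfinite(x)):
            raise HypoparcError("non-finite values in CDB input")
        trace = []
        y = x
        for i, (act, conv, bn) in enumerate(zip(self.acts, self.convs, self.bns)):
            if i == 0 and self.bn_in is not None:
                a = self.bn_in.forward(y, train)
            elif act is not None:
                a = act.forward(y)
            else:
                a = y
            t = bn.forward(conv.forward(a), train)
            if t.shape == y.shape:
                out, mask = maxout(t, y)
                trace.append(("max", mask))
            else:
                out, _ = t, None
                trace.append(("plain", None))
            y = out
        self._trace = trace
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dy = dout
        dskip_total = None
        for i in reversed(range(len(self.convs))):
            kind, mask = self._trace[i]
            if kind == "max":
                dt, dprev = maxout_backward(dy, mask)
            else:
                dt, dprev = dy, None
            da = self.convs[i].backward(self.bns[i].backward(dt))
            if i == 0 and self.bn_in is not None:
                da = self.bn_in.backward(da)
            elif self.acts[i] is not None:
                da = self.acts[i].backward(da)
            dy = da if dprev is None else da + dprev
        self._trace = None
        return dy
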