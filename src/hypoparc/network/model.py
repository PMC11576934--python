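"""The hetero-modal, voxel-size-independent 2D F-CNN.

UNet-type layout: an input CDB at native resolution (two modality-specific
input CDBs plus the fusion module in hetero-modal mode), an interpolation to
the internal base resolution, an encoder arm of CDBs with 2x2 max-pooling,
a bottleneck CDB, a decoder arm with index-preserving unpooling and
competitive (maxout) skip connections, an interpolation back to native
resolution, an output CDB that concatenates the upsampled decoder features
with the input-block skip, and a 1x1 classifier.  Segmentation logits are
therefore produced at the native in-plane grid of the input.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..lut_io import HypoparcError, LookupTable, ParameterError, ShapeError, merge_lateral_labels
from .core import CompetitiveDenseBlock, FusionModule, NetworkConfig
from .layers import (
    Conv2d,
    Param,
    bilinear_resize,
    bilinear_resize_backward,
    maxout,
    maxout_backward,
    maxpool2x2,
    maxpool_backward,
    maxunpool2x2,
    maxunpool_backward,
)

PLANES = ("axial", "coronal", "sagittal")


class ConfigurationError(HypoparcError):
    pass


class FCNN:
    """One per-plane 2.5D network (see module docstring for the layout)."""

    def __init__(self, cfg: NetworkConfig, plane: str, seed: int = 0):
        if plane not in PLANES:
            raise ConfigurationError(f"unknown plane {plane!r}")
        self.cfg = cfg
        self.plane = plane
        rng = np.random.default_rng(seed)
        inner, outer = cfg.inner_channels, cfg.outer_channels
        t = cfg.stack_thickness
        nc = cfg.convs_per_block

        if cfg.hetero_modal:
            self.inp_t1 = CompetitiveDenseBlock(t, outer, rng, "input_variant", nc, "inp_t1")
            self.inp_t2 = CompetitiveDenseBlock(t, outer, rng, "input_variant", nc, "inp_t2")
            self.fusion = FusionModule()
        else:
            self.inp = CompetitiveDenseBlock(t, outer, rng, "input_variant", nc, "inp")

        self.encoders: List[CompetitiveDenseBlock] = []
        for i in range(cfg.n_scales - 1):
            cin = outer if i == 0 else inner
            variant = "input_variant" if i == 0 else "standard"
            self.encoders.append(
                CompetitiveDenseBlock(cin, inner, rng, variant, nc, f"enc{i + 1}")
            )
        self.bottleneck = CompetitiveDenseBlock(inner, inner, rng, "standard", nc, "bottleneck")
        self.decoders: List[CompetitiveDenseBlock] = [
            CompetitiveDenseBlock(inner, inner, rng, "standard", nc, f"dec{i + 1}")
            for i in range(cfg.n_scales - 1)
        ]
        self.outp = CompetitiveDenseBlock(inner + outer, inner, rng, "standard", nc, "outp")
        self.classifier = Conv2d(inner, cfg.n_classes, 1, rng, name="classifier")
        self._ctx = None

    # -- parameters ---------------------------------------------------------
    def _blocks(self):
        blocks = []
        if self.cfg.hetero_modal:
            blocks += [self.inp_t1, self.inp_t2]
        else:
            blocks += [self.inp]
        blocks += self.encoders + [self.bottleneck] + self.decoders + [self.outp]
        return blocks

    def parameters(self) -> List[Param]:
        ps: List[Param] = []
        for b in self._blocks():
            ps += b.params()
        if self.cfg.hetero_modal:
            ps += self.fusion.params()
        ps += self.classifier.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        inputs: Dict[str, np.ndarray],
        native_res: float | Tuple[float, float],
        scale_jitter: float = 1.0,
        train: bool = False,
    ) -> np.ndarray:
        """Run the network; returns logits of shape (N, n_classes, H, W)."""
        if isinstance(native_res, (int, float)):
            native_res = (float(native_res), float(native_res))
        if scale_jitter <= 0:
            raise ParameterError("scale_jitter must be positive")
        x1 = inputs.get("T1")
        x2 = inputs.get("T2")
        if x1 is None and x2 is None:
            raise HypoparcError("at least one modality required")
        ctx: Dict[str, object] = {"present": (x1 is not None, x2 is not None)}

        if self.cfg.hetero_modal:
            h1 = self.inp_t1.forward(x1, train) if x1 is not None else None
            h2 = self.inp_t2.forward(x2, train) if x2 is not None else None
            fused = self.fusion.forward(h1, h2)
        else:
            x = x1 if x1 is not None else x2
            fused = self.inp.forward(x, train)
        n, _, hh, ww = fused.shape

        # first scale transition: native -> base resolution
        base = self.cfg.base_resolution
        sh = native_res[0] / base * scale_jitter
        sw = native_res[1] / base * scale_jitter
        from .core import normalized_size

        z, rn_down = bilinear_resize(fused, (normalized_size(hh, sh), normalized_size(ww, sw)))
        ctx["rn_down"] = rn_down

        skips, pools = [], []
        e = z
        for enc in self.encoders:
            e = enc.forward(e, train)
            skips.append(e)
            e, cache = maxpool2x2(e)
            pools.append(cache)
        d = self.bottleneck.forward(e, train)

        masks = []
        for dec, skip, cache in zip(self.decoders, reversed(skips), reversed(pools)):
            u = maxunpool2x2(d, cache)
            m, mask = maxout(u, skip)
            masks.append(mask)
            d = dec.forward(m, train)

        # last scale transition: base -> native resolution (restore exact size)
        up, rn_up = bilinear_resize(d, (hh, ww))
        ctx["rn_up"] = rn_up
        cat = np.concatenate([up, fused], axis=1)
        o = self.outp.forward(cat, train)
        logits = self.classifier.forward(o)
        ctx.update(pools=pools, masks=masks, split=up.shape[1])
        self._ctx = ctx
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        ctx = self._ctx
        if ctx is None:
            raise HypoparcError("backward called before forward")
        dcat = self.outp.backward(self.classifier.backward(dlogits))
        split = ctx["split"]
        dup, dfused = dcat[:, :split], dcat[:, split:]
        dd = bilinear_resize_backward(dup, ctx["rn_up"])

        dskips = [None] * len(self.encoders)
        for i in reversed(range(len(self.decoders))):
            dm = self.decoders[i].backward(dd)
            du, dskip = maxout_backward(dm, ctx["masks"][i])
            j = len(self.encoders) - 1 - i
            dskips[j] = dskip
            dd = maxunpool_backward(du, ctx["pools"][len(self.encoders) - 1 - i])

        db = self.bottleneck.backward(dd)
        for i in reversed(range(len(self.encoders))):
            de = maxpool_backward(db, ctx["pools"][i]) + dskips[i]
            db = self.encoders[i].backward(de)

        dz = bilinear_resize_backward(db, ctx["rn_down"]) + dfused
        if self.cfg.hetero_modal:
            dh1, dh2 = self.fusion.backward(dz)
            if dh1 is not None:
                self.inp_t1.backward(dh1)
            if dh2 is not None:
                self.inp_t2.backward(dh2)
        else:
            self.inp.backward(dz)
        self._ctx = None

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.parameters()}
        for b in self._blocks():
            bns = list(b.bns) + ([b.bn_in] if b.bn_in is not None else [])
            for bn in bns:
                base = bn.gamma.name.rsplit(".", 1)[0]
                state[f"{base}.running_mean"] = bn.running_mean
                state[f"{base}.running_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: Dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for b in self._blocks():
            bns = list(b.bns) + ([b.bn_in] if b.bn_in is not None else [])
            for bn in bns:
                base = bn.gamma.name.rsplit(".", 1)[0]
                bn.running_mean[...] = state[f"{base}.running_mean"]
                bn.running_var[...] = state[f"{base}.running_var"]


def build_fcnn(
    cfg: NetworkConfig, plane: str, seed: int = 0, lut: Optional[LookupTable] = None
) -> FCNN:
    """Build one per-plane F-CNN; with a LUT given, validate the class head.

    Axial/coronal heads carry one class per label plus background; the
    sagittal head uses the lateral-merged table (plus background).
    """
    if lut is not None:
        if plane == "sagittal":
            merged, _ = merge_lateral_labels(lut)
            expected = len(merged) + 1
        else:
            expected = len(lut) + 1
        if cfg.n_classes != expected:
            raise ConfigurationError(
                f"{plane} head must have {expected} classes for this LUT, got {cfg.n_classes}"
            )
    return FCNN(cfg, plane, seed=seed)


def count_parameters(net: FCNN) -> int:
    """Exact number of trainable scalars (convs, BN affine, PReLU, fusion, head)."""
    return int(sum(p.size for p in net.parameters()))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: FCNN, lut: LookupTable, extra: Optional[dict] = None) -> None:
    meta = {
        "config": asdict(net.cfg),
        "plane": net.plane,
        "lut_fingerprint": lut.fingerprint(),
        "extra": extra or {},
    }
    arrays = {f"arr::{k}": v for k, v in net.state_arrays().items()}
    np.savez_compressed(str(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, lut: LookupTable) -> Tuple[FCNN, dict]:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        arrays = {k[5:]: z[k] for k in z.files if k.startswith("arr::")}
    if meta["lut_fingerprint"] != lut.fingerprint():
        raise ConfigurationError("checkpoint was trained with a different lookup table")
    cfg = NetworkConfig(**meta["config"])
    cfg.kernel = tuple(cfg.kernel)
    net = FCNN(cfg, meta["plane"])
    net.load_state_arrays(arrays)
    return net, meta
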