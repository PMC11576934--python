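"""Whole-volume hetero-modal prediction, view aggregation and volume reports.

Per plane, the 2.5D network predicts softmax probabilities slice by slice at
native resolution; the sagittal prediction (lateral-merged classes) is
expanded back to the full class axis by copying each merged probability to
both lateral descendants; the three views are then ensembled by a fixed
weighted average (axial 0.4, coronal 0.4, sagittal 0.2) and renormalized.
Argmax ties break towards the lowest class index.  A missing modality is
handled inside the network by zeroing its fusion weight, never by feeding
zero-filled images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .lut_io import (
    HypoparcError,
    LookupTable,
    PLANE_AXES,
    RegistrationError,
    ShapeError,
    Volume,
    conform,
    extract_slice_stacks,
    merge_lateral_labels,
)
from .network.layers import _linear_resize_matrix
from .network.model import FCNN
from .train_engine import softmax

DEFAULT_VIEW_WEIGHTS = {"axial": 0.4, "coronal": 0.4, "sagittal": 0.2}


@dataclass
class ProbabilityMap:
    """Per-class soft prediction volume; per-voxel values form a simplex."""

    data: np.ndarray  # (n_classes, X, Y, Z)
    lut: LookupTable
    voxel_size: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ShapeError("probability map must be (C, X, Y, Z)")

    def check_simplex(self, tol: float = 1e-5) -> None:
        s = self.data.sum(axis=0)
        if np.abs(s - 1.0).max() > tol or self.data.min() < -tol or self.data.max() > 1 + tol:
            raise HypoparcError("probability map is not a per-voxel simplex")


@dataclass
class SegmentationResult:
    labelmap: Volume
    volumes_mm3: Dict[int, float]
    provenance: Dict[str, object] = field(default_factory=dict)
    probability: Optional[ProbabilityMap] = None


def class_channels(lut: LookupTable) -> Dict[int, int]:
    """Label id -> channel index (channel 0 is background)."""
    return {e.label_id: i + 1 for i, e in enumerate(lut.entries)}


def _mode_inputs(mode: str, vols: Dict[str, Volume]) -> Dict[str, Volume]:
    need = {"t1t2": ("T1", "T2"), "t1_only": ("T1",), "t2_only": ("T2",)}[mode]
    missing = [m for m in need if m not in vols]
    if missing:
        raise HypoparcError(f"mode {mode!r} requires volumes {missing}")
    return {m: vols[m] for m in need}


def predict_plane(
    net: FCNN,
    vols: Dict[str, Volume],
    plane: str,
    mode: str = "t1t2",
    lut: Optional[LookupTable] = None,
    batch_size: int = 8,
) -> ProbabilityMap:
    """Softmax probabilities for every slice, reassembled at native resolution."""
    if net.plane != plane:
        raise HypoparcError(f"checkpoint is for plane {net.plane!r}, not {plane!r}")
    use = _mode_inputs(mode, vols)
    stacks = extract_slice_stacks(use, plane, thickness=net.cfg.stack_thickness)
    res = stacks[0].in_plane_resolution
    probs: List[np.ndarray] = []
    for start in range(0, len(stacks), batch_size):
        chunk = stacks[start : start + batch_size]
        inputs = {
            m: np.stack([s.arrays[m] for s in chunk]) for m in use
        }
        logits = net.forward(inputs, res, train=False)
        probs.extend(softmax(logits))
    ref = next(iter(use.values()))
    vol4 = np.stack(probs, axis=0)  # (n_slices, C, H, W)
    vol4 = np.moveaxis(vol4, 0, 1 + PLANE_AXES[plane])
    return ProbabilityMap(vol4, lut, ref.voxel_size)


def unmerge_sagittal(
    p_merged: ProbabilityMap, mapping: Dict[int, int], lut: LookupTable
) -> ProbabilityMap:
    """Copy each merged-class probability to both lateral descendants.

    The per-voxel sums may exceed 1 afterwards; renormalization is deferred
    to :func:`aggregate_views` so the fixed view weights keep their meaning.
    """
    merged, _ = merge_lateral_labels(lut)
    if p_merged.data.shape[0] != len(merged) + 1:
        raise HypoparcError("merged probability map does not match the merged LUT")
    merged_ch = class_channels(merged)
    full_ch = class_channels(lut)
    out = np.empty((len(lut) + 1,) + p_merged.data.shape[1:])
    out[0] = p_merged.data[0]
    for lid, ch in full_ch.items():
        out[ch] = p_merged.data[merged_ch[mapping[lid]]]
    return ProbabilityMap(out, lut, p_merged.voxel_size)


def aggregate_views(
    maps: Dict[str, ProbabilityMap],
    weights: Optional[Dict[str, float]] = None,
) -> ProbabilityMap:
    """Weighted average of per-view probability maps, renormalized per voxel."""
    if not maps:
        raise HypoparcError("no probability maps to aggregate")
    weights = dict(weights or DEFAULT_VIEW_WEIGHTS)
    shapes = {m.data.shape for m in maps.values()}
    if len(shapes) > 1:
        raise ShapeError("probability maps must share shape and class axis")
    acc = None
    for plane, pm in maps.items():
        w = weights.get(plane, 0.0)
        if w < 0:
            raise HypoparcError("view weights must be non-negative")
        acc = w * pm.data if acc is None else acc + w * pm.data
    total = acc.sum(axis=0, keepdims=True)
    if np.any(total <= 0):
        raise HypoparcError("degenerate aggregation: zero total probability")
    ref = next(iter(maps.values()))
    return ProbabilityMap(acc / total, ref.lut, ref.voxel_size)


def _labelmap_from_probs(p: ProbabilityMap, affine: np.ndarray) -> Volume:
    arg = p.data.argmax(axis=0)  # ties break to the lowest class index
    ids = np.array([0] + [e.label_id for e in p.lut.entries])
    return Volume(ids[arg].astype(np.int32), p.voxel_size, affine, "LABEL")


def _structure_volumes(labelmap: Volume, lut: LookupTable) -> Dict[int, float]:
    vv = labelmap.voxel_volume_mm3()
    ids, counts = np.unique(labelmap.data, return_counts=True)
    found = dict(zip(ids.tolist(), counts.tolist()))
    return {e.label_id: found.get(e.label_id, 0) * vv for e in lut.entries}


def segment(
    t1: Optional[Volume],
    t2: Optional[Volume],
    checkpoints: Dict[str, FCNN],
    lut: LookupTable,
    mode: str = "auto",
    view_weights: Optional[Dict[str, float]] = None,
    keep_probability: bool = False,
) -> SegmentationResult:
    """Conform -> per-plane predict -> sagittal unmerge -> aggregate -> argmax."""
    if t1 is None and t2 is None:
        raise HypoparcError("at least one input modality required")
    vols: Dict[str, Volume] = {}
    if t1 is not None:
        vols["T1"] = conform(t1)
    if t2 is not None:
        vols["T2"] = conform(t2)
    if len(vols) == 2:
        a, b = vols["T1"], vols["T2"]
        if a.shape != b.shape or not np.allclose(a.voxel_size, b.voxel_size):
            raise RegistrationError("T1 and T2 must be co-registered (same grid)")
    if mode == "auto":
        mode = {frozenset({"T1", "T2"}): "t1t2", frozenset({"T1"}): "t1_only",
                frozenset({"T2"}): "t2_only"}[frozenset(vols)]
    if mode == "t2_only":
        warnings.warn(
            "T2-only inference is supported but is the lowest-performing input mode",
            stacklevel=2,
        )
    _, mapping = merge_lateral_labels(lut)
    per_view: Dict[str, ProbabilityMap] = {}
    for plane, net in checkpoints.items():
        pm = predict_plane(net, vols, plane, mode=mode,
                           lut=None if plane == "sagittal" else lut)
        if plane == "sagittal":
            pm.lut = merge_lateral_labels(lut)[0]
            pm = unmerge_sagittal(pm, mapping, lut)
        per_view[plane] = pm
    agg = aggregate_views(per_view, view_weights)
    ref = next(iter(vols.values()))
    labelmap = _labelmap_from_probs(agg, ref.affine)
    return SegmentationResult(
        labelmap=labelmap,
        volumes_mm3=_structure_volumes(labelmap, lut),
        provenance={
            "mode": mode,
            "planes": sorted(per_view),
            "view_weights": dict(view_weights or DEFAULT_VIEW_WEIGHTS),
            "voxel_size": ref.voxel_size,
        },
        probability=agg if keep_probability else None,
    )


# ---------------------------------------------------------------------------
# Inference at a working resolution with soft-label upsampling
# ---------------------------------------------------------------------------

def trilinear_resize(data: np.ndarray, out_shape: Sequence[int]) -> np.ndarray:
    """Separable trilinear resize of the trailing three axes."""
    mx = _linear_resize_matrix(data.shape[-3], out_shape[0])
    my = _linear_resize_matrix(data.shape[-2], out_shape[1])
    mz = _linear_resize_matrix(data.shape[-1], out_shape[2])
    return np.einsum("px,qy,rz,...xyz->...pqr", mx, my, mz, data, optimize=True)


def _resample_volume(v: Volume, work_res: float) -> Volume:
    factors = np.asarray(v.voxel_size) / work_res
    out_shape = [max(1, int(np.floor(n * f + 0.5))) for n, f in zip(v.shape, factors)]
    data = trilinear_resize(v.data.astype(np.float64), out_shape)
    scale = np.diag([work_res / s for s in v.voxel_size] + [1.0])
    return Volume(data, (work_res,) * 3, v.affine @ scale, v.modality)


def segment_upsample(
    t1: Optional[Volume],
    t2: Optional[Volume],
    checkpoints: Dict[str, FCNN],
    lut: LookupTable,
    work_res: float,
    mode: str = "auto",
    view_weights: Optional[Dict[str, float]] = None,
) -> SegmentationResult:
    """Run the network at ``work_res``, upsample soft labels to the native
    grid trilinearly, renormalize, then take hard labels (labels themselves
    are never interpolated)."""
    if work_res <= 0:
        raise HypoparcError("work_res must be positive")
    ref_in = t1 if t1 is not None else t2
    if ref_in is None:
        raise HypoparcError("at least one input modality required")
    native = conform(ref_in)
    if np.allclose(native.voxel_size, (work_res,) * 3):
        return segment(t1, t2, checkpoints, lut, mode, view_weights)
    t1w = _resample_volume(conform(t1), work_res) if t1 is not None else None
    t2w = _resample_volume(conform(t2), work_res) if t2 is not None else None
    res = segment(t1w, t2w, checkpoints, lut, mode, view_weights, keep_probability=True)
    probs = trilinear_resize(res.probability.data, native.shape)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=0, keepdims=True)
    pm = ProbabilityMap(probs, lut, native.voxel_size)
    labelmap = _labelmap_from_probs(pm, native.affine)
    return SegmentationResult(
        labelmap=labelmap,
        volumes_mm3=_structure_volumes(labelmap, lut),
        provenance={**res.provenance, "work_res": work_res,
                    "native_voxel_size": native.voxel_size},
        probability=None,
    )
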