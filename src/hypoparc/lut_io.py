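"""Volume I/O, canonical orientation, label lookup tables and 2.5D slice stacks.

The segmentation pipeline works on conformed volumes: a fixed ``(L, I, A)``
axis order so that the three anatomical planes map onto fixed array axes
(sagittal -> axis 0, axial -> axis 1, coronal -> axis 2), and image
intensities rescaled to [0, 1] by a robust min-max rule.  Label volumes are
never intensity-rescaled and are resampled nearest-neighbour everywhere.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np

CANONICAL_AXCODES = ("L", "I", "A")

#: array axis sliced over for each anatomical plane (after :func:`conform`)
PLANE_AXES = {"sagittal": 0, "axial": 1, "coronal": 2}

REGIONS = (
    "hypothalamic-anterior",
    "hypothalamic-middle",
    "hypothalamic-posterior",
    "optic",
    "others",
)

MODALITIES = ("T1", "T2", "LABEL")


class HypoparcError(Exception):
    """Base class for all package errors."""


class HeaderError(HypoparcError):
    pass


class ShapeError(HypoparcError):
    pass


class OrientationError(HypoparcError):
    pass


class LutError(HypoparcError):
    pass


class RegistrationError(HypoparcError):
    pass


class ParameterError(HypoparcError):
    pass


@dataclass
class Volume:
    """A 3D scalar image with voxel size (mm), world affine and modality tag."""

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    affine: np.ndarray
    modality: str = "T1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise HeaderError(f"voxel size must be 3 positive reals, got {self.voxel_size}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise HeaderError("affine must be 4x4")
        if self.modality not in MODALITIES:
            raise HypoparcError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class LutEntry:
    label_id: int
    name: str
    region: str
    partner_id: Optional[int]
    rgb: Tuple[int, int, int]


class LookupTable:
    """Ordered label table: id <-> (name, region group, lateral partner, color)."""

    def __init__(self, entries: Sequence[LutEntry]):
        entries = list(entries)
        ids = [e.label_id for e in entries]
        if len(set(ids)) != len(ids):
            raise LutError("label ids must be unique")
        if any(i <= 0 for i in ids):
            raise LutError("label ids must be positive (0 is reserved for background)")
        for e in entries:
            if e.region not in REGIONS:
                raise LutError(f"unknown region {e.region!r} for label {e.label_id}")
        self.entries: List[LutEntry] = entries
        self._by_id = {e.label_id: e for e in entries}
        # partner relation must be symmetric
        for e in entries:
            if e.partner_id is None:
                continue
            p = self._by_id.get(e.partner_id)
            if p is None or p.partner_id != e.label_id:
                raise LutError(f"asymmetric partner relation for label {e.label_id}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, label_id: int) -> LutEntry:
        return self._by_id[label_id]

    def __contains__(self, label_id: int) -> bool:
        return label_id in self._by_id

    def ids(self) -> List[int]:
        return [e.label_id for e in self.entries]

    def fingerprint(self) -> str:
        import hashlib

        text = ";".join(
            f"{e.label_id}:{e.name}:{e.region}:{e.partner_id}" for e in self.entries
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    # -- text format: FreeSurfer-style color table + region/partner sidecar columns
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# id name R G B A region partner\n")
            for e in self.entries:
                partner = e.partner_id if e.partner_id is not None else 0
                r, g, b = e.rgb
                fh.write(
                    f"{e.label_id} {e.name} {r} {g} {b} 0 {e.region} {partner}\n"
                )

    @classmethod
    def from_file(cls, path) -> "LookupTable":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 8:
                    raise LutError(f"malformed LUT line: {line!r}")
                lid, name, r, g, b, _a, region, partner = parts
                entries.append(
                    LutEntry(
                        label_id=int(lid),
                        name=name,
                        region=region,
                        partner_id=int(partner) or None,
                        rgb=(int(r), int(g), int(b)),
                    )
                )
        return cls(entries)


def default_lut() -> LookupTable:
    """The shipped 24-structure hypothalamus/adjacent-structure lookup table."""
    ref = importlib.resources.files("hypoparc.data").joinpath("hypothalamus_lut.txt")
    with importlib.resources.as_file(ref) as path:
        return LookupTable.from_file(path)


def toy_lut() -> LookupTable:
    """Six-label toy table (two lateral pairs) used for desk-scale phantoms."""
    ref = importlib.resources.files("hypoparc.data").joinpath("toy_lut.txt")
    with importlib.resources.as_file(ref) as path:
        return LookupTable.from_file(path)


@dataclass
class SliceStack:
    """Multi-slice 2.5D input: per-modality (S, H, W) arrays around one slice."""

    plane: str
    arrays: Dict[str, np.ndarray]
    in_plane_resolution: Tuple[float, float]
    center_index: int
    label: Optional[np.ndarray] = None  # (H, W) int labels of the center slice

    def __post_init__(self) -> None:
        if self.plane not in PLANE_AXES:
            raise ParameterError(f"unknown plane {self.plane!r}")
        shapes = {a.shape for a in self.arrays.values()}
        if len(shapes) > 1:
            raise ShapeError("modality arrays in a stack must share (S,H,W)")
        (s, _, _) = next(iter(shapes))
        if s % 2 != 1:
            raise ParameterError("stack thickness must be odd")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _check_shear(affine: np.ndarray, tol: float = 1e-3) -> None:
    m = affine[:3, :3]
    norms = np.linalg.norm(m, axis=0)
    if np.any(norms == 0):
        raise OrientationError("singular affine")
    r = m / norms
    off = r.T @ r - np.eye(3)
    if np.max(np.abs(off)) > tol:
        raise HeaderError(f"affine shear exceeds tolerance ({np.max(np.abs(off)):.2g})")


def read_volume(path, modality: str) -> Volume:
    """Read a NIfTI-1/2 volume; voxel sizes come from the header zooms."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ShapeError(f"expected 3D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise HeaderError(f"non-positive voxel size in header: {zooms}")
    affine = img.affine  # nibabel already prefers a valid sform over qform
    _check_shear(affine)
    dtype = np.int32 if modality == "LABEL" else np.float64
    return Volume(data.astype(dtype), tuple(float(z) for z in zooms), affine, modality)


def write_volume(vol: Volume, path) -> None:
    data = vol.data
    if vol.modality == "LABEL":
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Conform
# ---------------------------------------------------------------------------

def robust_rescale(data: np.ndarray, lo_pct: float = 0.1, hi_pct: float = 99.9) -> np.ndarray:
    """Clip to the [0.1, 99.9] percentile window and map to [0, 1].

    Idempotent in the generic case: after one pass the clipped tails sit
    exactly at 0 and 1, so the percentile window of the result is [0, 1].
    A constant volume maps to all zeros.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.min() >= 0.0 and data.max() <= 1.0:
        return data  # already normalized: exact idempotence
    lo, hi = np.percentile(data, [lo_pct, hi_pct])
    if hi <= lo:
        return np.zeros_like(data)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def conform(vol: Volume) -> Volume:
    """Reorient to the canonical (L, I, A) axis order and rescale intensities.

    LABEL volumes are reoriented only.  Idempotent: a conformed volume passes
    through unchanged.
    """
    if abs(np.linalg.det(vol.affine[:3, :3])) < 1e-12:
        raise OrientationError("singular affine")
    src_ornt = nib.orientations.io_orientation(vol.affine)
    dst_ornt = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(src_ornt, dst_ornt)
    data = nib.orientations.apply_orientation(vol.data, transform)
    inv_aff = nib.orientations.inv_ornt_aff(transform, vol.data.shape)
    affine = vol.affine @ inv_aff
    voxel_size = tuple(float(v) for v in np.linalg.norm(affine[:3, :3], axis=0))
    if vol.modality == "LABEL":
        data = np.ascontiguousarray(data)
    else:
        data = robust_rescale(data)
    return Volume(data, voxel_size, affine, vol.modality)


# ---------------------------------------------------------------------------
# Lateral-label merging (sagittal view)
# ---------------------------------------------------------------------------

def _strip_lateral_prefix(name: str) -> str:
    for pre in ("L-", "R-"):
        if name.startswith(pre):
            return name[len(pre):]
    return name


def merge_lateral_labels(lut: LookupTable) -> Tuple[LookupTable, Dict[int, int]]:
    """Collapse each symmetric lateral pair into one label.

    Returns the merged table and the ``label_id -> merged_id`` mapping.  A
    pair is merged onto the smaller of the two ids; unpartnered labels map to
    themselves.
    """
    mapping: Dict[int, int] = {}
    merged_entries: List[LutEntry] = []
    for e in lut:
        if e.partner_id is None:
            mapping[e.label_id] = e.label_id
            merged_entries.append(e)
            continue
        a, b = lut[e.label_id], lut[e.partner_id]
        if _strip_lateral_prefix(a.name) != _strip_lateral_prefix(b.name):
            raise LutError(
                f"partnered labels {a.name}/{b.name} differ by more than an L-/R- prefix"
            )
        keep = min(e.label_id, e.partner_id)
        mapping[e.label_id] = keep
        if e.label_id == keep:
            merged_entries.append(
                LutEntry(keep, _strip_lateral_prefix(e.name), e.region, None, e.rgb)
            )
    merged = LookupTable(merged_entries)
    return merged, mapping


def apply_label_mapping(labels: np.ndarray, mapping: Dict[int, int]) -> np.ndarray:
    """Relabel an integer map through ``mapping`` (background 0 passes through)."""
    out = np.zeros_like(labels)
    for src, dst in mapping.items():
        out[labels == src] = dst
    return out


# ---------------------------------------------------------------------------
# 2.5D slice-stack extraction
# ---------------------------------------------------------------------------

def _plane_resolution(voxel_size: Sequence[float], plane: str) -> Tuple[float, float]:
    axis = PLANE_AXES[plane]
    inplane = [voxel_size[i] for i in range(3) if i != axis]
    return (float(inplane[0]), float(inplane[1]))


def slice_windows(data: np.ndarray, plane: str, thickness: int) -> np.ndarray:
    """All multi-slice windows along a plane axis, edge-replicated at borders.

    Returns an array of shape (n_slices, thickness, H, W).
    """
    if thickness % 2 != 1 or thickness < 1:
        raise ParameterError("thickness must be a positive odd integer")
    axis = PLANE_AXES[plane]
    moved = np.moveaxis(data, axis, 0)
    k = thickness // 2
    pad = [(k, k)] + [(0, 0)] * (moved.ndim - 1)
    padded = np.pad(moved, pad, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, thickness, axis=0)
    # (n, H, W, S) -> (n, S, H, W)
    return np.ascontiguousarray(np.moveaxis(win, -1, 1))


def extract_slice_stacks(
    vols: Dict[str, Volume],
    plane: str,
    thickness: int = 7,
    labels: Optional[Volume] = None,
) -> List[SliceStack]:
    """One SliceStack per slice index along the plane axis of conformed volumes."""
    if not vols:
        raise HypoparcError("at least one input volume required")
    ref = next(iter(vols.values()))
    for v in vols.values():
        if v.shape != ref.shape or not np.allclose(v.voxel_size, ref.voxel_size):
            raise RegistrationError("modalities must share shape and voxel size")
    if labels is not None and labels.shape != ref.shape:
        raise RegistrationError("label volume must share the image grid")
    windows = {m: slice_windows(v.data, plane, thickness) for m, v in vols.items()}
    res = _plane_resolution(ref.voxel_size, plane)
    axis = PLANE_AXES[plane]
    label_slices = None
    if labels is not None:
        label_slices = np.moveaxis(labels.data, axis, 0)
    stacks = []
    n = ref.shape[axis]
    for i in range(n):
        stacks.append(
            SliceStack(
                plane=plane,
                arrays={m: windows[m][i] for m in windows},
                in_plane_resolution=res,
                center_index=i,
                label=None if label_slices is None else label_slices[i],
            )
        )
    return stacks


def reassemble_center_slices(stacks: Sequence[np.ndarray], plane: str) -> np.ndarray:
    """Stack per-slice center maps back into a volume along the plane axis."""
    vol = np.stack(list(stacks), axis=0)
    return np.moveaxis(vol, 0, PLANE_AXES[plane])
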