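"""Synthetic two-contrast brain phantoms with ground-truth labels.

The scene is defined *continuously* in millimetres (ellipsoids and capsule
"tubes"), then rasterized onto a voxel grid, so the same scene can be
rendered at several voxel sizes and per-structure physical volumes agree
across resolutions up to rasterization error.  The two channels emulate the
statistical structure the hetero-modal network relies on: partially inverted
contrast between the pseudo-T1 and pseudo-T2 channel (the ventricle-like
midline structure is dark on T1, bright on T2), a shared smooth texture with
opposite sign in the two channels (negative within-structure correlation),
additive Gaussian noise, and an optional multiplicative smooth bias field.
No MRI physics (k-space, sequences) is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .lut_io import (
    HypoparcError,
    LookupTable,
    ParameterError,
    Volume,
    default_lut,
    toy_lut,
)
from .train_engine import N_BIAS_COEFFS, polynomial_bias_field


class SpecError(HypoparcError):
    pass


@dataclass
class Structure:
    """One scene element: an ellipsoid or a capsule tube, in mm coordinates."""

    label_id: int
    kind: str  # "ellipsoid" | "tube"
    center: Optional[Tuple[float, float, float]] = None
    radii: Optional[Tuple[float, float, float]] = None
    p0: Optional[Tuple[float, float, float]] = None
    p1: Optional[Tuple[float, float, float]] = None
    radius: Optional[float] = None

    def extent(self) -> np.ndarray:
        """Per-axis maximum |coordinate| reached by the structure."""
        if self.kind == "ellipsoid":
            return np.abs(np.asarray(self.center)) + np.asarray(self.radii)
        pts = np.abs(np.stack([np.asarray(self.p0), np.asarray(self.p1)]))
        return pts.max(axis=0) + self.radius

    def mask(self, xx: np.ndarray, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
        if self.kind == "ellipsoid":
            cx, cy, cz = self.center
            rx, ry, rz = self.radii
            return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0
        if self.kind == "tube":
            p0 = np.asarray(self.p0)
            v = np.asarray(self.p1) - p0
            vv = float(v @ v)
            dx, dy, dz = xx - p0[0], yy - p0[1], zz - p0[2]
            t = np.clip((dx * v[0] + dy * v[1] + dz * v[2]) / vv, 0.0, 1.0)
            d2 = (dx - t * v[0]) ** 2 + (dy - t * v[1]) ** 2 + (dz - t * v[2]) ** 2
            return d2 <= self.radius**2
        raise SpecError(f"unknown structure kind {self.kind!r}")


@dataclass
class PhantomSpec:
    seed: int
    fov_mm: Tuple[float, float, float]
    voxel_size: float
    lut: LookupTable
    structures: List[Structure]
    contrast: Dict[int, Tuple[float, float]]  # label -> (T1-like, T2-like mean)
    noise_sd: float = 0.03
    bias: bool = False
    texture_amplitude: float = 0.12

    def validate(self) -> None:
        if self.voxel_size <= 0:
            raise ParameterError("voxel size must be positive")
        half = np.asarray(self.fov_mm) / 2.0
        for s in self.structures:
            if s.label_id not in self.lut:
                raise SpecError(f"structure label {s.label_id} missing from LUT")
            if np.any(s.extent() > half):
                raise SpecError(f"structure {s.label_id} extends outside the field of view")
        missing = {0, *(s.label_id for s in self.structures)} - set(self.contrast)
        if missing:
            raise SpecError(f"contrast table missing labels {sorted(missing)}")


def _texture(xx: np.ndarray, yy: np.ndarray, zz: np.ndarray) -> np.ndarray:
    # smooth deterministic mm-space field in [-1, 1]; shared by both channels
    return (
        np.sin(2 * np.pi * xx / 9.7)
        * np.sin(2 * np.pi * yy / 11.3)
        * np.sin(2 * np.pi * zz / 8.9)
    )


def _canonical_affine(voxel_size: float, shape: Sequence[int]) -> np.ndarray:
    # axis order (L, I, A): +axis0 -> -X, +axis1 -> -Z, +axis2 -> +Y (RAS world)
    v = float(voxel_size)
    aff = np.zeros((4, 4))
    aff[0, 0] = -v
    aff[2, 1] = -v
    aff[1, 2] = v
    aff[3, 3] = 1.0
    center = (np.asarray(shape) - 1) / 2.0
    aff[:3, 3] = -aff[:3, :3] @ center
    return aff


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, Volume, Volume]:
    """Rasterize the scene; returns (pseudo-T1, pseudo-T2, labels) volumes."""
    spec.validate()
    shape = tuple(
        max(8, int(np.floor(f / spec.voxel_size + 0.5))) for f in spec.fov_mm
    )
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_size for n in shape
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")

    labels = np.zeros(shape, dtype=np.int32)
    for s in spec.structures:  # first-listed structure takes precedence
        m = s.mask(xx, yy, zz) & (labels == 0)
        labels[m] = s.label_id

    t1 = np.full(shape, spec.contrast[0][0])
    t2 = np.full(shape, spec.contrast[0][1])
    for s in spec.structures:
        m = labels == s.label_id
        t1[m] = spec.contrast[s.label_id][0]
        t2[m] = spec.contrast[s.label_id][1]

    fg = labels > 0
    tex = _texture(xx, yy, zz) * spec.texture_amplitude
    t1 = t1 + tex * fg  # opposite sign: within-structure contrast inversion
    t2 = t2 - tex * fg

    streams = np.random.SeedSequence(spec.seed).spawn(3)
    rng_t1, rng_t2, rng_bias = (np.random.default_rng(s) for s in streams)
    t1 = t1 + rng_t1.normal(0.0, spec.noise_sd, size=shape)
    t2 = t2 + rng_t2.normal(0.0, spec.noise_sd, size=shape)
    if spec.bias:
        for img, rng in ((t1, rng_bias), (t2, rng_bias)):
            coeffs = rng.uniform(-0.2, 0.2, size=N_BIAS_COEFFS)
            img *= polynomial_bias_field(shape, coeffs)

    affine = _canonical_affine(spec.voxel_size, shape)
    vs = (spec.voxel_size,) * 3
    return (
        Volume(t1, vs, affine, "T1"),
        Volume(t2, vs, affine, "T2"),
        Volume(labels, vs, affine, "LABEL"),
    )


def generate_multires_pair(
    spec: PhantomSpec, res_a: float, res_b: float
) -> Tuple[Tuple[Volume, Volume, Volume], Tuple[Volume, Volume, Volume]]:
    """The identical continuous scene rasterized at two voxel sizes."""
    if res_a == res_b:
        raise ParameterError("the two resolutions must differ")
    a = generate_phantom(replace(spec, voxel_size=float(res_a)))
    b = generate_phantom(replace(spec, voxel_size=float(res_b)))
    return a, b


# ---------------------------------------------------------------------------
# Shipped scenes
# ---------------------------------------------------------------------------

def toy_phantom_spec(seed: int = 0, voxel_size: float = 0.8, bias: bool = False) -> PhantomSpec:
    """Six-label desk-scale scene (25.6 mm FOV -> 32^3 at 0.8 mm)."""
    structures = [
        Structure(1, "ellipsoid", center=(0.0, 0.0, 0.0), radii=(2.2, 5.0, 3.6)),
        Structure(2, "ellipsoid", center=(5.5, 0.0, 2.0), radii=(2.8, 3.2, 3.0)),
        Structure(3, "ellipsoid", center=(-5.5, 0.0, 2.0), radii=(2.8, 3.2, 3.0)),
        Structure(4, "tube", p0=(4.5, 5.0, -9.0), p1=(4.5, 5.0, 7.0), radius=1.4),
        Structure(5, "tube", p0=(-4.5, 5.0, -9.0), p1=(-4.5, 5.0, 7.0), radius=1.4),
        Structure(6, "tube", p0=(-5.0, -6.0, -5.0), p1=(5.0, -6.0, -5.0), radius=1.2),
    ]
    contrast = {
        0: (0.35, 0.45),
        1: (0.08, 0.92),  # CSF-like: dark on T1, bright on T2
        2: (0.65, 0.40),
        3: (0.65, 0.40),
        4: (0.85, 0.25),
        5: (0.85, 0.25),
        6: (0.80, 0.30),
    }
    return PhantomSpec(
        seed=seed,
        fov_mm=(25.6, 25.6, 25.6),
        voxel_size=voxel_size,
        lut=toy_lut(),
        structures=structures,
        contrast=contrast,
        bias=bias,
    )


def full_phantom_spec(seed: int = 0, voxel_size: float = 0.8, bias: bool = False) -> PhantomSpec:
    """All 24 structures of the shipped lookup table in one 38.4 mm FOV scene."""

    def pair(lid_l, lid_r, make):
        return [make(lid_l, +1.0), make(lid_r, -1.0)]

    def ell(lid, sign, c, r):
        return Structure(lid, "ellipsoid", center=(sign * c[0], c[1], c[2]), radii=r)

    def tub(lid, sign, p0, p1, r):
        return Structure(
            lid, "tube", p0=(sign * p0[0], p0[1], p0[2]), p1=(sign * p1[0], p1[1], p1[2]), radius=r
        )

    structures: List[Structure] = []
    structures += pair(1, 2, lambda l, s: ell(l, s, (3.0, 1.0, 4.0), (1.5, 1.8, 1.8)))
    structures += pair(3, 4, lambda l, s: ell(l, s, (2.5, 0.0, 1.0), (1.4, 1.6, 1.6)))
    structures += pair(5, 6, lambda l, s: ell(l, s, (4.8, 0.0, 1.0), (1.5, 2.0, 2.0)))
    structures.append(Structure(7, "ellipsoid", center=(0.0, -1.5, 0.5), radii=(1.8, 1.4, 1.8)))
    structures += pair(8, 9, lambda l, s: ell(l, s, (2.5, 0.5, -3.0), (1.4, 1.6, 1.6)))
    structures += pair(10, 11, lambda l, s: ell(l, s, (1.5, -2.0, -5.5), (1.2, 1.2, 1.2)))
    structures.append(Structure(12, "ellipsoid", center=(0.0, 3.5, 0.0), radii=(1.2, 4.5, 5.0)))
    structures += pair(13, 14, lambda l, s: tub(l, s, (2.0, 5.0, -6.0), (2.0, 9.0, 4.0), 1.0))
    structures.append(Structure(15, "ellipsoid", center=(0.0, 7.0, -9.0), radii=(1.3, 1.3, 1.3)))
    structures.append(Structure(16, "ellipsoid", center=(0.0, -8.0, 2.0), radii=(2.2, 1.8, 2.0)))
    structures.append(Structure(17, "tube", p0=(0.0, -3.5, 1.5), p1=(0.0, -6.5, 2.0), radius=1.0))
    structures.append(Structure(18, "tube", p0=(-5.0, 4.0, 6.0), p1=(5.0, 4.0, 6.0), radius=1.1))
    structures += pair(19, 20, lambda l, s: tub(l, s, (6.0, -4.0, 6.0), (9.0, -5.0, 10.0), 1.3))
    structures += pair(21, 22, lambda l, s: ell(l, s, (1.5, -4.5, 5.5), (1.5, 1.2, 1.4)))
    structures += pair(23, 24, lambda l, s: tub(l, s, (2.0, -4.0, 4.5), (7.0, -3.0, -2.0), 1.2))

    gray = (0.60, 0.45)
    white = (0.85, 0.28)
    contrast: Dict[int, Tuple[float, float]] = {0: (0.35, 0.45)}
    for lid in range(1, 12):
        contrast[lid] = gray
    contrast[12] = (0.08, 0.92)
    for lid in (13, 14, 18):
        contrast[lid] = white
    contrast[15] = (0.55, 0.60)
    contrast[16] = (0.70, 0.50)
    contrast[17] = (0.60, 0.50)
    for lid in (19, 20, 21, 22, 23, 24):
        contrast[lid] = (0.85, 0.25)
    return PhantomSpec(
        seed=seed,
        fov_mm=(38.4, 38.4, 38.4),
        voxel_size=voxel_size,
        lut=default_lut(),
        structures=structures,
        contrast=contrast,
        bias=bias,
    )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator,
                 center_mm: float = 1.0, radius_frac: float = 0.1) -> PhantomSpec:
    """Seeded per-phantom jitter of centers/radii, kept mirror-symmetric."""
    groups: Dict[int, Tuple[np.ndarray, float]] = {}

    def group_key(lid: int) -> int:
        e = spec.lut[lid]
        return min(lid, e.partner_id) if e.partner_id else lid

    jittered: List[Structure] = []
    for s in spec.structures:
        key = group_key(s.label_id)
        if key not in groups:
            groups[key] = (
                rng.uniform(-center_mm, center_mm, size=3),
                float(rng.uniform(1 - radius_frac, 1 + radius_frac)),
            )
        d, f = groups[key]
        sign = 1.0
        e = spec.lut[s.label_id]
        if e.partner_id is not None and s.label_id > e.partner_id:
            sign = -1.0  # mirror the x-shift for the right-hand partner
        shift = np.array([sign * d[0], d[1], d[2]])
        if s.kind == "ellipsoid":
            jittered.append(
                replace(
                    s,
                    center=tuple(np.asarray(s.center) + shift),
                    radii=tuple(np.asarray(s.radii) * f),
                )
            )
        else:
            jittered.append(
                replace(
                    s,
                    p0=tuple(np.asarray(s.p0) + shift),
                    p1=tuple(np.asarray(s.p1) + shift),
                    radius=s.radius * f,
                )
            )
    return replace(spec, structures=jittered)


def dataset_specs(
    n: int,
    base_spec: PhantomSpec,
    seed: int = 0,
    jitter_mm: float = 1.0,
    jitter_radius_frac: float = 0.1,
) -> List[PhantomSpec]:
    """n seeded, jittered copies of the base scene (still continuous: they can
    be rasterized at any voxel size)."""
    if n < 1:
        raise ParameterError("need n >= 1")
    specs = []
    for sq in np.random.SeedSequence(seed).spawn(n):
        rng = np.random.default_rng(sq)
        spec_i = _jitter_spec(base_spec, rng, jitter_mm, jitter_radius_frac)
        specs.append(replace(spec_i, seed=int(rng.integers(0, 2**31 - 1))))
    return specs


def make_dataset(
    n: int,
    base_spec: PhantomSpec,
    seed: int = 0,
    jitter_mm: float = 1.0,
    jitter_radius_frac: float = 0.1,
    val_fraction: float = 0.25,
):
    """n jittered phantoms, a deterministic train/val split and label histogram."""
    triplets = [
        generate_phantom(s)
        for s in dataset_specs(n, base_spec, seed, jitter_mm, jitter_radius_frac)
    ]
    n_val = int(np.floor(n * val_fraction))
    train = triplets[: n - n_val]
    val = triplets[n - n_val :]
    hist: Dict[int, int] = {}
    for _, _, lab in train:
        ids, counts = np.unique(lab.data, return_counts=True)
        for i, c in zip(ids, counts):
            hist[int(i)] = hist.get(int(i), 0) + int(c)
    return train, val, hist
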