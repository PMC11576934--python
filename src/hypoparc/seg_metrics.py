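"""Accuracy and reliability metrics: Dice, volume similarity, HD95, ICC(A,1).

For binary label maps M (reference) and P (prediction):

    Dice = 2|M ∩ P| / (|M| + |P|)
    VS   = 1 - ||M| - |P|| / (|M| + |P|)
    HD95 = max(d95(M, P), d95(P, M))

where d95(A, B) is the 95th percentile (linear interpolation between order
statistics) over the border voxels of A of the minimum Euclidean distance in
mm to the border voxels of B.  Borders are the 6-connectivity erosion
difference of each mask, and distances account for anisotropic voxels.
Dice <= VS holds for every mask pair; both are 1 for two empty masks and 0
for empty-vs-nonempty, while HD95 is undefined (flagged) on empty masks.

Test-retest reliability uses the two-way, absolute-agreement, single-measure
intraclass correlation ICC(A,1) of McGraw & Wong, with an F-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .lut_io import HypoparcError, LookupTable, ShapeError, Volume


class UndefinedMetricError(HypoparcError):
    pass


def _as_bool(m) -> np.ndarray:
    a = np.asarray(m)
    return a.astype(bool)


def _check_shapes(m: np.ndarray, p: np.ndarray) -> None:
    if m.shape != p.shape:
        raise ShapeError(f"mask shapes differ: {m.shape} vs {p.shape}")


def dice(m, p) -> float:
    """Overlap agreement in [0, 1]; both-empty is defined as 1."""
    m, p = _as_bool(m), _as_bool(p)
    _check_shapes(m, p)
    sm, sp = int(m.sum()), int(p.sum())
    if sm + sp == 0:
        return 1.0
    return 2.0 * int(np.logical_and(m, p).sum()) / (sm + sp)


def volume_similarity(m, p) -> float:
    """Volume agreement in [0, 1]; insensitive to spatial overlap."""
    m, p = _as_bool(m), _as_bool(p)
    _check_shapes(m, p)
    sm, sp = int(m.sum()), int(p.sum())
    if sm + sp == 0:
        return 1.0
    return 1.0 - abs(sm - sp) / (sm + sp)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def border_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxels of the mask not surviving a 6-connectivity erosion (N, 3)."""
    mask = _as_bool(mask)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~eroded)


def _directed_d95(a_mm: np.ndarray, b_tree: cKDTree) -> float:
    dists, _ = b_tree.query(a_mm, k=1)
    return float(np.percentile(dists, 95))


def hd95(m, p, voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm (anisotropy-aware)."""
    m, p = _as_bool(m), _as_bool(p)
    _check_shapes(m, p)
    if m.sum() == 0 or p.sum() == 0:
        raise UndefinedMetricError("HD95 undefined for an empty mask")
    vs = np.asarray(voxel_size, dtype=float)
    bm = border_voxels(m) * vs
    bp = border_voxels(p) * vs
    tm, tp = cKDTree(bm), cKDTree(bp)
    return max(_directed_d95(bm, tp), _directed_d95(bp, tm))


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------

def icc_a1(x: np.ndarray, ci: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """Two-way, absolute-agreement, single-measure ICC with an F-based CI.

    ``x`` is an (n subjects, k raters/repeats) table with no missing cells.
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise HypoparcError("need an (n>=2, k>=2) table")
    if not np.all(np.isfinite(x)):
        raise HypoparcError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-30 or ss_total == 0:
        raise UndefinedMetricError("zero total variance: ICC undefined")
    value = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - ci
    if mse <= 0:
        return float(np.clip(value, -1.0, 1.0)), (float("nan"), float("nan"))
    a = (k * value) / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + (k * value * (n - 1)) / (n * (1 - value)) if value < 1 else np.inf
    fj = msc / mse
    vn = (a * fj + b) ** 2 / (
        (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, vn)
    f_u = stats.f.ppf(1 - alpha / 2, vn, n - 1)
    fo = msr / mse
    lo = n * (fo - f_l) / (f_l * (k * fj + k * (n - 1) - n) + n * fo)
    hi = n * (f_u * fo - 1) / (k * fj + k * (n - 1) - n + n * f_u * fo)
    return float(np.clip(value, -1.0, 1.0)), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Per-structure reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsRow:
    label_id: int
    name: str
    region: str
    dice: float
    vs: float
    hd95_mm: float  # NaN when undefined
    present: bool


def evaluate_pair(pred: Volume, ref: Volume, lut: LookupTable) -> pd.DataFrame:
    """Per-label Dice/VS/HD95 plus region and global unweighted means.

    Labels absent from both maps are flagged not-applicable and excluded from
    the aggregates.  Returns a tidy DataFrame with one row per structure and
    extra ``region:*`` / ``global`` aggregate rows.
    """
    if pred.shape != ref.shape:
        raise ShapeError("prediction and reference must share the grid")
    found = set(np.unique(pred.data)) | set(np.unique(ref.data))
    allowed = set(lut.ids()) | {0}
    if not found <= allowed:
        raise HypoparcError(f"labels outside the lookup table: {sorted(found - allowed)}")
    rows: List[MetricsRow] = []
    for e in lut:
        m = ref.data == e.label_id
        p = pred.data == e.label_id
        if not m.any() and not p.any():
            rows.append(MetricsRow(e.label_id, e.name, e.region, np.nan, np.nan, np.nan, False))
            continue
        try:
            h = hd95(m, p, ref.voxel_size)
        except UndefinedMetricError:
            h = np.nan
        rows.append(
            MetricsRow(e.label_id, e.name, e.region, dice(m, p), volume_similarity(m, p), h, True)
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    present = df[df.present]
    aggs = []
    groups = [("region:" + g, sub) for g, sub in present.groupby("region")]
    groups.append(("global", present))
    for name, sub in groups:
        aggs.append(
            {
                "label_id": -1,
                "name": name,
                "region": "",
                "dice": sub.dice.mean(),
                "vs": sub.vs.mean(),
                "hd95_mm": sub.hd95_mm.mean(),
                "present": True,
            }
        )
    return pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)


def foreground_dice(pred: np.ndarray, ref: np.ndarray, labels: Sequence[int]) -> float:
    """Unweighted mean Dice over the given labels present in either map."""
    vals = []
    for lab in labels:
        m = ref == lab
        p = pred == lab
        if m.any() or p.any():
            vals.append(dice(m, p))
    if not vals:
        raise UndefinedMetricError("no foreground labels present")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------

@dataclass
class PairedComparison:
    statistic: float
    p_raw: float
    p_bonferroni: float
    degenerate: bool


def paired_comparison(
    scores_a: Sequence[float], scores_b: Sequence[float], n_tests: int = 1
) -> PairedComparison:
    """Two-sided paired Wilcoxon signed-rank test with Bonferroni correction."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise HypoparcError("need paired 1D vectors of equal length >= 5")
    if n_tests < 1:
        raise HypoparcError("n_tests must be >= 1")
    if np.all(a == b):
        return PairedComparison(np.nan, 1.0, 1.0, True)
    res = stats.wilcoxon(a, b, alternative="two-sided")
    p_b = min(1.0, n_tests * float(res.pvalue))
    return PairedComparison(float(res.statistic), float(res.pvalue), p_b, False)
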