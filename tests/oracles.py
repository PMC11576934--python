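"""Independent brute-force oracles used to validate the metric implementations.

These deliberately avoid the code paths of the package: HD95 builds the full
pairwise distance matrix, the ICC oracle recomputes the two-way ANOVA
decomposition with explicit Python loops, and the signed-rank oracle
enumerates every sign assignment.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage


def brute_force_hd95(m: np.ndarray, p: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> float:
    """95th-percentile Hausdorff distance via the full O(|M||P|) matrix."""
    struct = ndimage.generate_binary_structure(3, 1)

    def border(mask):
        mask = mask.astype(bool)
        return np.argwhere(mask & ~ndimage.binary_erosion(mask, struct, border_value=0))

    vs = np.asarray(voxel_size, dtype=float)
    a = border(m) * vs
    b = border(p) * vs
    dmat = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    d_ab = np.percentile(dmat.min(axis=1), 95)
    d_ba = np.percentile(dmat.min(axis=0), 95)
    return float(max(d_ab, d_ba))


def anova_icc_a1(x: np.ndarray) -> float:
    """ICC(A,1) from explicitly accumulated sums of squares."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (x[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (x[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (x[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def exact_signed_rank_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n signs."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws, dtype=float)
    p_lo = (ws <= w_obs).mean()
    p_hi = (ws >= w_obs).mean()
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))
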