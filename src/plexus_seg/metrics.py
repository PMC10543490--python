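"""Segmentation performance and method-agreement statistics.

Overlap (Dice), surface distance (95% Hausdorff in mm), voxelwise ranking
(ROC AUC), and the agreement statistics used to compare volumetry methods:
ICC(2,1), Bland-Altman limits, paired two-sided Wilcoxon signed-rank tests
and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .image_io import BinaryMask3D

__all__ = [
    "dice_coefficient",
    "hausdorff95",
    "roc_auc",
    "icc",
    "bland_altman",
    "BlandAltman",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "fdr_adjust",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _check_pair(a: BinaryMask3D, b: BinaryMask3D) -> None:
    if not a.same_geometry(b):
        raise ValueError("masks must share shape and affine")


def dice_coefficient(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice-Sørensen overlap 2|A∩B|/(|A|+|B|); two empty masks agree (1.0)."""
    _check_pair(a, b)
    na, nb = int(a.data.sum()), int(b.data.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a.data & b.data).sum()) / (na + nb)


def _surface_coords(mask: BinaryMask3D) -> np.ndarray:
    """World-space (mm) coordinates of surface voxels.

    A set voxel is on the surface if at least one face neighbour is unset or
    it touches the grid boundary (erosion with zero border handles both).
    """
    eroded = ndimage.binary_erosion(mask.data, structure=_FACE_STRUCT, border_value=0)
    surf = mask.data & ~eroded
    idx = np.argwhere(surf).astype(np.float64)
    return idx * mask.spacing[None, :]


def hausdorff95(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Symmetric 95% Hausdorff distance in mm.

    Directed distance = 95th percentile (linear interpolation) of Euclidean
    distances from each surface voxel of one mask to the nearest surface voxel
    of the other; the result is the max of the two directions.
    """
    _check_pair(a, b)
    if not a.data.any() or not b.data.any():
        raise ValueError("95% Hausdorff distance is undefined for an empty mask")
    pa, pb = _surface_coords(a), _surface_coords(b)
    d_ab = cKDTree(pb).query(pa, workers=1)[0]
    d_ba = cKDTree(pa).query(pb, workers=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def icc(table: np.ndarray, form: str = "icc2_1") -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``table`` is an n_subjects x k_methods matrix with no missing cells.
    """
    if form != "icc2_1":
        raise ValueError(f"unsupported ICC form {form!r}")
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x methods)")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 methods")
    gm = x.mean()
    if np.allclose(x, gm):
        raise ValueError("zero variance in all cells; ICC undefined")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - gm) ** 2).sum()
    ss_rows = k * ((row_means - gm) ** 2).sum()
    ss_cols = n * ((col_means - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)))


@dataclasses.dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(x, y) -> BlandAltman:
    """Bias and 95% limits of agreement of the paired differences x - y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    pvalue: float
    n: int  # pairs remaining after dropping zero differences
    degenerate: bool = False


def _exact_wilcoxon_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments, via a subset-sum DP.

    Midranks are doubled so all rank sums are integers; an outcome is at
    least as extreme as the observed one if its |W+ - S/2| is >= observed.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2 * w_plus
    dev = abs(w2 - total / 2)
    sums = np.arange(total + 1, dtype=np.float64)
    extreme = np.abs(sums - total / 2) >= dev - 1e-9
    return float(counts[extreme].sum())


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (classical convention).  For n <= 25 pairs
    the exact permutation null over all sign assignments is used (midranks
    for ties); above that, the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_plus)
    else:
        p = float(stats.wilcoxon(d, correction=True, method="approx",
                                 alternative="two-sided").pvalue)
    return WilcoxonResult(w, min(p, 1.0), n)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
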