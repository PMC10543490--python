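"""Metric implementations against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from plexus_seg.image_io import BinaryMask3D
from plexus_seg.metrics import (
    bland_altman,
    dice_coefficient,
    fdr_adjust,
    hausdorff95,
    icc,
    roc_auc,
    wilcoxon_signed_rank,
)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    return BinaryMask3D(np.asarray(data, dtype=bool), aff)


# ---------------------------------------------------------------------------
# Dice


class TestDice:
    def test_identical_masks(self):
        data = np.random.default_rng(0).random((6, 6, 6)) < 0.4
        data[0, 0, 0] = True
        assert dice_coefficient(_mask(data), _mask(data)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[:2], b[4:] = True, True
        assert dice_coefficient(_mask(a), _mask(b)) == 0.0

    def test_shifted_cube_half_overlap(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        b[2:4, 1:3, 1:3] = True  # overlap 4 voxels of 8+8
        assert dice_coefficient(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_both_empty_defined_as_one(self):
        e = _mask(np.zeros((4, 4, 4)))
        assert dice_coefficient(e, e) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = _mask(rng.random((8, 8, 8)) < 0.3)
        b = _mask(rng.random((8, 8, 8)) < 0.3)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_geometry_mismatch_rejected(self):
        a = _mask(np.ones((4, 4, 4)))
        b = _mask(np.ones((4, 4, 4)), spacing=(2, 1, 1))
        with pytest.raises(ValueError):
            dice_coefficient(a, b)


# ---------------------------------------------------------------------------
# HD95


def _oracle_hd95(a, b, spacing):
    """All-pairs surface-distance oracle with explicit neighbour checks."""
    def surface(m):
        pts = []
        for idx in np.argwhere(m):
            on_boundary = (idx == 0).any() or (idx == np.array(m.shape) - 1).any()
            unset_neighbour = False
            for ax in range(3):
                for d in (-1, 1):
                    j = idx.copy()
                    j[ax] += d
                    if (0 <= j[ax] < m.shape[ax]) and not m[tuple(j)]:
                        unset_neighbour = True
            if on_boundary or unset_neighbour:
                pts.append(idx)
        return np.asarray(pts, dtype=float) * np.asarray(spacing)

    pa, pb = surface(a), surface(b)
    d = cdist(pa, pb)
    d_ab = np.percentile(d.min(axis=1), 95)
    d_ba = np.percentile(d.min(axis=0), 95)
    return max(d_ab, d_ba)


class TestHausdorff95:
    def test_identical_masks_zero(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[2:5, 2:5, 2:5] = True
        assert hausdorff95(_mask(data), _mask(data)) == 0.0

    def test_single_voxels_isotropic(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0, 0, 0], b[3, 0, 0] = True, True
        assert hausdorff95(_mask(a), _mask(b)) == pytest.approx(3.0)

    def test_single_voxels_anisotropic_spacing(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[0, 0, 0], b[3, 0, 0] = True, True
        sp = (2.0, 1.0, 1.0)
        assert hausdorff95(_mask(a, sp), _mask(b, sp)) == pytest.approx(6.0)

    def test_empty_mask_rejected(self):
        full = _mask(np.ones((4, 4, 4)))
        empty = _mask(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            hausdorff95(full, empty)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (9, 9, 9)
        a = np.zeros(shape, dtype=bool)
        b = np.zeros(shape, dtype=bool)
        ca, cb = rng.integers(2, 7, size=(2, 3))
        a[ca[0]-2:ca[0]+2, ca[1]-2:ca[1]+2, ca[2]-2:ca[2]+2] = rng.random((4, 4, 4)) < 0.7
        b[cb[0]-2:cb[0]+2, cb[1]-2:cb[1]+2, cb[2]-2:cb[2]+2] = rng.random((4, 4, 4)) < 0.7
        a[ca[0], ca[1], ca[2]] = True
        b[cb[0], cb[1], cb[2]] = True
        spacing = rng.choice([0.5, 1.0, 2.0], size=3)
        got = hausdorff95(_mask(a, spacing), _mask(b, spacing))
        want = _oracle_hd95(a, b, spacing)
        assert got == pytest.approx(want, abs=1e-9)
        # bounded by the classical (100th percentile) Hausdorff distance
        sym = max(got, 0.0)
        full_a = np.argwhere(a) * spacing
        full_b = np.argwhere(b) * spacing
        classical = max(cdist(full_a, full_b).min(axis=1).max(),
                        cdist(full_a, full_b).min(axis=0).max())
        assert sym <= classical + 1e-9


# ---------------------------------------------------------------------------
# AUC


def _oracle_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1.0
        elif p == n:
            wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_scores_equal_labels(self):
        labels = np.array([0, 1, 0, 1, 1])
        assert roc_auc(labels.astype(float), labels) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.ones(6), np.array([0, 0, 1, 1, 1, 0])) == 0.5

    def test_worked_example(self):
        assert roc_auc([0.9, 0.7, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 25)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # coarse grid to force ties
        assert roc_auc(scores, labels) == pytest.approx(
            _oracle_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.standard_normal(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2 * scores) + 3, labels)
        assert a == pytest.approx(b, abs=1e-12)


# ---------------------------------------------------------------------------
# ICC


def _oracle_icc21(x):
    """Two-way ANOVA by explicit loops."""
    n, k = x.shape
    gm = x.mean()
    ms_r = k * sum((x[i].mean() - gm) ** 2 for i in range(n)) / (n - 1)
    ms_c = n * sum((x[:, j].mean() - gm) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + gm) ** 2
    ms_e = sse / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


class TestIcc:
    def test_identical_columns_give_one(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        assert icc(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        col = np.array([1.0, 2.0, 5.0, 9.0])
        val = icc(np.column_stack([col, col + 10.0]))
        assert val < 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_hand_anova(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((6, 3)) + rng.standard_normal((6, 1)) * 2
        assert icc(x) == pytest.approx(_oracle_icc21(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1)) * 2
        long = pd.DataFrame(
            {"subject": np.repeat(np.arange(8), 3),
             "rater": np.tile(np.arange(3), 8),
             "y": x.ravel()})
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="y")
        # ICC(A,1): two-way random, absolute agreement, single rater = ICC(2,1)
        want = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(x) == pytest.approx(want, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 3)))

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((2, 2)))


# ---------------------------------------------------------------------------
# Bland-Altman


class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(5.0)
        r = bland_altman(x, x)
        assert (r.bias, r.sd_diff, r.loa_low, r.loa_high) == (0, 0, 0, 0)

    def test_constant_difference(self):
        x = np.arange(4.0) + 1.0
        r = bland_altman(x, np.arange(4.0))
        assert r.bias == 1.0 and r.sd_diff == 0.0
        assert r.loa_low == r.loa_high == 1.0

    def test_two_point_hand_arithmetic(self):
        r = bland_altman([0.0, 2.0], [0.0, 0.0])
        assert r.bias == pytest.approx(1.0)
        assert r.sd_diff == pytest.approx(np.sqrt(2.0))
        assert r.loa_low == pytest.approx(1.0 - 1.96 * np.sqrt(2.0))
        assert r.loa_high == pytest.approx(1.0 + 1.96 * np.sqrt(2.0))

    def test_limits_formula_on_random_data(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 30))
        r = bland_altman(x, y)
        d = x - y
        assert r.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert r.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)


# ---------------------------------------------------------------------------
# Wilcoxon


def _oracle_wilcoxon_p(d):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev_obs = abs(w_obs - total / 2)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - total / 2) >= dev_obs - 1e-9:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_three_positive_differences(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(0.25)

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert r.degenerate and r.pvalue == 1.0

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        x = np.round(rng.standard_normal(n), 1)
        y = np.round(rng.standard_normal(n), 1)
        if np.all(x - y == 0):
            x[0] += 1.0
        r = wilcoxon_signed_rank(x, y)
        assert r.pvalue == pytest.approx(_oracle_wilcoxon_p(x - y), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40) * 0.5 + 0.3
        r = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x - y, correction=True, method="approx")
        assert r.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(11)
        d = rng.standard_normal(10)
        r = wilcoxon_signed_rank(d, np.zeros(10))
        ref = stats.wilcoxon(d, method="exact")
        assert r.pvalue == pytest.approx(float(ref.pvalue), abs=1e-12)


# ---------------------------------------------------------------------------
# FDR


def _oracle_fdr(p):
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_uniform_ladder_collapses(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_two_value_hand_arithmetic(self):
        np.testing.assert_allclose(fdr_adjust([0.005, 0.04]), [0.01, 0.04],
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(2, 15))
        np.testing.assert_allclose(fdr_adjust(p), _oracle_fdr(p), atol=1e-12)

    def test_monotone_in_input_order(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(10))
        adj = fdr_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
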