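"""Dice, Bhattacharyya, Wilcoxon and the method-comparison report."""

import itertools

import numpy as np
import pytest

from tractsheet.evaluation import (
    bhattacharyya_distance, compare_projection_methods, dice, fa_histogram,
    pairwise_median_dice, wilcoxon_signed_rank,
)
from tractsheet.types import BinaryMask, Histogram, ValidationError


def _mask(vox, dims=(6, 6, 6)):
    vals = np.zeros(dims, bool)
    for v in vox:
        vals[v] = True
    return BinaryMask(values=vals, affine=np.eye(4))


class TestDice:
    def test_identical_masks(self):
        m = _mask([(0, 0, 0), (1, 1, 1)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert dice(_mask([(0, 0, 0)]), _mask([(5, 5, 5)])) == 0.0

    def test_half_overlap_arithmetic(self):
        a = _mask([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        b = _mask([(2, 0, 0), (3, 0, 0), (4, 0, 0), (5, 0, 0)])
        assert dice(a, b) == 0.5

    def test_symmetry(self, rng):
        a = BinaryMask(values=rng.random((6, 6, 6)) > 0.5, affine=np.eye(4))
        b = BinaryMask(values=rng.random((6, 6, 6)) > 0.5, affine=np.eye(4))
        assert dice(a, b) == dice(b, a)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            dice(_mask([]), _mask([]))


class TestMedianDice:
    def test_identical_cohort(self):
        m = _mask([(0, 0, 0), (1, 1, 1)])
        assert np.allclose(pairwise_median_dice([m, m, m]), 1.0)

    def test_one_disjoint_subject(self):
        a = _mask([(0, 0, 0), (1, 0, 0)])
        b = _mask([(0, 0, 0), (1, 0, 0)])
        c = _mask([(5, 5, 5), (4, 4, 4)])
        med = pairwise_median_dice([a, b, c])
        assert med[2] == 0.0
        assert med[0] == med[1] == 0.5  # median over {1, 0}

    def test_brute_force_all_pairs_oracle(self, rng):
        masks = [BinaryMask(values=rng.random((5, 5, 5)) > 0.4, affine=np.eye(4))
                 for _ in range(6)]
        med = pairwise_median_dice(masks)
        for i in range(6):
            scores = [dice(masks[i], masks[j]) for j in range(6) if j != i]
            assert med[i] == pytest.approx(np.median(scores))


class TestHistogram:
    def test_single_bin_concentration(self):
        h = fa_histogram([0.55] * 20, n_bins=10)
        assert h.probs[5] == 1.0

    def test_uniform_sampling(self, rng):
        h = fa_histogram(rng.random(100_000), n_bins=10)
        assert np.all(np.abs(h.probs - 0.1) < 0.01)

    def test_probs_sum_to_one(self, rng):
        h = fa_histogram(rng.random(100), n_bins=7)
        assert h.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning):
            fa_histogram([0.5, 1.2], n_bins=4)


class TestBhattacharyya:
    def test_identity_zero(self):
        h = fa_histogram([0.1, 0.5, 0.9], n_bins=5)
        assert bhattacharyya_distance(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_bins(self):
        edges = np.array([0.0, 0.5, 1.0])
        p = Histogram(bin_edges=edges, probs=np.array([1.0, 0.0]))
        q = Histogram(bin_edges=edges, probs=np.array([0.5, 0.5]))
        assert bhattacharyya_distance(p, q) == pytest.approx(-np.log(np.sqrt(0.5)), abs=1e-9)
        assert bhattacharyya_distance(p, q) == pytest.approx(0.34657, abs=1e-5)

    def test_independent_summation_oracle(self, rng):
        for _ in range(20):
            a = rng.random(8); a /= a.sum()
            b = rng.random(8); b /= b.sum()
            edges = np.linspace(0, 1, 9)
            p, q = Histogram(edges, a), Histogram(edges, b)
            expect = -np.log(sum(np.sqrt(x * y) for x, y in zip(a, b)))
            assert bhattacharyya_distance(p, q) == pytest.approx(expect, abs=1e-12)
            assert bhattacharyya_distance(q, p) == bhattacharyya_distance(p, q)

    def test_disjoint_support_infinite(self):
        edges = np.array([0.0, 0.5, 1.0])
        p = Histogram(edges, np.array([1.0, 0.0]))
        q = Histogram(edges, np.array([0.0, 1.0]))
        with pytest.warns(UserWarning):
            assert bhattacharyya_distance(p, q) == np.inf

    def test_bin_permutation_invariance(self, rng):
        a = rng.random(6); a /= a.sum()
        b = rng.random(6); b /= b.sum()
        edges = np.linspace(0, 1, 7)
        perm = rng.permutation(6)
        d1 = bhattacharyya_distance(Histogram(edges, a), Histogram(edges, b))
        d2 = bhattacharyya_distance(Histogram(edges, a[perm]), Histogram(edges, b[perm]))
        assert d1 == pytest.approx(d2, abs=1e-12)


def _wilcoxon_brute_force(diffs, alternative):
    """Exhaustive enumeration over all sign assignments."""
    from scipy.stats import rankdata
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    ge = np.mean(ws >= w_obs - 1e-12)
    le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(le, ge))


class TestWilcoxon:
    def test_all_positive_n5_two_sided(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5])
        assert r.p_value == pytest.approx(2 / 32)

    def test_antisymmetric_p_one(self):
        r = wilcoxon_signed_rank([1.0, -1.0, 2.5, -2.5, 0.7, -0.7])
        assert r.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_matches_exhaustive_enumeration(self, alternative, rng):
        for n in range(5, 13):
            d = rng.normal(0.3, 1.0, size=n)
            d[d == 0] = 0.1
            r = wilcoxon_signed_rank(d, alternative=alternative)
            assert r.p_value == pytest.approx(
                _wilcoxon_brute_force(d, alternative), abs=1e-12)

    def test_ties_exact_enumeration(self, rng):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -3.0, 0.5])
        for alt in ("two_sided", "greater", "less"):
            assert wilcoxon_signed_rank(d, alternative=alt).p_value == pytest.approx(
                _wilcoxon_brute_force(d, alt), abs=1e-12)

    def test_zeros_dropped_and_reported(self):
        r = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, -1.0, 3.0, 0.5])
        assert r.n_zeros_dropped == 2
        assert r.n_used == 5

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_normal_approximation_close_to_exact(self, rng):
        d = rng.normal(0.4, 1.0, size=24)
        exact = wilcoxon_signed_rank(d, exact_max_n=25)
        approx = wilcoxon_signed_rank(d, exact_max_n=10)
        assert approx.method == "normal_approx"
        assert approx.p_value == pytest.approx(exact.p_value, rel=0.15)

    def test_p_in_unit_interval(self, rng):
        for n in (5, 10, 30):
            r = wilcoxon_signed_rank(rng.normal(size=n))
            assert 0.0 < r.p_value <= 1.0


class TestCompareProjectionMethods:
    def test_identical_tsa_zero_distance(self, rng):
        native = [rng.random(200) for _ in range(5)]
        tbss = [v + 0.05 for v in native]
        report, tests = compare_projection_methods(native, native, tbss, n_bins=20)
        assert len(report) == 5
        assert np.allclose(report["db_native_tsa"], 0.0)
        assert np.allclose(report["mean_tsa"] - report["mean_native"], 0.0)
        assert np.all(report["db_native_tbss"] > 0)

    def test_report_row_count(self, rng):
        n = 8
        vals = [rng.random(50) for _ in range(n)]
        report, _ = compare_projection_methods(vals, vals, vals)
        assert len(report) == n

    def test_inflated_tbss_detected(self, rng):
        """When every subject's TBSS values are shifted up, the one-sided
        paired Wilcoxon flags the mean inflation."""
        native = [np.clip(rng.normal(0.4, 0.05, 300), 0, 1) for _ in range(10)]
        tsa = [v + rng.normal(0, 0.002, v.shape) for v in native]
        tsa = [np.clip(v, 0, 1) for v in tsa]
        tbss = [np.clip(v + 0.1, 0, 1) for v in native]
        report, tests = compare_projection_methods(native, tsa, tbss, n_bins=50)
        assert tests["mean_tbss_vs_tsa_greater"].p_value < 0.05
        assert tests["db_tbss_vs_tsa_greater"].p_value < 0.05
        assert np.all(report["mean_tbss"] > report["mean_tsa"])
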