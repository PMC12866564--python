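"""Unit and property tests for the statistical kernels."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from phyllopan import stats
from phyllopan.stats import ContingencyTable2x2


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(c + d, c1 - k)
               for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)


class TestFisherExact:
    def test_worked_example(self):
        odds_ratio, p = stats.fisher_exact(ContingencyTable2x2(10, 90, 5, 195))
        assert odds_ratio == pytest.approx(10 * 195 / (90 * 5))
        assert p == pytest.approx(float(fisher_oracle(10, 90, 5, 195)), abs=1e-12)

    def test_symmetric_table_is_null(self):
        odds_ratio, p = stats.fisher_exact(ContingencyTable2x2(5, 5, 5, 5))
        assert odds_ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_infinite_or(self):
        odds_ratio, p = stats.fisher_exact(ContingencyTable2x2(2, 0, 0, 2))
        assert odds_ratio == math.inf
        assert p == pytest.approx(1 / 3)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 3, 4)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_scipy(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        _, p = stats.fisher_exact(ContingencyTable2x2(a, b, c, d))
        _, p_ref = scipy.stats.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_haldane_corrected_lor_flagged(self):
        lor, corrected = stats.log_odds_ratio(ContingencyTable2x2(3, 0, 1, 5))
        assert corrected
        assert lor == pytest.approx(math.log((3.5 * 5.5) / (0.5 * 1.5)))
        lor2, corrected2 = stats.log_odds_ratio(ContingencyTable2x2(2, 2, 2, 2))
        assert not corrected2 and lor2 == 0.0


class TestMultipleTesting:
    @pytest.mark.parametrize("pvals, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.04, 0.03], [0.015, 0.04, 0.04]),
        ([0.37], [0.37]),
        ([], []),
    ])
    def test_bh_worked_examples(self, pvals, expected):
        assert stats.bh_adjust(pvals) == pytest.approx(expected)

    @pytest.mark.parametrize("pvals, expected", [
        ([0.01, 0.01, 0.01], [0.03, 0.03, 0.03]),
        ([0.5, 0.6], [1.0, 1.0]),
        ([0.2], [0.2]),
    ])
    def test_bonferroni(self, pvals, expected):
        assert stats.bonferroni_adjust(pvals) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_bh_dominates_raw_and_is_monotone_on_sorted(self, pvals):
        adjusted = stats.bh_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-12)
        assert np.all(adjusted <= 1.0 + 1e-12)
        resorted = adjusted[np.argsort(pvals, kind="stable")]
        assert np.all(np.diff(resorted) >= -1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bh_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        assert stats.bh_adjust(pvals) == pytest.approx(ref, abs=1e-12)


def mwu_enumeration_oracle(x, y):
    """Two-sided p over all C(n1+n2, n1) labelings of the pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)
    mu = n1 * len(y) / 2

    def u_of(xs, ys):
        return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                   for xi in xs for yj in ys)

    dev_obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if abs(u_of(xs, ys) - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_small_separated_example(self):
        res = stats.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_all_tied(self):
        res = stats.mann_whitney_u([2, 2, 2], [2, 2, 2])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value == pytest.approx(1.0)

    def test_interleaved_example(self):
        res = stats.mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert res.statistic == pytest.approx(3.0)
        assert res.p_value == pytest.approx(
            mwu_enumeration_oracle([1, 3, 5], [2, 4, 6]))

    def test_exact_equals_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n1, n2 = rng.integers(1, 7, size=2)
            x = rng.integers(0, 4, size=n1).tolist()
            y = rng.integers(0, 4, size=n2).tolist()
            res = stats.mann_whitney_u(x, y, mode="exact")
            assert res.p_value == pytest.approx(mwu_enumeration_oracle(x, y),
                                                abs=1e-12), (x, y)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1, 2])

    def test_normal_mode_close_to_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=25)
        y = rng.normal(loc=0.8, size=30)
        res = stats.mann_whitney_u(x, y, mode="normal")
        ref = scipy.stats.mannwhitneyu(x, y, method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = stats.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_scores_equal(self):
        auc, _ = stats.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_partial_ranking(self):
        auc, _ = stats.roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_auc([0.1, 0.2], [1, 1])

    def test_auc_equals_normalized_u(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        auc, _ = stats.roc_auc(scores, labels)
        u = stats.mann_whitney_u(scores[labels == 1], scores[labels == 0],
                                 mode="normal").statistic
        assert auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_roc_endpoints(self):
        _, points = stats.roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert points[0] == pytest.approx([0.0, 0.0])
        assert points[-1] == pytest.approx([1.0, 1.0])
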