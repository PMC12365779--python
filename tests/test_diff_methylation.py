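"""Per-CpG testing: coverage filter, LRT/Fisher, BH, DMS calling."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import xlogy

import methylfollicle as mf
from methylfollicle.diff_methylation import EmptyResultError

from conftest import make_records


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def lrt_by_numeric_maximization(case_counts, control_counts):
    """LRT statistic via direct numerical maximization of the binomial
    log-likelihood under the null (common p) and alternative (per-group p)."""

    def negloglik(p, pairs):
        return -sum(xlogy(m, p) + xlogy(u, 1 - p) for m, u in pairs)

    def maximize(pairs):
        res = minimize_scalar(
            negloglik, args=(pairs,), bounds=(1e-9, 1 - 1e-9), method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    ll_alt = maximize(case_counts) + maximize(control_counts)
    ll_null = maximize(list(case_counts) + list(control_counts))
    return 2 * (ll_alt - ll_null)


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Two-sided Fisher p by direct enumeration of the hypergeometric tail."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)}
    cutoff = pmf[a] * (1 + 1e-7)
    return sum(p for p in pmf.values() if p <= cutoff)


def bh_bruteforce(p):
    """q_i = min over {j: p_j >= p_i} of p_j * n / rank(p_j), straight from
    the step-up definition, O(n^2)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        q[i] = min(
            min(p[j] * n / ranks[j] for j in range(n) if p[j] >= p[i]), 1.0
        )
    return q


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------


class TestFilterCoverage:
    def test_low_coverage_removed(self):
        recs = make_records({10: [(4, 5)], 20: [(5, 5)]}, "g")
        kept = mf.filter_coverage(recs, min_cov=10, max_percentile=100)
        assert {r.pos for r in kept} == {20}

    def test_boundary_coverage_retained(self):
        recs = make_records({p: [(5, 5)] for p in (10, 20, 30)}, "g")
        kept = mf.filter_coverage(recs, min_cov=10, max_percentile=100)
        assert len(kept) == 3

    def test_extreme_coverage_removed_by_percentile(self):
        """One million-fold site among ~30x sites exceeds the 99.9% quantile."""
        rng = np.random.default_rng(0)
        depths = rng.poisson(30, size=4000) + 1
        counts = {i + 1: [(int(d) // 2, int(d) - int(d) // 2)] for i, d in enumerate(depths)}
        counts[5000] = [(500_000, 500_000)]
        recs = make_records(counts, "g")
        ceiling = np.percentile([r.coverage for r in recs], 99.9)
        assert 1_000_000 > ceiling
        kept = mf.filter_coverage(recs, min_cov=1, max_percentile=99.9)
        assert 5000 not in {r.pos for r in kept}
        assert all(r.coverage <= ceiling for r in kept)

    def test_complete_case_intersection(self):
        recs = make_records({10: [(10, 10), (10, 10)], 20: [(10, 10), (2, 2)]}, "g")
        kept = mf.filter_coverage(recs, min_cov=10, max_percentile=100)
        assert {r.pos for r in kept} == {10}

    def test_empty_result_raises(self):
        recs = make_records({10: [(1, 1)]}, "g")
        with pytest.raises(EmptyResultError):
            mf.filter_coverage(recs, min_cov=10, max_percentile=100)

    @pytest.mark.parametrize("kwargs", [{"min_cov": 0}, {"max_percentile": 40.0}])
    def test_bad_parameters(self, kwargs):
        recs = make_records({10: [(10, 10)]}, "g")
        with pytest.raises(ValueError):
            mf.filter_coverage(recs, **{"min_cov": 10, "max_percentile": 99.9, **kwargs})


# ---------------------------------------------------------------------------
# Per-site tests
# ---------------------------------------------------------------------------


class TestTestCpg:
    def test_identical_groups_give_null(self):
        stat, p = mf.test_cpg([(15, 15)] * 3, [(15, 15)] * 3)
        assert stat == 0.0 and p == 1.0

    def test_extreme_separation(self):
        stat, p = mf.test_cpg([(30, 0), (30, 0)], [(0, 30), (0, 30)])
        assert p < 1e-6
        oracle = lrt_by_numeric_maximization([(30, 0), (30, 0)], [(0, 30), (0, 30)])
        assert stat == pytest.approx(oracle, abs=1e-5)

    @pytest.mark.parametrize(
        "case,control",
        [
            ([(12, 3), (8, 9)], [(4, 11), (6, 10), (2, 14)]),
            ([(1, 19)], [(10, 5), (9, 6)]),
            ([(7, 7), (6, 8), (9, 4)], [(5, 9), (8, 6)]),
        ],
    )
    def test_statistic_matches_numeric_oracle(self, case, control):
        stat, _ = mf.test_cpg(case, control)
        assert stat == pytest.approx(lrt_by_numeric_maximization(case, control), abs=1e-5)

    @pytest.mark.parametrize(
        "table", [(12, 3, 4, 11), (0, 10, 10, 0), (5, 5, 5, 5), (1, 0, 0, 1), (8, 2, 7, 3)]
    )
    def test_one_vs_one_equals_fisher_exact(self, table):
        a, b, c, d = table
        _, p = mf.test_cpg([(a, b)], [(c, d)])
        assert p == pytest.approx(fisher_two_sided_by_enumeration(a, b, c, d), abs=1e-9)

    def test_zero_coverage_group_is_untestable(self):
        stat, p = mf.test_cpg([(0, 0)], [(5, 5)])
        assert math.isnan(stat) and math.isnan(p)


class TestBhAdjust:
    def test_stepup_example(self):
        assert mf.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value(self):
        assert mf.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal(self):
        assert mf.bh_adjust([0.4] * 5) == pytest.approx([0.4] * 5)

    def test_nan_excluded_from_n(self):
        q = mf.bh_adjust([0.01, math.nan, 0.04])
        assert math.isnan(q[1])
        # n = 2 tested p-values, not 3
        assert q[0] == pytest.approx(0.02)
        assert q[2] == pytest.approx(0.04)

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(1, 200))
            p = rng.random(n) ** rng.uniform(0.5, 3)
            q = mf.bh_adjust(p)
            assert np.max(np.abs(q - bh_bruteforce(p))) < 1e-12
            q_sm = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(q - q_sm)) < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mf.bh_adjust([0.5, 1.5])


class TestCallDms:
    @pytest.mark.parametrize(
        "diff,q,is_dms,direction",
        [
            (30.0, 0.005, True, "hyper"),
            (25.0, 0.001, False, "none"),  # strict > on the difference
            (-40.0, 0.011, False, "none"),  # strict < on q
            (-25.1, 0.0099, True, "hypo"),
        ],
    )
    def test_threshold_boundaries(self, diff, q, is_dms, direction):
        r = mf.CpGTestResult("chr1", 1, 2, 2, 50 + diff, 50.0, diff, 1e-4, q_value=q)
        mf.call_dms([r])
        assert (r.is_dms, r.direction) == (is_dms, direction)


class TestCompareGroups:
    @staticmethod
    def _random_records(rng, n_sites=40, n_case=4, n_ctrl=3):
        records = []
        for pos in range(1, n_sites + 1):
            for i in range(n_case):
                cov = int(rng.integers(10, 40))
                m = int(rng.binomial(cov, 0.4))
                records.append(mf.CpGRecord("chr1", pos, m, cov - m, f"c{i}", "case"))
            for i in range(n_ctrl):
                cov = int(rng.integers(10, 40))
                m = int(rng.binomial(cov, 0.3))
                records.append(mf.CpGRecord("chr1", pos, m, cov - m, f"k{i}", "ctrl"))
        return records

    def test_label_swap_negates_diff_and_keeps_p(self):
        rng = np.random.default_rng(31)
        records = self._random_records(rng)
        fwd = mf.compare_groups(records, "case", "ctrl")
        rev = mf.compare_groups(records, "ctrl", "case")
        assert [r.pos for r in fwd] == [r.pos for r in rev]
        np.testing.assert_allclose(
            [r.meth_diff for r in fwd], [-r.meth_diff for r in rev], atol=1e-12
        )
        np.testing.assert_allclose(
            [r.p_value for r in fwd], [r.p_value for r in rev], rtol=1e-12
        )

    def test_diff_is_pooled_case_minus_control(self):
        records = make_records({5: [(30, 10), (10, 30)]}, "case", "c") + make_records(
            {5: [(5, 15), (5, 15)]}, "ctrl", "k"
        )
        (r,) = mf.compare_groups(records, "case", "ctrl")
        assert r.meth_frac_case == pytest.approx(50.0)
        assert r.meth_frac_control == pytest.approx(25.0)
        assert r.meth_diff == pytest.approx(25.0)

    def test_missing_group_raises(self):
        records = make_records({5: [(10, 10)]}, "case")
        with pytest.raises(EmptyResultError):
            mf.compare_groups(records, "case", "ghost")

    def test_one_vs_one_uses_fisher(self):
        records = make_records({5: [(12, 3)]}, "case", "c") + make_records(
            {5: [(4, 11)]}, "ctrl", "k"
        )
        (r,) = mf.compare_groups(records, "case", "ctrl")
        assert r.p_value == pytest.approx(
            fisher_two_sided_by_enumeration(12, 3, 4, 11), abs=1e-9
        )
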