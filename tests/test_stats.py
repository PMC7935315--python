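"""Unit and property tests for the statistical primitives.

Each primitive is checked against an independent oracle: full enumeration
of labelings for the rank test, a naive O(m^2) step-up for BH, the
rank-Pearson formula for Spearman, and scipy/statsmodels implementations as
external cross-checks.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from microsplice.stats import (
    bh_adjust,
    binomial_test,
    fisher_exact,
    holm_adjust,
    hypergeom_ora,
    mann_whitney,
    ora_scan,
    spearman_rho,
)


def enumerate_mw_pvalues(x, y):
    """Tail probabilities of U over all C(n+m, n) relabelings of the pool."""
    x, y = list(x), list(y)
    pooled = np.array(x + y, dtype=float)
    n, total = len(x), len(pooled)
    ranks = ss.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(total), n):
        us.append(ranks[list(combo)].sum() - n * (n + 1) / 2)
    us = np.array(us)
    return (us >= u_obs).mean(), (us <= u_obs).mean()


class TestMannWhitney:
    def test_separated_groups_two_sided(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12], sided="two")
        assert res.p == pytest.approx(0.1)  # 2 * 1/20
        assert res.method == "exact"

    def test_identical_groups(self):
        assert mann_whitney([5, 5, 5, 5], [5, 5, 5, 5]).p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7, size=2, endpoint=True)
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        pg, pl = enumerate_mw_pvalues(x, y)
        assert mann_whitney(x, y, "greater").p == pytest.approx(pg, abs=1e-12)
        assert mann_whitney(x, y, "less").p == pytest.approx(pl, abs=1e-12)
        assert mann_whitney(x, y, "two").p == pytest.approx(
            min(1.0, 2 * min(pg, pl)), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_approx_close_to_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, size=30).astype(float)  # ties force approx path
        y = rng.integers(0, 10, size=40).astype(float) + rng.integers(0, 3, 40)
        res = mann_whitney(x, y, "two")
        assert res.method == "approx"
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_refused_with_ties(self):
        with pytest.raises(ValueError, match="ties"):
            mann_whitney([1, 1, 2], [2, 3, 4], method="exact")


def bh_oracle(p):
    """Naive step-up: q_i = min over ranks j >= rank(i) of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_test(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_q_dominates_p_and_is_monotone_in_rank(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSpearman:
    def test_perfect_anti_rank(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_ties_match_rank_pearson_oracle(self):
        x, y = [1, 1, 2], [1, 2, 3]
        rx, ry = ss.rankdata(x), ss.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        y[rng.integers(0, 30, 5)] = np.nan
        keep = ~np.isnan(y)
        ref = ss.spearmanr(x[keep], y[keep]).statistic
        assert spearman_rho(x, y) == pytest.approx(ref, abs=1e-12)

    def test_undefined_cases_are_none(self):
        assert spearman_rho([1, 2], [3, 4]) is None
        assert spearman_rho([1, 1, 1], [1, 2, 3]) is None


class TestFisher:
    def test_perfect_separation(self):
        assert fisher_exact([[5, 0], [0, 5]], "greater") == pytest.approx(1 / 252)

    def test_balanced_table(self):
        assert fisher_exact([[1, 1], [1, 1]], "greater") == pytest.approx(5 / 6)

    def test_degenerate_margin(self):
        assert fisher_exact([[0, 0], [3, 4]], "greater") == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [1, 1]])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 25, size=(2, 2))
        for sided, alt in [("greater", "greater"), ("less", "less"), ("two", "two-sided")]:
            ref = ss.fisher_exact(table, alternative=alt).pvalue
            assert fisher_exact(table.tolist(), sided) == pytest.approx(ref, abs=1e-10)


class TestBinomial:
    def test_nine_of_ten(self):
        assert binomial_test(9, 10, 0.5, "two") == 22 / 1024

    def test_all_successes_one_sided(self):
        for n in (3, 10, 20):
            assert binomial_test(n, n, 0.5, "greater") == pytest.approx(0.5**n)

    def test_central_observation(self):
        assert binomial_test(5, 10, 0.5, "two") == 1.0

    def test_two_sided_doubles_tail_at_half(self):
        # symmetric null: two-sided = min(1, 2 * smaller tail)
        for k, n in [(8, 10), (2, 12), (15, 20)]:
            one = min(
                binomial_test(k, n, 0.5, "greater"), binomial_test(k, n, 0.5, "less")
            )
            assert binomial_test(k, n, 0.5, "two") == pytest.approx(min(1, 2 * one))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        ref = ss.binomtest(k, n, p0, alternative="two-sided").pvalue
        assert binomial_test(k, n, p0, "two") == pytest.approx(ref, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test(11, 10)
        with pytest.raises(ValueError):
            binomial_test(1, 10, p0=0.0)


class TestHypergeomORA:
    def test_full_overlap(self):
        u = set(range(10))
        assert hypergeom_ora(set(range(5)), set(range(5)), u, "greater") == pytest.approx(1 / 252)

    def test_expected_overlap_two_sided(self):
        # symmetric design: 2 of 4 drawn from a half-annotated universe of 8
        universe = set(range(8))
        query = {0, 1, 4, 5}
        annotated = {0, 1, 2, 3}
        assert hypergeom_ora(query, annotated, universe, "two") == 1.0

    def test_query_outside_universe(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_ora({"x"}, {"a"}, {"a", "b"})

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_fisher_on_induced_table(self, seed):
        rng = np.random.default_rng(seed)
        universe = set(range(int(rng.integers(10, 60))))
        query = set(rng.choice(sorted(universe), size=rng.integers(1, 10), replace=False))
        annotated = set(rng.choice(sorted(universe), size=rng.integers(1, 20), replace=False))
        k = len(query & annotated)
        d = len(universe) - len(query) - len(annotated) + k
        table = [[k, len(query) - k], [len(annotated) - k, d]]
        assert hypergeom_ora(query, annotated, universe, "greater") == pytest.approx(
            fisher_exact(table, "greater"), abs=1e-14
        )


def test_holm_matches_statsmodels():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=25)
    np.testing.assert_allclose(holm_adjust(p), multipletests(p, method="holm")[1], atol=1e-12)


def test_ora_scan_applies_stepdown():
    universe = set(range(40))
    query = set(range(10))
    sets = {"hit": set(range(10)), "miss": set(range(30, 40))}
    out = ora_scan(query, sets, universe)
    assert out["hit"][0] < 1e-6
    assert out["hit"][1] >= out["hit"][0]  # adjusted never smaller
    assert math.isclose(out["miss"][1], 1.0) or out["miss"][1] >= out["miss"][0]
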