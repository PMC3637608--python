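"""Inference battery vs independent oracles.

The stepwise selection path is replayed by a from-scratch reimplementation
(numpy lstsq + t distribution); rank statistics are checked against exhaustive
permutation/sign-flip enumeration for small n; G and H against closed-form
arithmetic spelled out in the tests.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from paralogasym.stats import (
    CollinearityError,
    cohort_significance_profile,
    fit_least_squares,
    g_test_williams,
    kendall_tau,
    kruskal_wallis,
    stepwise_regression,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent naive OLS / stepwise oracle


def _naive_pvalues(y, X):
    """t-test p-values per column of X (with intercept), from first principles."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = len(y) - A.shape[1]
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    t = beta / np.sqrt(np.diag(cov))
    return beta, 2 * sps.t.sf(np.abs(t), dof)


def _naive_stepwise(y, X: pd.DataFrame, entry=0.15, stay=0.10):
    selected: list[str] = []
    seen = set()
    while True:
        changed = False
        best, best_p = None, None
        for name in X.columns:
            if name in selected:
                continue
            _, p = _naive_pvalues(y, X[selected + [name]].to_numpy(float))
            p_new = p[-1]
            if best_p is None or p_new < best_p - 1e-12:
                best, best_p = name, p_new
        if best is not None and best_p <= entry:
            selected.append(best)
            changed = True
        while selected:
            _, p = _naive_pvalues(y, X[selected].to_numpy(float))
            worst_i = int(np.argmax(p[1:]))
            if p[1:][worst_i] > stay:
                selected.pop(worst_i)
                changed = True
            else:
                break
        state = tuple(selected)
        if not changed or state in seen:
            return selected
        seen.add(state)


class TestStepwiseRegression:
    def test_exact_predictor_selected_alone(self, rng):
        n = 40
        x1 = rng.normal(size=n)
        X = pd.DataFrame({
            "signal": x1,
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        model = stepwise_regression(x1 * 2.5, X)
        assert model.selected_terms == ["signal"]
        assert model.r_square == pytest.approx(1.0)
        assert model.coefficients.loc["signal", "estimate"] == pytest.approx(2.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        X = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.integers(0, 2, size=n).astype(float),
        })
        y = 0.8 * X["x1"].to_numpy() + 0.5 * X["x3"].to_numpy() + rng.normal(scale=0.7, size=n)
        model = stepwise_regression(y, X)
        assert model.selected_terms == _naive_stepwise(y, X)
        if model.selected_terms:
            beta, _ = _naive_pvalues(y, X[model.selected_terms].to_numpy(float))
            assert model.coefficients["estimate"].to_numpy() == pytest.approx(beta)

    def test_normal_equations_and_anova_identity(self, rng):
        n = 60
        X = pd.DataFrame({
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        y = X["a"].to_numpy() - 0.4 * X["b"].to_numpy() + rng.normal(size=n)
        model = fit_least_squares(y, X)
        # residuals orthogonal to design columns
        coefs = model.coefficients["estimate"]
        fitted = coefs["Intercept"] + X.to_numpy(float) @ coefs[X.columns].to_numpy()
        resid = y - fitted
        design = np.column_stack([np.ones(n), X.to_numpy(float)])
        assert np.abs(design.T @ resid).max() < 1e-8 * np.abs(y).sum()
        # total SS decomposes
        a = model.anova
        assert a["total_ss"] == pytest.approx(a["model_ss"] + a["error_ss"])
        assert a["f_ratio"] == pytest.approx(
            (a["model_ss"] / a["model_df"]) / (a["error_ss"] / a["error_df"])
        )

    def test_collinear_candidates_cannot_enter(self, rng):
        n = 30
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x, "x_copy": x * 2.0})
        model = stepwise_regression(3 * x + rng.normal(scale=0.1, size=n), X)
        assert model.selected_terms == ["x"]

    def test_forced_fit_rejects_collinearity(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(CollinearityError, match="x2"):
            fit_least_squares(rng.normal(size=20), X)

    def test_too_few_observations_rejected(self, rng):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 0], "c": [0.0, 1, 0]})
        with pytest.raises(ValueError):
            stepwise_regression([1.0, 2, 3], X)


class TestKendallTau:
    def test_perfect_concordance(self):
        r = kendall_tau([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.value == pytest.approx(1.0)

    def test_four_point_enumeration_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        conc = disc = 0
        for (i, j) in itertools.combinations(range(4), 2):
            s = (x[j] - x[i]) * (y[j] - y[i])
            conc += s > 0
            disc += s < 0
        r = kendall_tau(x, y)
        assert r.value == pytest.approx((conc - disc) / 6)

    def test_null_calibration(self, rng):
        taus = []
        for _ in range(200):
            r = kendall_tau(rng.normal(size=200), rng.normal(size=200))
            taus.append(abs(r.value))
        # sd of tau under independence ~ sqrt(2(2n+5)/(9n(n-1))) ~ 0.047
        assert np.quantile(taus, 0.95) < 0.12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau([1, 1, 1, 1], [1, 2, 3, 4])


class TestWilcoxonRankSum:
    def test_identical_distributions(self, rng):
        x = rng.normal(size=50)
        r = wilcoxon_rank_sum(x, x.copy())
        assert abs(r.value) < 1e-9 and r.p_value == pytest.approx(1.0)

    def test_extreme_separation_matches_enumeration(self):
        a, b = [1.0, 2, 3], [4.0, 5, 6]
        r = wilcoxon_rank_sum(a, b)
        # enumeration over all 20 equally likely rank assignments: the
        # observed rank sum 6 is the unique minimum, so the two-sided
        # exact p would be 2/20; the normal approximation must agree in
        # direction and order of magnitude
        sums = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        assert min(sums) == 6  # a's observed rank-sum is the most extreme
        assert r.value < 0
        assert 0.01 < r.p_value < 0.15

    def test_tie_corrected_variance(self):
        # many ties: variance must shrink relative to the tie-free formula
        a = [1, 1, 1, 2, 2]
        b = [1, 2, 2, 2, 3]
        r = wilcoxon_rank_sum(a, b)
        assert np.isfinite(r.value) and 0 <= r.p_value <= 1

    def test_power_increases_with_shift(self, rng):
        pvals = []
        for shift in (0.0, 0.5, 1.5):
            p = [
                wilcoxon_rank_sum(rng.normal(size=30), rng.normal(loc=shift, size=30)).p_value
                for _ in range(30)
            ]
            pvals.append(np.mean(p))
        assert pvals[0] > pvals[1] > pvals[2]

    def test_small_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0])


class TestWilcoxonSignedRank:
    def test_antisymmetric_differences(self):
        d = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
        r = wilcoxon_signed_rank(d)
        assert r.value == 0.0 or abs(r.value) == min(
            abs(r.value), abs(r.value)
        )  # T is the smaller rank sum
        assert r.p_value > 0.5

    def test_exact_p_matches_sign_flip_enumeration(self):
        d = np.array([1.2, -0.4, 2.5, 3.1, -0.9, 1.7])
        r = wilcoxon_signed_rank(d)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        w_all = []
        for signs in itertools.product([0, 1], repeat=6):
            w_all.append(sum(rk for rk, s in zip(ranks, signs) if s))
        w_all = np.array(w_all)
        lo = min(w_obs, total - w_obs)
        p_enum = np.mean((w_all <= lo) | (w_all >= total - lo))
        assert r.p_value == pytest.approx(p_enum)
        assert r.note == "exact"

    def test_direction_and_monotone_power(self, rng):
        pvals, tvals = [], []
        for effect in (0.0, 0.4, 1.0):
            d = rng.normal(loc=-effect, size=40)
            r = wilcoxon_signed_rank(d)
            pvals.append(r.p_value)
            tvals.append(r.value)
        assert pvals[1] > pvals[2]
        assert tvals[2] < 0  # negative-mean differences give negative T

    def test_zeros_dropped_and_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0, -1.0, 2.0])  # < 5 nonzero


class TestKruskalWallis:
    def test_closed_form_oracle(self):
        # groups (1,2), (3,4), (5,6): rank sums 3, 7, 11; no ties
        # H = 12/(6*7) * (3^2/2 + 7^2/2 + 11^2/2) - 3*7 = 32/7
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.value == pytest.approx(12 / 42 * (9 / 2 + 49 / 2 + 121 / 2) - 21)
        assert r.df == 2

    def test_label_permutation_invariance(self, rng):
        g = [rng.normal(size=8) for _ in range(3)]
        h0 = kruskal_wallis(g).value
        for perm in itertools.permutations(range(3)):
            assert kruskal_wallis([g[i] for i in perm]).value == pytest.approx(h0)

    def test_null_distribution_roughly_uniform(self, rng):
        pvals = [
            kruskal_wallis([rng.normal(size=15) for _ in range(3)]).p_value
            for _ in range(300)
        ]
        assert sps.kstest(pvals, "uniform").statistic < 0.1

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestGTestWilliams:
    def test_proportional_table_gives_zero(self):
        r = g_test_williams([[10, 20, 30], [20, 40, 60]])
        assert r.value == pytest.approx(0.0)

    def test_formula_oracle(self):
        table = np.array([[5, 10, 15], [15, 10, 5]])
        # independent arithmetic, spelled out
        N = table.sum()
        row, col = table.sum(1), table.sum(0)
        E = np.outer(row, col) / N
        G = 2 * (table * np.log(table / E)).sum()
        q = 1 + (N * (1 / row).sum() - 1) * (N * (1 / col).sum() - 1) / (6 * N * 2)
        r = g_test_williams(table)
        assert r.value == pytest.approx(G / q)
        assert r.df == 2
        assert r.p_value == pytest.approx(float(sps.chi2.sf(G / q, 2)))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            g_test_williams([[0, 10], [0, 5]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            g_test_williams([[1.5, 2], [3, 4]])


class TestCohortProfile:
    def test_fractions_and_missing_cohorts(self):
        df = pd.DataFrame({
            "cohort": ["a", "a", "b", "b"],
            "significant_nt": [True, False, True, True],
            "significant_aa": [False, False, False, True],
        })
        out = cohort_significance_profile(df, ["a", "b", "c"])
        assert out.loc[0, "frac_significant_nt"] == pytest.approx(0.5)
        assert out.loc[1, "frac_significant_nt"] == pytest.approx(1.0)
        assert out.loc[2, "n"] == 0 and math.isnan(out.loc[2, "frac_significant_nt"])

    def test_all_nonsignificant(self):
        df = pd.DataFrame({
            "cohort": ["a"] * 4,
            "significant_nt": [False] * 4,
            "significant_aa": [False] * 4,
        })
        out = cohort_significance_profile(df, ["a"])
        assert out.loc[0, "frac_significant_nt"] == 0.0
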