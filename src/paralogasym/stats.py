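"""Inference battery relating rate asymmetry to genomic features.

Centerpiece: stepwise multiple linear regression with *mixed* selection —
at each step the candidate with the smallest partial-F p-value enters if it
clears the entry threshold (default 0.15), then any included term whose
p-value has drifted above the stay threshold (default 0.10) is removed; the
procedure stops when no entry or removal occurs, and the selected terms are
refit by ordinary least squares. Two-level nominal predictors are coded 0/1
(reference levels: "same" chromosome, "homogeneous" structure), so reported
coefficients read as the effect of relocation / heterogeneity.

The remaining tests mirror a classical nonparametric toolkit: Kendall's
tau-b, Wilcoxon two-sample (normal approximation with tie-corrected
variance), Wilcoxon signed-rank (exact null for small untied samples),
Kruskal–Wallis, and the log-likelihood-ratio G-test with Williams'
correction. No multiple-testing correction is applied anywhere; each test is
reported at its own alpha, matching the per-test usage this battery
reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic_name: str  # Z, T, H, G_adj, tau, chi_square
    value: float
    p_value: float
    n: tuple[int, ...]
    df: int | None = None
    note: str = ""

    def __str__(self) -> str:
        df = f"; df = {self.df}" if self.df is not None else ""
        return f"{self.statistic_name} = {self.value:.4g}{df}; p = {self.p_value:.4g} (n = {self.n})"


# ---------------------------------------------------------------------------
# Stepwise regression


@dataclass
class StepwiseModel:
    """Selected predictors and the final least-squares fit, reported in the
    classical three blocks: summary of fit, ANOVA, parameter estimates."""

    selected_terms: list[str]
    coefficients: pd.DataFrame  # index: Intercept + terms; estimate/std_error/t_ratio/p_value
    r_square: float
    r_square_adj: float
    rmse: float
    mean_response: float
    n_obs: int
    anova: dict[str, float]
    selection_path: list[str] = field(default_factory=list)
    reference_levels: dict[str, str] = field(default_factory=dict)

    def render(self) -> str:
        lines = ["Summary of fit:"]
        lines.append(f"  R-square              {self.r_square:.4f}")
        lines.append(f"  R-square adjusted     {self.r_square_adj:.4f}")
        lines.append(f"  Root mean square error {self.rmse:.6g}")
        lines.append(f"  Mean of response      {self.mean_response:.6g}")
        lines.append(f"  Observations          {self.n_obs}")
        a = self.anova
        lines.append("Analysis of variance:")
        lines.append("  Source    df    Sum of squares   Mean square   F-ratio   p-value")
        lines.append(
            f"  Model     {a['model_df']:<5g} {a['model_ss']:<16.6g} {a['model_ms']:<13.6g} "
            f"{a['f_ratio']:<9.4g} {a['p_value']:.4g}"
        )
        lines.append(f"  Error     {a['error_df']:<5g} {a['error_ss']:<16.6g} {a['error_ms']:.6g}")
        lines.append(f"  C. Total  {a['total_df']:<5g} {a['total_ss']:.6g}")
        lines.append("Parameter estimates:")
        lines.append("  Term                         Estimate      Std. Error   t ratio   p-value")
        for term, row in self.coefficients.iterrows():
            lines.append(
                f"  {term:<28} {row['estimate']:<13.6g} {row['std_error']:<12.6g} "
                f"{row['t_ratio']:<9.3g} {row['p_value']:.4g}"
            )
        return "\n".join(lines)


class CollinearityError(ValueError):
    pass


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise CollinearityError(
            f"perfect collinearity among terms: {list(X.columns)}"
        )


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X.astype(float), has_constant="add")
    return sm.OLS(y, design).fit()


def fit_least_squares(y, predictors: pd.DataFrame, selection_path: list[str] | None = None) -> StepwiseModel:
    """Ordinary least-squares fit of all given predictors, reported in the
    same three-block shape the stepwise procedure emits."""
    y = np.asarray(y, dtype=float)
    X = predictors.copy()
    if len(X.columns):
        _check_rank(X)
    res = _ols(y, X)
    names = ["Intercept"] + list(X.columns)
    coef = pd.DataFrame(
        {
            "estimate": res.params.to_numpy(),
            "std_error": res.bse.to_numpy(),
            "t_ratio": res.tvalues.to_numpy(),
            "p_value": res.pvalues.to_numpy(),
        },
        index=names,
    )
    n = len(y)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    error_ss = float(res.ssr)
    model_ss = total_ss - error_ss
    model_df = len(X.columns)
    error_df = n - model_df - 1
    model_ms = model_ss / model_df if model_df else float("nan")
    error_ms = error_ss / error_df if error_df else float("nan")
    if model_df and error_df and error_ms > 0:
        f_ratio = model_ms / error_ms
        p = float(sps.f.sf(f_ratio, model_df, error_df))
    else:
        f_ratio, p = float("nan"), float("nan")
    return StepwiseModel(
        selected_terms=list(X.columns),
        coefficients=coef,
        r_square=float(res.rsquared) if model_df else 0.0,
        r_square_adj=float(res.rsquared_adj) if model_df else 0.0,
        rmse=math.sqrt(error_ms) if error_df else float("nan"),
        mean_response=float(y.mean()),
        n_obs=n,
        anova={
            "model_df": model_df, "error_df": error_df, "total_df": n - 1,
            "model_ss": model_ss, "error_ss": error_ss, "total_ss": total_ss,
            "model_ms": model_ms, "error_ms": error_ms,
            "f_ratio": f_ratio, "p_value": p,
        },
        selection_path=selection_path or [],
    )


def stepwise_regression(
    y,
    predictors: pd.DataFrame,
    entry_alpha: float = 0.15,
    stay_alpha: float = 0.10,
    max_steps: int = 100,
) -> StepwiseModel:
    """Mixed-selection stepwise linear regression.

    Candidate order (the column order of ``predictors``) breaks p-value ties
    deterministically. Preconditions: n > #candidates + 1; nominal candidates
    already coded as 0/1 indicators.
    """
    y = np.asarray(y, dtype=float)
    if predictors.isnull().any().any():
        raise ValueError("predictors contain missing values")
    candidates = list(predictors.columns)
    if len(y) <= len(candidates) + 1:
        raise ValueError("need n > number of candidate predictors + 1")
    selected: list[str] = []
    path: list[str] = []
    seen_states: set[tuple[str, ...]] = set()

    total_ss = float(np.sum((y - y.mean()) ** 2))
    for _ in range(max_steps):
        changed = False
        # entry: smallest partial-F p-value (== t-test p with 1 df) wins;
        # skipped when the current model already fits to machine precision
        # (partial tests on a ~zero residual are numerically meaningless)
        exact_fit = False
        if selected:
            ssr = float(_ols(y, predictors[selected]).ssr)
            exact_fit = ssr <= 1e-12 * max(total_ss, 1e-300)
        best_name, best_p = None, None
        for name in candidates if not exact_fit else []:
            if name in selected:
                continue
            trial = predictors[selected + [name]]
            mat = np.column_stack([np.ones(len(trial)), trial.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(mat) < mat.shape[1]:
                continue  # candidate collinear with current model; cannot enter
            p = float(_ols(y, trial).pvalues[name])
            if np.isnan(p):
                continue
            # ties (within numerical noise) go to the earlier candidate
            if best_p is None or p < best_p - 1e-12:
                best_name, best_p = name, p
        if best_name is not None and best_p <= entry_alpha:
            selected.append(best_name)
            path.append(f"+{best_name}")
            changed = True
        # removal: any included term whose p-value exceeds the stay threshold
        while selected:
            res = _ols(y, predictors[selected])
            pvals = res.pvalues[selected]
            worst = pvals.idxmax()
            if float(pvals[worst]) > stay_alpha:
                selected.remove(worst)
                path.append(f"-{worst}")
                changed = True
            else:
                break
        state = tuple(selected)
        if not changed or state in seen_states:
            break
        seen_states.add(state)

    model = fit_least_squares(y, predictors[selected], selection_path=path)
    return model


# ---------------------------------------------------------------------------
# Rank-based tests


def kendall_tau(x, y) -> TestResult:
    """Kendall's tau-b with tie correction; exact p for small untied samples,
    normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    has_ties = (len(np.unique(x)) < len(x)) or (len(np.unique(y)) < len(y))
    method = "exact" if (len(x) <= 30 and not has_ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return TestResult("tau", float(res.statistic), float(res.pvalue), (len(x),))


def wilcoxon_rank_sum(a, b, continuity: bool = False) -> TestResult:
    """Two-sample Wilcoxon rank-sum test, Z with tie-corrected variance,
    two-sided p from the normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    N = n1 + n2
    if N < 4:
        raise ValueError("total sample size < 4")
    ranks = sps.rankdata(np.concatenate([a, b]))
    W = float(ranks[:n1].sum())
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult("Z", 0.0, 1.0, (n1, n2), note="all observations tied")
    diff = W - mu
    if continuity:
        diff -= 0.5 * np.sign(diff)
    z = diff / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return TestResult("Z", float(z), min(p, 1.0), (n1, n2))


def wilcoxon_signed_rank(differences) -> TestResult:
    """One-sample Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; absolute values are midranked. The reported T is the
    smaller of the positive/negative rank sums, carrying the sign of the
    median nonzero difference (so a negative T means the negative differences
    dominate). p is exact for n <= 25 without ties, else a tie-corrected
    normal approximation on the positive rank sum.
    """
    d = np.asarray(differences, dtype=float)
    if len(d) and np.all(d == 0):
        raise ValueError("degenerate: all differences zero")
    d = d[d != 0]
    n = len(d)
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    direction = float(np.median(d))
    if direction == 0:
        direction = w_plus - w_minus
    T = min(w_plus, w_minus) * (1.0 if direction > 0 else -1.0)

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        res = sps.wilcoxon(d, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        note = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
        z = (w_plus - mu) / math.sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        note = "normal approximation"
    return TestResult("T", T, p, (n,), note=note)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from χ² with k−1 df."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    sizes = tuple(len(g) for g in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, 1.0, sizes, df=len(groups) - 1, note="all values tied")
    h, p = sps.kruskal(*arrays)
    return TestResult("H", float(h), float(p), sizes, df=len(groups) - 1)


def g_test_williams(table) -> TestResult:
    """Log-likelihood-ratio G-test of independence with Williams' correction.

    For an r x k table of counts, G = 2 sum O ln(O/E); Williams' divisor
    q = 1 + (N*sum(1/r_i) - 1)(N*sum(1/c_j) - 1) / (6N(r-1)(k-1));
    G_adj = G/q is referred to χ² with (r-1)(k-1) df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 rows and 2 columns")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain nonnegative integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in table")
    N = obs.sum()
    expected = np.outer(row, col) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    G = 2.0 * float(terms.sum())
    r, k = obs.shape
    df = (r - 1) * (k - 1)
    q = 1.0 + (N * (1.0 / row).sum() - 1.0) * (N * (1.0 / col).sum() - 1.0) / (6.0 * N * df)
    g_adj = G / q
    p = float(sps.chi2.sf(g_adj, df))
    return TestResult("G_adj", g_adj, p, tuple(int(x) for x in row), df=df)


# ---------------------------------------------------------------------------
# Cohort significance profile


def cohort_significance_profile(results: pd.DataFrame, cohort_order: list[str]) -> pd.DataFrame:
    """Fraction of pairs with a significant relative-rate test per age cohort.

    ``results`` needs columns cohort, significant_nt, significant_aa. Cohorts
    listed in ``cohort_order`` but absent from the data appear with n = 0 and
    missing fractions.
    """
    for col in ("cohort", "significant_nt", "significant_aa"):
        if col not in results.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for label in cohort_order:
        sub = results[results["cohort"] == label]
        n = len(sub)
        rows.append({
            "cohort": label,
            "n": n,
            "frac_significant_nt": float(sub["significant_nt"].mean()) if n else float("nan"),
            "frac_significant_aa": float(sub["significant_aa"].mean()) if n else float("nan"),
        })
    return pd.DataFrame(rows)
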