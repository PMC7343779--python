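"""Group statistics: multivariate GLM, univariate tests, FDR correction.

The battery mirrors a typical between-group neuroimaging analysis:

* a multivariate general linear model (MANCOVA) testing the effect of
  diagnostic group on several outcomes at once after partialling out
  covariates (age, head movement, scanner), via Wilks' Lambda with Rao's
  F approximation, plus per-outcome "between-subjects" F tests from the
  same linear model;
* pooled-variance two-sample t tests, Pearson chi-square for 2x2 tables,
  one-way ANOVA;
* Fisher-LSD style pairwise post-hocs that reuse the omnibus ANOVA's
  pooled within-group variance, with all p values pooled by the caller
  into one Benjamini-Hochberg FDR family.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from cortexdti.errors import DesignError, VarianceError


@dataclasses.dataclass
class TestResult:
    """A single hypothesis test with optional FDR-adjusted p value."""

    name: str
    statistic_name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_adjusted: float | None = None
    significant: bool | None = None


def _dummy_code(series: pd.Series, prefix: str) -> pd.DataFrame:
    """First-level-reference dummy coding of a categorical column."""
    levels = list(pd.unique(series))
    return pd.DataFrame(
        {f"{prefix}[{lev}]": (series == lev).astype(float) for lev in levels[1:]},
        index=series.index,
    )


def _build_design(
    data: pd.DataFrame, group: str, covariates: list[str]
) -> tuple[np.ndarray, list[str], int]:
    """Intercept + covariates + group dummies; returns (X, names, n_group_cols)."""
    parts = [pd.Series(1.0, index=data.index, name="intercept")]
    for cov in covariates:
        col = data[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = _dummy_code(col, cov)
            parts.extend(dummies[c] for c in dummies)
        else:
            parts.append(col.astype(float))
    group_dummies = _dummy_code(data[group], group)
    parts.extend(group_dummies[c] for c in group_dummies)
    X = pd.concat(parts, axis=1)
    return X.to_numpy(dtype=float), list(X.columns), group_dummies.shape[1]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that are linear combinations of earlier ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def _rss_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum-of-squares-and-cross-products matrix of Y on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid.T @ resid


def mancova(
    data: pd.DataFrame,
    outcomes: list[str],
    group: str,
    covariates: list[str] | None = None,
) -> tuple[TestResult, dict[str, TestResult]]:
    """Multivariate GLM: effect of ``group`` on ``outcomes`` given covariates.

    The multivariate effect is tested with Wilks' Lambda and Rao's F
    approximation; each outcome additionally gets a univariate F test
    (extra sum of squares for the group dummies) from the same model.
    Degrees of freedom are reported as the (df1, df2) pair of the F
    statistic.  Categorical covariates (object/categorical dtype, e.g.
    scanner) are dummy coded with a first-level reference.
    """
    covariates = list(covariates or [])
    Y = data[outcomes].to_numpy(dtype=float)
    n, p = Y.shape
    X_full, names, n_group = _build_design(data, group, covariates)
    _check_rank(X_full, names)
    X_red = X_full[:, : X_full.shape[1] - n_group]

    r_full = X_full.shape[1]
    ve = n - r_full  # error df
    vh = n_group  # hypothesis df
    if ve <= 0:
        raise DesignError("not enough observations for the design")

    E = _rss_matrix(X_full, Y)
    E_red = _rss_matrix(X_red, Y)
    H = E_red - E
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))

    # Rao's F approximation for Wilks' Lambda
    if p * p + vh * vh - 5 > 0:
        t = np.sqrt((p * p * vh * vh - 4.0) / (p * p + vh * vh - 5.0))
    else:
        t = 1.0
    w = ve + vh - (p + vh + 1) / 2.0
    df1 = p * vh
    df2 = w * t - (p * vh - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    p_mv = float(stats.f.sf(F, df1, df2))
    multivariate = TestResult(
        name=f"{group} (multivariate)",
        statistic_name="Wilks-F",
        statistic=float(F),
        df=(float(df1), float(df2)),
        p=p_mv,
    )

    per_outcome: dict[str, TestResult] = {}
    for j, out in enumerate(outcomes):
        y = Y[:, [j]]
        rss_full = _rss_matrix(X_full, y).item()
        rss_red = _rss_matrix(X_red, y).item()
        Fj = ((rss_red - rss_full) / vh) / (rss_full / ve)
        per_outcome[out] = TestResult(
            name=f"{group} on {out}",
            statistic_name="F",
            statistic=float(Fj),
            df=(float(vh), float(ve)),
            p=float(stats.f.sf(Fj, vh, ve)),
        )
    return multivariate, per_outcome


def ttest_ind(x, y, name: str = "t-test") -> TestResult:
    """Two-sample pooled-variance t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise VarianceError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(
        name=name, statistic_name="t", statistic=float(t),
        df=(float(len(x) + len(y) - 2),), p=float(p),
    )


def chi_square(table, name: str = "chi-square") -> TestResult:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        name=name, statistic_name="chi2", statistic=float(res.statistic),
        df=(float(res.dof),), p=float(res.pvalue),
    )


def anova_oneway(values, groups, name: str = "one-way ANOVA") -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) < 2 for s in samples):
        raise VarianceError("each group needs at least 2 observations")
    k, n = len(levels), len(values)
    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    F = (ss_between / df_b) / (ss_within / df_w)
    return TestResult(
        name=name, statistic_name="F", statistic=float(F),
        df=(float(df_b), float(df_w)), p=float(stats.f.sf(F, df_b, df_w)),
    )


def posthoc_pairwise(values, groups, name_prefix: str = "") -> list[TestResult]:
    """Fisher-LSD pairwise comparisons for all unordered group pairs.

    Each pair is compared with a t statistic whose denominator uses the
    pooled within-group variance (MS_within) of the omnibus one-way ANOVA,
    with N - k error degrees of freedom.  P values are returned raw — the
    caller pools them (e.g. regions x pairs) into one FDR family.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    samples = {g: values[groups == g] for g in levels}
    if len(levels) < 2 or any(len(s) < 2 for s in samples.values()):
        raise VarianceError("each group needs at least 2 observations")
    n, k = len(values), len(levels)
    ms_within = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / (n - k)
    df_err = n - k
    out = []
    for a, b in itertools.combinations(levels, 2):
        xa, xb = samples[a], samples[b]
        se = np.sqrt(ms_within * (1.0 / len(xa) + 1.0 / len(xb)))
        t = (xa.mean() - xb.mean()) / se
        out.append(
            TestResult(
                name=f"{name_prefix}{a} vs {b}",
                statistic_name="t(LSD)",
                statistic=float(t),
                df=(float(df_err),),
                p=float(2.0 * stats.t.sf(abs(t), df_err)),
            )
        )
    return out


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p values, rejection flags at level ``q``).  Adjusted
    values are ``p_(i) * m / i`` with a running minimum from the largest
    rank down, clipped to 1; a test is rejected when its adjusted p <= q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)
    adjusted = np.empty_like(adj_sorted)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def apply_fdr(results: list[TestResult], q: float = 0.05) -> list[TestResult]:
    """Annotate a family of TestResults with BH-adjusted p values in place."""
    adjusted, reject = fdr_bh([r.p for r in results], q=q)
    for r, pa, rej in zip(results, adjusted, reject):
        r.p_adjusted = float(pa)
        r.significant = bool(rej)
    return results
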