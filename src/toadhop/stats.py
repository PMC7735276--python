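"""Comparative statistics for the cohort analyses.

Implements the fixed-effects nested ANOVA (invasion category plus
population nested within category, Type III sums of squares), the
profile-analysis MANOVA of the category x trait interaction, backward
stepwise elimination for multiple regression, and Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    NestingDegeneracyError,
    ParameterError,
    RankDeficiencyError,
    UndefinedCorrelationError,
)


@dataclass
class AnovaResult:
    term: str
    df_num: int
    df_den: int
    F: float
    p: float
    wilks: float | None = None


@dataclass
class TermResult:
    name: str
    beta: float
    se: float
    t: float
    p: float


@dataclass
class RegressionResult:
    terms: list
    trace: list = field(default_factory=list)  # (name, p at removal), in order

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def retained(self) -> list:
        return [t.name for t in self.terms]


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


# --------------------------------------------------------------------------
# nested ANOVA
# --------------------------------------------------------------------------

def _sum_code(labels: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
    """Deviation (sum-to-zero) coding columns for a factor.

    ``rows`` optionally restricts the factor to a subset of rows (nested
    coding); outside rows the columns are zero.
    """
    labels = np.asarray(labels)
    n = len(labels)
    mask = np.ones(n, dtype=bool) if rows is None else rows
    levels = sorted(pd.unique(labels[mask]))
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[mask & (labels == lev), j] = 1.0
        cols[mask & (labels == levels[-1]), j] = -1.0
    return cols


def _ssr(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def nested_anova(
    y,
    invasion_category,
    population,
) -> list[AnovaResult]:
    """Fixed-effects ANOVA: y ~ category + population(category).

    Both factors are tested against the residual mean square with
    Type III (partial) sums of squares under sum-to-zero coding, matching
    the conventional treatment of a fixed nested design. Requires at least
    two populations per category (unless every category holds exactly one
    population, in which case the model collapses to a one-way ANOVA on
    category) and at least two observations per population.
    """
    y = np.asarray(y, dtype=float)
    cat = np.asarray(invasion_category)
    pop = np.asarray(population)
    if not (len(y) == len(cat) == len(pop)):
        raise ParameterError("y, category and population must have equal length")
    cats = sorted(pd.unique(cat))
    if len(cats) < 2:
        raise ParameterError("need at least two invasion categories")
    pops_per_cat = {c: sorted(pd.unique(pop[cat == c])) for c in cats}
    for c, ps in pops_per_cat.items():
        for p_ in ps:
            if np.sum((cat == c) & (pop == p_)) < 2:
                raise ParameterError(
                    f"population {p_!r} in category {c!r} has <2 observations"
                )
    n_single = sum(len(ps) == 1 for ps in pops_per_cat.values())
    if 0 < n_single < len(cats):
        bad = [c for c, ps in pops_per_cat.items() if len(ps) == 1]
        raise NestingDegeneracyError(
            f"category {bad[0]!r} contains a single population: the nested "
            f"term cannot be separated from the category effect"
        )
    collapse = n_single == len(cats)

    n = len(y)
    intercept = np.ones((n, 1))
    cat_cols = _sum_code(cat)
    blocks = [intercept, cat_cols]
    pop_cols = None
    if not collapse:
        pop_cols = np.hstack([_sum_code(pop, rows=(cat == c)) for c in cats])
        blocks.append(pop_cols)
    X_full = np.hstack(blocks)
    df_den = n - X_full.shape[1]
    if df_den < 1:
        raise ParameterError("no residual degrees of freedom")
    sse_full = _ssr(y, X_full)
    mse = sse_full / df_den
    scale = max(float(np.var(y)) * n, 1.0)

    def term_result(name: str, drop_cols: np.ndarray, keep: list[np.ndarray]) -> AnovaResult:
        ss = _ssr(y, np.hstack(keep)) - sse_full
        df_num = drop_cols.shape[1]
        if ss < 1e-12 * scale and mse < 1e-12 * scale:
            F, p = 0.0, 1.0
        elif mse == 0:
            F, p = np.inf, 0.0
        else:
            F = max(ss, 0.0) / df_num / mse
            p = float(sps.f.sf(F, df_num, df_den))
        return AnovaResult(name, df_num, df_den, float(F), p)

    results = [
        term_result("invasion_category", cat_cols,
                    [intercept] + ([pop_cols] if pop_cols is not None else []))
    ]
    if not collapse:
        results.append(
            term_result("population(invasion_category)", pop_cols,
                        [intercept, cat_cols])
        )
    return results


# --------------------------------------------------------------------------
# MANOVA: category x trait interaction (profile analysis)
# --------------------------------------------------------------------------

def manova_traits_interaction(
    trait_residuals,
    invasion_category,
    statistic: str = "wilks",
) -> AnovaResult:
    """Test whether multi-trait profiles are parallel across categories.

    Successive within-subject differences between adjacent trait columns
    form the contrast matrix; a one-way MANOVA of those contrasts on
    invasion category tests the category x trait interaction. Wilks'
    lambda with Rao's F approximation (exact for two categories) is the
    default; Pillai's trace is available via ``statistic="pillai"``.
    The reported numerator df follows the (traits-1) x (categories-1)
    convention.
    """
    Y = np.asarray(trait_residuals, dtype=float)
    cat = np.asarray(invasion_category)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ParameterError("need an (n, m) trait matrix with m >= 2 traits")
    if np.isnan(Y).any():
        raise ParameterError("trait matrix must have complete rows")
    if len(cat) != len(Y):
        raise ParameterError("category labels must match trait rows")
    D = np.diff(Y, axis=1)          # within-subject trait contrasts
    n, p = D.shape
    groups = sorted(pd.unique(cat))
    g = len(groups)
    if g < 2:
        raise ParameterError("need at least two categories")
    nu_e = n - g
    if p > nu_e:
        raise RankDeficiencyError(
            f"{p} trait contrasts exceed {nu_e} residual df"
        )
    grand = D.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for grp in groups:
        Dg = D[cat == grp]
        mg = Dg.mean(axis=0)
        C = Dg - mg
        E += C.T @ C
        H += len(Dg) * np.outer(mg - grand, mg - grand)
    q = g - 1
    df_num = p * q
    if statistic == "wilks":
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        t = (
            np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
            if p * p + q * q - 5.0 > 0 else 1.0
        )
        omega = nu_e + q - (p + q + 1.0) / 2.0
        df_den = omega * t - (p * q - 2.0) / 2.0
        lam_t = lam ** (1.0 / t)
        F = (1.0 - lam_t) / lam_t * df_den / df_num if lam_t > 0 else np.inf
        pval = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        return AnovaResult("invasion_category x trait", df_num, int(round(df_den)),
                           float(F), pval, wilks=lam)
    if statistic == "pillai":
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        s = min(p, q)
        m_ = 0.5 * (abs(p - q) - 1.0)
        n_ = 0.5 * (nu_e - p - 1.0)
        df1 = s * (2.0 * m_ + s + 1.0)
        df2 = s * (2.0 * n_ + s + 1.0)
        F = (df2 / df1) * V / (s - V) if s - V > 0 else np.inf
        pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        return AnovaResult("invasion_category x trait", int(df1), int(round(df2)),
                           float(F), pval)
    raise ParameterError(f"unknown statistic {statistic!r}")


# --------------------------------------------------------------------------
# backward stepwise elimination
# --------------------------------------------------------------------------

def backward_eliminate(
    y,
    predictors: pd.DataFrame,
    stay_threshold: float = 0.05,
    condition_tol: float = 1e8,
) -> RegressionResult:
    """Backward stepwise OLS: drop the weakest term until all p < threshold.

    At each step the full model (with intercept) is refitted and the term
    with the largest p-value at or above ``stay_threshold`` is removed
    (ties broken towards the later column). The removal order is recorded
    in ``trace``.
    """
    y = np.asarray(y, dtype=float)
    X = predictors.copy()
    if not isinstance(X, pd.DataFrame):
        raise ParameterError("predictors must be a DataFrame with named columns")
    k = X.shape[1]
    if len(y) <= k + 2:
        raise ParameterError(f"need n > predictors + 2 (n={len(y)}, k={k})")
    Z = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    if k >= 2:
        corr = Z.corr().to_numpy()
        iu = np.triu_indices(k, 1)
        worst = np.argmax(np.abs(corr[iu]))
        if np.abs(corr[iu][worst]) > 1 - 1e-10:
            pair = (X.columns[iu[0][worst]], X.columns[iu[1][worst]])
            raise CollinearityError(
                f"predictors {pair[0]!r} and {pair[1]!r} are collinear", pair=pair
            )
        if np.linalg.cond(Z.to_numpy()) > condition_tol:
            raise CollinearityError("predictor matrix ill-conditioned", pair=None)

    trace = []
    while X.shape[1] > 0:
        model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        pvals = model.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p < stay_threshold:
            terms = [
                TermResult(c, float(model.params[c]), float(model.bse[c]),
                           float(model.tvalues[c]), float(model.pvalues[c]))
                for c in X.columns
            ]
            return RegressionResult(terms=terms, trace=trace)
        ties = [c for c in X.columns if pvals[c] >= worst_p - 1e-12]
        drop = ties[-1]  # later column wins the tie
        trace.append((drop, float(pvals[drop])))
        X = X.drop(columns=[drop])
    return RegressionResult(terms=[], trace=trace)


# --------------------------------------------------------------------------
# Pearson correlation
# --------------------------------------------------------------------------

def pearson_corr(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedCorrelationError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(x), p=float(res.pvalue))
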