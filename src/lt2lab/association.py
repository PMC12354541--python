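"""Association analyses: correlations with interpretation bands, sex-group
comparison, bidirectional stepwise-AIC multiple regression, and
commonality analysis of the regression variance.

The stepwise search starts from the intercept-only model and at each
step evaluates every single-term addition and removal, applying the move
with the largest AIC reduction until none reduces AIC.  The AIC
convention is ``n·log(RSS/n) + 2·k`` (k = number of estimated mean
parameters including the intercept), which differs from the likelihood
form only by an additive constant shared across models on the same data
— only AIC differences drive selection.

Commonality analysis decomposes the full-model R² of three predictors
into seven components: a unique effect per predictor (the R² lost when
that predictor is dropped from the full model) and common effects for
every predictor subset, obtained by inclusion-exclusion over the R² of
all subset regressions.  Components may be negative (suppression); they
always sum to the full-model R².
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import InsufficientDataError

__all__ = [
    "CorrelationResult",
    "GroupComparison",
    "RegressionResult",
    "CommonalityResult",
    "correlate",
    "group_compare",
    "stepwise_aic",
    "commonality",
    "ols_fit",
]


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p: float
    n: int
    method: str  # "pearson" | "spearman"
    interpretation: str


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t-test" | "wilcoxon-rank-sum"
    statistic: float
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    beta: float
    se: float
    std_beta: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[RegressionTerm, ...]  # intercept first
    r2: float
    adj_r2: float
    f: float
    p: float
    aic: float
    step_trace: tuple[tuple[str, str | None, float], ...]  # (action, term, aic)


@dataclass(frozen=True)
class CommonalityResult:
    components: dict[tuple[str, ...], float]
    total_r2: float
    percent_of_total: dict[tuple[str, ...], float]


_CORR_BANDS = ((0.30, "negligible"), (0.50, "low"), (0.70, "moderate"),
               (0.90, "high"), (np.inf, "very_high"))


def _interpret_r(r: float) -> str:
    for cut, label in _CORR_BANDS:
        if abs(r) < cut:
            return label
    return "very_high"


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson's r or Spearman's rho with a two-sided p and the
    0.30/0.50/0.70/0.90 interpretation bands."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("correlation needs >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method '{method}'")
    return CorrelationResult(coefficient=float(r), p=float(p), n=int(x.size),
                             method=method, interpretation=_interpret_r(float(r)))


def group_compare(values, groups, normal: bool = True) -> GroupComparison:
    """Two-group comparison: independent-sample t-test under normality,
    Wilcoxon rank-sum otherwise."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    g1 = values[groups == levels[0]]
    g2 = values[groups == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if normal:
        res = stats.ttest_ind(g1, g2)
        name = "t-test"
    else:
        res = stats.ranksums(g1, g2)
        name = "wilcoxon-rank-sum"
    return GroupComparison(test_name=name, statistic=float(res.statistic),
                           p=float(res.pvalue), n1=len(g1), n2=len(g2))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def aic_ols(y: np.ndarray, X: np.ndarray) -> float:
    """AIC (up to a data-shared constant) of an OLS fit with design X."""
    n = y.size
    rss = _rss(y, X)
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * X.shape[1]


def _design(candidates: pd.DataFrame, names) -> np.ndarray:
    cols = [np.ones(len(candidates))]
    cols += [candidates[n].to_numpy(float) for n in names]
    return np.column_stack(cols)


def ols_fit(y, candidates: pd.DataFrame, names,
            step_trace=()) -> RegressionResult:
    """Full OLS report (coefficients, SE, standardized beta, t, p, R²,
    adjusted R², F, AIC) for the given predictor subset."""
    y = np.asarray(y, float)
    names = list(names)
    n = y.size
    X = _design(candidates, names)
    p_terms = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dfe = n - p_terms
    adj = 1.0 - (1.0 - r2) * (n - 1) / dfe if dfe > 0 else np.nan
    sigma2 = rss / dfe if dfe > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfe)

    # standardized betas: z-score y and each predictor, refit
    std_beta = np.full(p_terms, np.nan)
    if names:
        Z = np.column_stack(
            [np.ones(n)] + [
                (candidates[c].to_numpy(float) - candidates[c].mean())
                / candidates[c].std(ddof=1)
                for c in names
            ])
        zb, *_ = np.linalg.lstsq(Z, (y - y.mean()) / y.std(ddof=1), rcond=None)
        std_beta[1:] = zb[1:]

    if names and rss > 1e-300 * max(tss, 1.0):
        f_stat = ((tss - rss) / (p_terms - 1)) / (rss / dfe)
        f_p = float(stats.f.sf(f_stat, p_terms - 1, dfe))
    elif names:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat, f_p = np.nan, np.nan

    terms = tuple(
        RegressionTerm(name=nm, beta=float(b), se=float(s),
                       std_beta=float(sb), t=float(t_), p=float(p_))
        for nm, b, s, sb, t_, p_ in zip(
            ["(Intercept)"] + names, beta, se, std_beta, tvals, pvals)
    )
    return RegressionResult(
        terms=terms, r2=r2, adj_r2=float(adj), f=float(f_stat), p=float(f_p),
        aic=float(aic_ols(y, X)), step_trace=tuple(step_trace),
    )


def stepwise_aic(y, candidates: pd.DataFrame) -> RegressionResult:
    """Bidirectional stepwise OLS selection by AIC reduction, starting
    from the intercept-only model."""
    y = np.asarray(y, float)
    names = list(candidates.columns)
    n = y.size
    if n <= len(names) + 2:
        raise InsufficientDataError(
            f"n = {n} too small for {len(names)} candidates")
    full = _design(candidates, names)
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(f"candidate columns are rank deficient: {names}")

    selected: list[str] = []
    current_aic = aic_ols(y, _design(candidates, selected))
    trace: list[tuple[str, str | None, float]] = [("start", None, current_aic)]

    while True:
        moves = []
        for nm in names:
            if nm not in selected:
                cand = selected + [nm]
                moves.append(("add", nm, aic_ols(y, _design(candidates, cand))))
        for nm in selected:
            cand = [s for s in selected if s != nm]
            moves.append(("drop", nm, aic_ols(y, _design(candidates, cand))))
        if not moves:
            break
        action, nm, best = min(moves, key=lambda m: m[2])
        if best >= current_aic - 1e-12:
            break
        if action == "add":
            selected.append(nm)
        else:
            selected.remove(nm)
        current_aic = best
        trace.append((action, nm, best))

    return ols_fit(y, candidates, selected, step_trace=trace)


def _subset_r2(y: np.ndarray, candidates: pd.DataFrame, names) -> dict[frozenset, float]:
    r2 = {}
    all_names = list(names)
    tss = float(((y - y.mean()) ** 2).sum())
    for k in range(1, len(all_names) + 1):
        for combo in itertools.combinations(all_names, k):
            X = _design(candidates, combo)
            r2[frozenset(combo)] = 1.0 - _rss(y, X) / tss
    r2[frozenset()] = 0.0
    return r2


def commonality(y, x1, x2, x3, names=("x1", "x2", "x3")) -> CommonalityResult:
    """Commonality decomposition of the R² of y on three predictors.

    Returns the seven components keyed by predictor-name tuples; they sum
    to the full-model R² (machine precision) and individual common
    effects may be negative.
    """
    y = np.asarray(y, float)
    n = y.size
    if n <= 5:
        raise InsufficientDataError("commonality analysis needs n > 5")
    names = tuple(names)
    cand = pd.DataFrame({names[0]: np.asarray(x1, float),
                         names[1]: np.asarray(x2, float),
                         names[2]: np.asarray(x3, float)})
    X_full = _design(cand, names)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError(f"predictors are rank deficient: {list(names)}")
    R = _subset_r2(y, cand, names)
    n1, n2, n3 = names
    f = frozenset
    total = R[f(names)]
    comp = {
        (n1,): total - R[f((n2, n3))],
        (n2,): total - R[f((n1, n3))],
        (n3,): total - R[f((n1, n2))],
        (n1, n2): R[f((n1, n3))] + R[f((n2, n3))] - R[f((n3,))] - total,
        (n1, n3): R[f((n1, n2))] + R[f((n2, n3))] - R[f((n2,))] - total,
        (n2, n3): R[f((n1, n2))] + R[f((n1, n3))] - R[f((n1,))] - total,
        (n1, n2, n3): (total + R[f((n1,))] + R[f((n2,))] + R[f((n3,))]
                       - R[f((n1, n2))] - R[f((n1, n3))] - R[f((n2, n3))]),
    }
    pct = {k: (100.0 * v / total if total != 0 else np.nan)
           for k, v in comp.items()}
    return CommonalityResult(components=comp, total_r2=total,
                             percent_of_total=pct)
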