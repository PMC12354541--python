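"""Agreement between modeled and experimentally determined power at LT2.

Two complementary views are computed for each model variant:

* **Bland-Altman** — fixed bias (mean of paired differences, tested
  against zero with a one-sample t-test), random bias (limits of
  agreement, mean ± 1.96·SD), and proportional bias (two-sided t-test of
  the slope of the OLS line of differences on pairwise means).  A
  relative variant expresses each difference as a percentage of the
  pairwise mean.

* **ICC(A,1)** — the intraclass correlation for a two-way model, single
  measurement, absolute agreement, in the McGraw-Wong definitional
  frame:

      ICC(A,1) = (MSR - MSE) / (MSR + (k-1)·MSE + k/n·(MSC - MSE))

  with MSR/MSC/MSE the subject, method and error mean squares of the
  n×k table (here k = 2 methods).  The 95% CI uses the F-based
  approximation of the same framework, with the Satterthwaite degrees
  of freedom

      v = (a·MSC + b·MSE)² / [(a·MSC)²/(k-1) + (b·MSE)²/((n-1)(k-1))],
      a = k·ICC / (n·(1-ICC)),  b = 1 + k·ICC·(n-1)/(n·(1-ICC)).

  Interpretation bands: < 0.50 poor, 0.50-0.75 moderate, 0.75-0.90
  good, > 0.90 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import Config, DEFAULT_CONFIG, InsufficientDataError

__all__ = ["BlandAltmanResult", "ICCResult", "bland_altman", "icc_a1"]


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float  # W (a - b)
    sd_diff: float
    loa_low: float
    loa_high: float
    mean_diff_pct: float  # 100·(a-b)/pairwise mean
    sd_diff_pct: float
    loa_low_pct: float
    loa_high_pct: float
    fixed_bias_p: float
    prop_slope: float
    prop_intercept: float
    prop_slope_p: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    interpretation: str
    n: int
    k: int = 2


def _interpret_icc(icc: float) -> str:
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def bland_altman(a, b, cfg: Config = DEFAULT_CONFIG) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements ``a`` (e.g. modeled)
    vs ``b`` (criterion)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 3:
        raise InsufficientDataError(f"Bland-Altman needs >= 3 pairs, got {n}")
    d = a - b
    m = (a + b) / 2.0

    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    half = cfg.loa_multiplier * sd_diff

    if np.allclose(d, d[0], rtol=0.0, atol=1e-10 * max(1.0, abs(mean_diff))):
        # (near-)zero-variance differences: t-test degenerate
        fixed_p = 0.0 if abs(mean_diff) > 0 else 1.0
    else:
        fixed_p = float(stats.ttest_1samp(d, 0.0).pvalue)

    # proportional bias: OLS of d on m
    if np.all(m == m[0]) or np.allclose(d, d.mean()):
        slope, intercept, slope_p = 0.0, mean_diff, 1.0
    else:
        lr = stats.linregress(m, d)
        slope, intercept, slope_p = float(lr.slope), float(lr.intercept), float(lr.pvalue)

    nz = m != 0
    if not np.all(nz):
        warnings.warn("pairs with zero mean excluded from the relative "
                      "Bland-Altman variant", stacklevel=2)
    rel = 100.0 * d[nz] / m[nz]
    mean_pct = float(rel.mean())
    sd_pct = float(rel.std(ddof=1)) if rel.size > 1 else 0.0
    half_pct = cfg.loa_multiplier * sd_pct

    return BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - half, loa_high=mean_diff + half,
        mean_diff_pct=mean_pct, sd_diff_pct=sd_pct,
        loa_low_pct=mean_pct - half_pct, loa_high_pct=mean_pct + half_pct,
        fixed_bias_p=fixed_p, prop_slope=slope, prop_intercept=intercept,
        prop_slope_p=slope_p, n=int(n),
    )


def icc_a1(a, b, alpha: float = 0.05) -> ICCResult:
    """ICC for absolute agreement of two measurement methods (single
    measurements, two-way model); see the module docstring for formulas."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise InsufficientDataError("ICC needs >= 2 paired observations")
    if n < 5:
        warnings.warn(f"ICC on only {n} pairs is unstable", stacklevel=2)

    table = np.column_stack([a, b])
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    sst = float(((table - grand) ** 2).sum())
    ssr = float(k * ((row_means - grand) ** 2).sum())
    ssc = float(n * ((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    if sst <= 0:
        raise ValueError("degenerate table: zero total variance")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # F-based CI (two-way absolute agreement, single measurement)
    if icc >= 1.0 - 1e-15:
        lo, hi = icc, icc
    else:
        a_coef = (k * icc) / (n * (1.0 - icc))
        b_coef = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        num = (a_coef * msc + b_coef * mse) ** 2
        den = ((a_coef * msc) ** 2 / (k - 1)
               + (b_coef * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num / den if den > 0 else np.inf
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_lo * mse)
              / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_hi * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi),
                     interpretation=_interpret_icc(float(icc)), n=int(n))
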