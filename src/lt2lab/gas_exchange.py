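"""Gas-exchange processing: V̇O2peak, exhaustion verification, stage
averaging, the submaximal V̇O2-power regression, fractional utilization,
and oxygen cost / gross efficiency at three target intensities.

V̇O2peak is the highest 30-s moving average of the per-second V̇O2 trace
(right-aligned full windows).  All submaximal spirometric data — stages
up to and including the LT2 power — are averaged over the last 60 s of
each stage, and ordinary least squares of V̇O2 (and V̇CO2) on power over
those stage means yields the economy regression.  Oxygen cost of cycling
(Cc, mL·min⁻¹·W⁻¹) and gross efficiency (GE, %) are evaluated on that
regression line at three intensities: a fixed 3 W·kg⁻¹, the power at 75%
V̇O2peak, and 90% of the LT2 power.

Energy expenditure for GE follows the standard non-protein carbohydrate/
fat stoichiometry for moderate exercise: EE [kcal·min⁻¹] =
0.550·V̇CO2 [L·min⁻¹] + 4.471·V̇O2 [L·min⁻¹], converted with
1 kcal·min⁻¹ = 69.733 W (4184 J/kcal / 60 s).  Since Cc and GE at a
given power both derive from the same predicted gas-exchange values they
are tied by an exact inverse relationship at fixed RER.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import Config, DEFAULT_CONFIG, InsufficientDataError, StepTest

__all__ = [
    "GasExchangeSummary",
    "SubmaxRegression",
    "EconomyResult",
    "vo2peak",
    "check_exhaustion",
    "stage_average",
    "submax_regression",
    "economy",
    "ge_at",
    "metabolic_power",
    "summarize_gas_exchange",
    "KCAL_PER_L_VO2",
    "KCAL_PER_L_VCO2",
    "WATT_PER_KCAL_MIN",
]

# Energy equivalents (kcal per litre of gas) and unit bridge, kept in one
# place; see module docstring.
KCAL_PER_L_VO2 = 4.471
KCAL_PER_L_VCO2 = 0.550
WATT_PER_KCAL_MIN = 4184.0 / 60.0  # = 69.7333... W per kcal·min⁻¹


@dataclass(frozen=True)
class GasExchangeSummary:
    """Peak-exercise summary of one step test."""

    vo2peak: float  # mL·min⁻¹
    vo2peak_rel: float  # mL·kg⁻¹·min⁻¹
    peak_power: float  # W
    rer_max: float
    hr_max: float | None
    bla_max: float
    exhaustion_criteria_met: int
    exhaustion_ok: bool


@dataclass(frozen=True)
class SubmaxRegression:
    """OLS of stage-mean V̇O2 and V̇CO2 on power over submaximal stages."""

    slope_vo2: float  # mL·min⁻¹·W⁻¹
    intercept_vo2: float  # mL·min⁻¹
    slope_vco2: float
    intercept_vco2: float
    stages_used: tuple[int, ...]
    r2: float

    def predict_vo2(self, power):
        return self.intercept_vo2 + self.slope_vo2 * np.asarray(power, float)

    def predict_vco2(self, power):
        return self.intercept_vco2 + self.slope_vco2 * np.asarray(power, float)


@dataclass(frozen=True)
class EconomyResult:
    """Fractional utilization and Cc/GE at the three target intensities."""

    frac_util: float  # fraction of V̇O2peak at LT2
    cc_fix: float  # mL·min⁻¹·W⁻¹ at 3 W·kg⁻¹
    cc_frac_vo2: float  # at 75% V̇O2peak
    cc_frac_lt2: float  # at 90% LT2 power
    ge_fix: float  # %
    ge_frac_vo2: float
    ge_frac_lt2: float
    eval_powers: tuple[float, float, float]  # W (fix, %V̇O2peak, %LT2)
    warnings: tuple[str, ...] = ()


def vo2peak(breaths, window: float = 30.0) -> float:
    """Highest ``window``-s moving average of V̇O2 (full windows only).

    Expects the per-second sampling of the input contract; windows are
    right-aligned and partial windows at the series edges are ignored.
    """
    v = np.asarray(breaths["vo2"], dtype=float)
    w = int(round(window))
    if v.size < w:
        raise InsufficientDataError(
            f"breath series of {v.size} s shorter than {w}-s window")
    means = np.convolve(v, np.full(w, 1.0 / w), mode="valid")
    return float(means.max())


def check_exhaustion(rer_max: float, hr_max: float | None, age: float,
                     bla_max: float, volitional: bool) -> tuple[int, bool]:
    """Count the satisfied exhaustion criteria and verify at least two.

    Criteria: RER >= 1.10; HR >= 95% of the age-predicted maximum
    (220 - age); bLa >= 8 mmol·L⁻¹; volitional exhaustion.  A missing HR
    simply cannot satisfy its criterion.  Boundary equality counts as
    met.  A count of 1 is reported as not ok; callers may still retain
    such tests, flagged.
    """
    count = 0
    if rer_max >= 1.10:
        count += 1
    if hr_max is not None and not np.isnan(hr_max) and hr_max >= 0.95 * (220.0 - age):
        count += 1
    if bla_max >= 8.0:
        count += 1
    if volitional:
        count += 1
    return count, count >= 2


def stage_average(breaths, stage, tail: float = 60.0) -> tuple[float, float]:
    """Mean V̇O2 and V̇CO2 over the last ``tail`` s of a stage.

    Samples with ``end_t - tail < t <= end_t`` enter the mean; fewer than
    80% of the expected per-second samples raises a coverage error.
    """
    t = np.asarray(breaths["t"], dtype=float)
    mask = (t > stage.end_t - tail) & (t <= stage.end_t)
    n = int(mask.sum())
    if n < 0.8 * tail:
        raise InsufficientDataError(
            f"stage {stage.index}: only {n} breath samples in the last "
            f"{tail:.0f} s (need >= {0.8 * tail:.0f})")
    vo2 = float(np.asarray(breaths["vo2"], float)[mask].mean())
    vco2 = float(np.asarray(breaths["vco2"], float)[mask].mean())
    return vo2, vco2


def submax_regression(stage_means, lt2_power: float) -> SubmaxRegression:
    """OLS of stage-mean V̇O2 (and V̇CO2) on power over the submaximal
    stages, i.e. every stage whose power does not exceed the LT2 power
    (boundary stage included).

    ``stage_means`` is a sequence of ``(stage_index, power, vo2, vco2)``.
    """
    rows = [(int(i), float(p), float(o), float(c)) for i, p, o, c in stage_means]
    used = [r for r in rows if r[1] <= lt2_power]
    if len(used) < 2:
        raise InsufficientDataError(
            f"only {len(used)} stages at or below LT2 power {lt2_power:.0f} W "
            "(need >= 2)")
    p = np.array([r[1] for r in used])
    vo2 = np.array([r[2] for r in used])
    vco2 = np.array([r[3] for r in used])
    X = np.column_stack([np.ones_like(p), p])
    beta_o, *_ = np.linalg.lstsq(X, vo2, rcond=None)
    beta_c, *_ = np.linalg.lstsq(X, vco2, rcond=None)
    fitted = X @ beta_o
    sst = float(((vo2 - vo2.mean()) ** 2).sum())
    sse = float(((vo2 - fitted) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return SubmaxRegression(
        slope_vo2=float(beta_o[1]), intercept_vo2=float(beta_o[0]),
        slope_vco2=float(beta_c[1]), intercept_vco2=float(beta_c[0]),
        stages_used=tuple(r[0] for r in used), r2=r2,
    )


def metabolic_power(vo2: float, vco2: float) -> float:
    """Metabolic power input (W) from V̇O2 and V̇CO2 in mL·min⁻¹."""
    kcal_min = KCAL_PER_L_VCO2 * vco2 / 1000.0 + KCAL_PER_L_VO2 * vo2 / 1000.0
    return kcal_min * WATT_PER_KCAL_MIN


def ge_at(power: float, vo2: float, vco2: float) -> float:
    """Gross efficiency (%) at a mechanical power with measured/predicted
    V̇O2 and V̇CO2 (mL·min⁻¹)."""
    if power <= 0:
        raise ValueError("power must be positive")
    if vo2 <= 0:
        raise ValueError("vo2 must be positive")
    rer = vco2 / vo2
    if not (0.7 <= rer <= 1.3):
        warnings.warn(f"RER {rer:.2f} outside the 0.7-1.3 physiological range",
                      stacklevel=2)
    return 100.0 * power / metabolic_power(vo2, vco2)


def economy(reg: SubmaxRegression, vo2peak_value: float, lt2_power: float,
            body_mass: float, cfg: Config = DEFAULT_CONFIG) -> EconomyResult:
    """Fractional utilization at LT2 plus Cc and GE at the three target
    intensities, evaluated on the submaximal regression line.

    The three powers are: ``cfg.cc_fix_rel_power * body_mass`` (fixed,
    default 3 W·kg⁻¹); the power where the regression predicts
    ``cfg.cc_frac_vo2 * vo2peak`` (default 75%); and
    ``cfg.cc_frac_lt2 * lt2_power`` (default 90%).  Cc = predicted
    V̇O2 / power; GE from predicted V̇O2 and V̇CO2 via :func:`ge_at`.
    """
    warns: list[str] = []
    frac_util = float(reg.predict_vo2(lt2_power)) / vo2peak_value
    if not (0 < frac_util <= 1):
        warns.append("frac-util-outside-(0,1]")

    p_fix = cfg.cc_fix_rel_power * body_mass
    p_lt2 = cfg.cc_frac_lt2 * lt2_power
    if reg.slope_vo2 <= 0:
        raise ValueError("non-positive submaximal V̇O2 slope")
    p_vo2 = (cfg.cc_frac_vo2 * vo2peak_value - reg.intercept_vo2) / reg.slope_vo2
    if p_vo2 <= 0:
        raise ValueError(
            f"solved power at {100 * cfg.cc_frac_vo2:.0f}% V̇O2peak is "
            f"non-positive ({p_vo2:.1f} W)")
    if p_vo2 > lt2_power:
        warns.append("p-vo2-extrapolated-above-lt2")

    powers = (float(p_fix), float(p_vo2), float(p_lt2))
    ccs = []
    ges = []
    for p in powers:
        vo2 = float(reg.predict_vo2(p))
        vco2 = float(reg.predict_vco2(p))
        ccs.append(vo2 / p)
        ges.append(ge_at(p, vo2, vco2))
    return EconomyResult(
        frac_util=frac_util,
        cc_fix=ccs[0], cc_frac_vo2=ccs[1], cc_frac_lt2=ccs[2],
        ge_fix=ges[0], ge_frac_vo2=ges[1], ge_frac_lt2=ges[2],
        eval_powers=powers, warnings=tuple(warns),
    )


def summarize_gas_exchange(test: StepTest, cfg: Config = DEFAULT_CONFIG) -> GasExchangeSummary:
    """Peak values and exhaustion verification for one step test."""
    peak = vo2peak(test.breaths, cfg.window)
    vo2 = np.asarray(test.breaths["vo2"], float)
    vco2 = np.asarray(test.breaths["vco2"], float)
    w = int(round(cfg.window))
    kern = np.full(w, 1.0 / w)
    # RER on window means, robust against single-breath spikes
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.convolve(vco2, kern, "valid") / np.convolve(vo2, kern, "valid")
    rer_max = float(np.nanmax(rer))
    hr = np.asarray(test.breaths["hr"], float)
    hr_max = float(np.nanmax(hr)) if np.any(~np.isnan(hr)) else None
    bla_max = max(s.bla_end for s in test.stages)
    count, ok = check_exhaustion(rer_max, hr_max, test.athlete.age, bla_max,
                                 test.volitional_exhaustion)
    return GasExchangeSummary(
        vo2peak=peak, vo2peak_rel=peak / test.athlete.body_mass,
        peak_power=test.peak_power, rer_max=rer_max, hr_max=hr_max,
        bla_max=bla_max, exhaustion_criteria_met=count, exhaustion_ok=ok,
    )
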