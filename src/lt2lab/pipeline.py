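"""End-to-end cohort pipeline: thresholds → gas exchange → economy →
model → ċLamax → agreement → association → report.

Per-athlete processing produces one joined record; athletes whose tests
fail a validity rule are excluded from cohort statistics with a
machine-readable reason (mirroring routine performance-diagnostics
bookkeeping): ``invalid-lt2:<code>`` for threshold failures,
``exhaustion-not-verified`` when strict mode is on, ``parse-failure``
for unreadable files.  Sex-stratified analyses are always produced
alongside the pooled ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import bland_altman, icc_a1
from .association import commonality, stepwise_aic
from .gas_exchange import economy, stage_average, submax_regression, summarize_gas_exchange
from .model import model_all
from .simulate import CohortSpec, generate_cohort
from .sprint import clamax as compute_clamax
from .threshold import determine_lt2
from .types import Config, DEFAULT_CONFIG, DataError, SprintTest, StepTest

logger = logging.getLogger("lt2lab")

__all__ = ["CohortResults", "process_athlete", "run_pipeline", "run_simulated"]

MODEL_VARIANTS = ("mod_lt2_fix", "mod_lt2_frac_vo2", "mod_lt2_frac_lt2")

_DESCRIPTIVE_VARS = (
    "age", "height", "body_mass", "peak_power", "vo2peak", "vo2peak_rel",
    "cc_fix", "cc_frac_vo2", "cc_frac_lt2", "ge_fix", "ge_frac_vo2",
    "ge_frac_lt2", "frac_util_pct", "lt2_power", "lt2_bla",
    "mod_lt2_fix", "mod_lt2_frac_vo2", "mod_lt2_frac_lt2", "clamax",
)


@dataclass
class CohortResults:
    """Cohort-level results bundle."""

    records: pd.DataFrame  # one row per athlete, including excluded ones
    descriptives: pd.DataFrame
    agreement_table: pd.DataFrame
    regression_table: pd.DataFrame
    commonality_table: pd.DataFrame
    exclusion_table: pd.DataFrame
    n_included: int
    n_excluded: int


def process_athlete(step: StepTest, sprint: SprintTest | None = None,
                    cfg: Config = DEFAULT_CONFIG,
                    strict_exhaustion: bool = False) -> dict:
    """Process one athlete's tests into a flat record."""
    a = step.athlete
    rec: dict = {
        "id": a.id, "sex": a.sex.value, "age": a.age, "height": a.height,
        "body_mass": a.body_mass, "discipline": a.discipline.value,
        "exclusion_reason": None,
    }
    summary = summarize_gas_exchange(step, cfg)
    rec.update({
        "vo2peak": summary.vo2peak, "vo2peak_rel": summary.vo2peak_rel,
        "peak_power": summary.peak_power, "rer_max": summary.rer_max,
        "hr_max": summary.hr_max, "bla_max": summary.bla_max,
        "exhaustion_criteria_met": summary.exhaustion_criteria_met,
        "exhaustion_ok": summary.exhaustion_ok,
    })

    thr = determine_lt2(step.lactate_points, cfg)
    rec.update({"lt2_power": thr.lt2_power, "lt2_bla": thr.lt2_bla,
                "first_rise_power": thr.first_rise_power,
                "lt2_valid": thr.valid})
    if not thr.valid:
        rec["exclusion_reason"] = "invalid-lt2:" + ",".join(thr.reasons)
        return rec
    if strict_exhaustion and not summary.exhaustion_ok:
        rec["exclusion_reason"] = "exhaustion-not-verified"
        return rec

    means = [(s.index, s.power, *stage_average(step.breaths, s, cfg.stage_avg))
             for s in step.stages]
    reg = submax_regression(means, thr.lt2_power)
    econ = economy(reg, summary.vo2peak, thr.lt2_power, a.body_mass, cfg)
    est = model_all(econ, summary.vo2peak)
    rec.update({
        "cc_slope": reg.slope_vo2, "vo2_intercept": reg.intercept_vo2,
        "frac_util": econ.frac_util, "frac_util_pct": 100.0 * econ.frac_util,
        "cc_fix": econ.cc_fix, "cc_frac_vo2": econ.cc_frac_vo2,
        "cc_frac_lt2": econ.cc_frac_lt2,
        "ge_fix": econ.ge_fix, "ge_frac_vo2": econ.ge_frac_vo2,
        "ge_frac_lt2": econ.ge_frac_lt2,
        "mod_lt2_fix": est.mod_lt2_fix,
        "mod_lt2_frac_vo2": est.mod_lt2_frac_vo2,
        "mod_lt2_frac_lt2": est.mod_lt2_frac_lt2,
    })
    if sprint is not None:
        rec["clamax"] = compute_clamax(sprint, cfg).clamax
    return rec


def _strata(df: pd.DataFrame):
    yield "all", df
    for sex in ("male", "female"):
        yield sex, df[df["sex"] == sex]


def _descriptives(inc: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for stratum, sub in _strata(inc):
        for var in _DESCRIPTIVE_VARS:
            if var not in sub.columns:
                continue
            vals = sub[var].dropna().to_numpy(float)
            rows.append({
                "stratum": stratum, "variable": var, "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def _agreement(inc: pd.DataFrame, cfg: Config) -> pd.DataFrame:
    rows = []
    for stratum, sub in _strata(inc):
        crit = sub["lt2_power"].to_numpy(float)
        for variant in MODEL_VARIANTS:
            mod = sub[variant].to_numpy(float)
            row = {"stratum": stratum, "variant": variant, "n": len(sub)}
            if len(sub) >= 3:
                ba = bland_altman(mod, crit, cfg)
                icc = icc_a1(mod, crit, cfg.alpha)
                row.update({
                    "mean_diff_pct": ba.mean_diff_pct,
                    "loa_half_width_pct": cfg.loa_multiplier * ba.sd_diff_pct,
                    "mean_diff_w": ba.mean_diff, "sd_diff_w": ba.sd_diff,
                    "fixed_bias_p": ba.fixed_bias_p,
                    "prop_slope": ba.prop_slope, "prop_slope_p": ba.prop_slope_p,
                    "icc": icc.icc, "icc_ci_low": icc.ci_low,
                    "icc_ci_high": icc.ci_high,
                    "icc_interpretation": icc.interpretation,
                })
            rows.append(row)
    return pd.DataFrame(rows)


_PREDICTORS = {"vo2peak": "vo2peak", "cc_frac_lt2": "cc_frac_lt2",
               "frac_util_pct": "frac_util_pct"}


def _association(inc: pd.DataFrame, with_clamax: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    reg_rows, com_rows = [], []
    for stratum, sub in _strata(inc):
        names = dict(_PREDICTORS)
        if with_clamax and sub["clamax"].notna().all():
            names["clamax"] = "clamax"
        if len(sub) <= len(names) + 2:
            continue
        y = sub["lt2_power"].to_numpy(float)
        X = sub[list(names)].astype(float)
        res = stepwise_aic(y, X)
        for t in res.terms:
            reg_rows.append({
                "stratum": stratum, "term": t.name, "beta": t.beta,
                "se": t.se, "std_beta": t.std_beta, "t": t.t, "p": t.p,
                "r2": res.r2, "adj_r2": res.adj_r2, "f": res.f,
                "model_p": res.p, "aic": res.aic, "n": len(sub),
            })
        com = commonality(y, sub["vo2peak"], sub["cc_frac_lt2"],
                          sub["frac_util_pct"],
                          names=("vo2peak", "cc_frac_lt2", "frac_util_pct"))
        for comp, val in com.components.items():
            com_rows.append({
                "stratum": stratum, "component": "+".join(comp),
                "coefficient": val,
                "percent_of_total": com.percent_of_total[comp],
                "total_r2": com.total_r2, "n": len(sub),
            })
    return pd.DataFrame(reg_rows), pd.DataFrame(com_rows)


def run_pipeline(athletes: list[tuple[StepTest, SprintTest | None]],
                 cfg: Config = DEFAULT_CONFIG,
                 strict_exhaustion: bool = False,
                 with_clamax: bool = False) -> CohortResults:
    """Run the full analysis on prepared tests.

    ``athletes`` pairs each step test with an optional sprint test.
    Cohort statistics use included (valid) rows only; exclusion counts
    are logged and returned.
    """
    if not athletes:
        raise DataError("no athletes")
    records = []
    for step, sprint in athletes:
        try:
            records.append(process_athlete(step, sprint, cfg, strict_exhaustion))
        except Exception as e:  # noqa: BLE001 - record and exclude
            records.append({"id": step.athlete.id, "sex": step.athlete.sex.value,
                            "exclusion_reason": f"parse-failure:{e}"})
    df = pd.DataFrame(records)
    if "clamax" not in df.columns:
        df["clamax"] = np.nan
    inc = df[df["exclusion_reason"].isna()].reset_index(drop=True)
    exc = df[df["exclusion_reason"].notna()]
    tally = exc["exclusion_reason"].value_counts()
    exclusion_table = tally.rename_axis("reason").reset_index(name="count")
    if len(inc) == 0:
        raise DataError(
            "all athletes excluded: "
            + "; ".join(f"{r}={c}" for r, c in tally.items()))
    logger.info("included %d of %d athletes (%d excluded)",
                len(inc), len(df), len(exc))

    reg_table, com_table = _association(inc, with_clamax)
    return CohortResults(
        records=df,
        descriptives=_descriptives(inc),
        agreement_table=_agreement(inc, cfg),
        regression_table=reg_table,
        commonality_table=com_table,
        exclusion_table=exclusion_table,
        n_included=len(inc),
        n_excluded=len(exc),
    )


def run_simulated(spec: CohortSpec, cfg: Config = DEFAULT_CONFIG,
                  strict_exhaustion: bool = False,
                  with_clamax: bool = False) -> CohortResults:
    """Generate a synthetic cohort and run the pipeline on it.

    The ground-truth columns are merged into ``records`` (prefix
    ``true_``) for recovery diagnostics.
    """
    cohort = generate_cohort(spec)
    pairs = [(step, sprint) for _, step, sprint, _ in cohort]
    results = run_pipeline(pairs, cfg, strict_exhaustion, with_clamax)
    truth = pd.DataFrame([
        {"id": ath.id, "true_cc": gt.cc_true, "true_vo2peak": gt.vo2peak_true,
         "true_lt2_power": gt.lt2_power_noiseless,
         "true_clamax": gt.clamax_true, "true_frac_util": gt.frac_util_op}
        for ath, _, _, gt in cohort
    ])
    results.records = results.records.merge(truth, on="id", how="left")
    return results
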