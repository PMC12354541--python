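"""Synthetic cohort generator with known ground truth.

Generates athletes, incremental step tests and sprint tests whose
statistical structure mirrors the young cyclist/triathlete cohort the
analysis targets: sex-specific body mass and relative V̇O2peak, an
oxygen cost of cycling around 13.3 mL·min⁻¹·W⁻¹, fractional utilization
near 0.83, and a maximal lactate accumulation rate of 0.48 ± 0.10
mmol·L⁻¹·s⁻¹.

Generative model per athlete
----------------------------
* Steady-state V̇O2 at power P is ``intercept + cc_true·P`` (capped at
  V̇O2peak); the per-second trace approaches each stage's steady state
  mono-exponentially (time constant 30 s) with multiplicative Gaussian
  noise.  V̇CO2 is RER(P)·V̇O2 with RER rising linearly from 0.85 at the
  first stage to 1.12 at peak.
* The protocol starts near 1.5 W·kg⁻¹ (rounded to the 20-W grid, kept
  within the 40-120 W protocol window) and adds 20 W per 3-min stage up
  to the first stage whose steady-state demand exceeds V̇O2peak.
* The blood-lactate curve is exponential, ``bLa(P) = b0 + b1·e^{b2·P}``
  with b0 = 1.0 — deliberately *not* the cubic family the threshold
  fitter uses, so parameter-recovery tests are not circular.  Its two
  free constants are pinned by the peak-stage lactate (drawn from
  8-12 mmol·L⁻¹) and by a first-stage excess of 0.3 mmol·L⁻¹ over
  baseline.  The geometry of a convex exponential under a cubic fit
  places the modified maximal-deviation point at roughly 60-63% of the
  stage span, so the drawn fractional utilization serves feasibility
  checking, while the operationally realized utilization (recorded in
  the ground truth) emerges from the curve geometry and clusters
  somewhat below the drawn value.
* End-of-stage lactate adds Gaussian noise (SD 0.2 mmol·L⁻¹, truncated
  at 0).  The sprint recovery series rises to ``la_rest +
  clamax_true·(duration − t_alac)`` at minute 5 and decays 5% per
  minute, with the same lactate noise.

Ground truth is operational: ``lt2_power_noiseless`` is what the
threshold method itself returns on the noise-free dense curve, because
that functional — not an analytic inflection — is the estimand of the
method under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .threshold import determine_lt2
from .types import Athlete, Config, Discipline, Sex, SprintTest, Stage, StepTest

__all__ = [
    "SexParams",
    "CohortSpec",
    "GroundTruth",
    "GenerationError",
    "generate_athlete",
    "generate_cohort",
    "write_cohort",
]

STAGE_DURATION_S = 180.0
STAGE_INCREMENT_W = 20.0
VO2_TIME_CONSTANT_S = 30.0
RER_FIRST_STAGE = 0.85
RER_PEAK = 1.12
LACTATE_BASELINE = 1.0  # b0, mmol·L⁻¹
SPRINT_DURATION_S = 15.0
SPRINT_PEAK_MINUTE = 5
SPRINT_DECAY_PER_MIN = 0.95
FIRST_STAGE_LA_EXCESS = 0.3  # mmol·L⁻¹ above baseline at the first stage


class GenerationError(RuntimeError):
    """The cohort spec cannot produce a physiologically consistent athlete."""


@dataclass(frozen=True)
class SexParams:
    """Per-sex population parameters (means and SDs of the draws)."""

    vo2peak_rel_mean: float  # mL·kg⁻¹·min⁻¹
    vo2peak_rel_sd: float
    mass_mean: float  # kg
    mass_sd: float
    height_mean: float  # cm
    height_sd: float
    cc_mean: float  # mL·min⁻¹·W⁻¹
    cc_sd: float
    frac_util_mean: float  # fraction
    frac_util_sd: float
    clamax_mean: float  # mmol·L⁻¹·s⁻¹
    clamax_sd: float


MALE_DEFAULTS = SexParams(
    vo2peak_rel_mean=61.3, vo2peak_rel_sd=5.6,
    mass_mean=60.1, mass_sd=10.2,
    height_mean=173.0, height_sd=9.0,
    cc_mean=13.3, cc_sd=0.9,
    frac_util_mean=0.832, frac_util_sd=0.040,
    clamax_mean=0.48, clamax_sd=0.10,
)

FEMALE_DEFAULTS = SexParams(
    vo2peak_rel_mean=53.4, vo2peak_rel_sd=5.1,
    mass_mean=56.2, mass_sd=6.1,
    height_mean=166.0, height_sd=5.0,
    cc_mean=13.3, cc_sd=1.0,
    frac_util_mean=0.807, frac_util_sd=0.040,
    clamax_mean=0.48, clamax_sd=0.10,
)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, composition, population parameters and noise levels."""

    n: int = 83
    p_male: float = 61.0 / 83.0
    male: SexParams = MALE_DEFAULTS
    female: SexParams = FEMALE_DEFAULTS
    bla_sd: float = 0.2  # mmol·L⁻¹
    vo2_cv: float = 0.03  # multiplicative
    p_triathlete: float = 36.0 / 83.0
    t_alac: float = 3.5  # s, used to build the sprint recovery series
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GenerationError("cohort size must be >= 1")
        if not (0 < self.p_male < 1):
            raise GenerationError("p_male must lie in (0, 1)")
        if self.bla_sd < 0 or self.vo2_cv < 0:
            raise GenerationError("noise SDs must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-known quantities for parameter-recovery tests."""

    cc_true: float  # mL·min⁻¹·W⁻¹
    vo2_intercept_true: float  # mL·min⁻¹
    vo2peak_true: float  # mL·min⁻¹
    lt2_power_noiseless: float  # W, operational mDmax on the noise-free curve
    clamax_true: float  # mmol·L⁻¹·s⁻¹
    frac_util_target: float  # drawn fractional utilization
    frac_util_op: float  # utilization realized at lt2_power_noiseless
    lactate_coeffs: tuple[float, float, float]  # (b0, b1, b2)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _lactate_curve(b0, b1, b2):
    def f(p):
        return b0 + b1 * np.exp(b2 * np.asarray(p, float))
    return f


def _solve_curve(p1: float, pp: float, la_peak: float, delta: float,
                 b0: float = LACTATE_BASELINE):
    """(b1, b2) so that bLa(p1) = b0 + delta and bLa(pp) = la_peak."""
    b2 = np.log((la_peak - b0) / delta) / (pp - p1)
    b1 = delta * np.exp(-b2 * p1)
    return b1, b2


def _dense_lt2(p1: float, pp: float, la_peak: float,
               delta: float = FIRST_STAGE_LA_EXCESS) -> float:
    """Operational LT2 of the noise-free curve sampled every 1 W."""
    b1, b2 = _solve_curve(p1, pp, la_peak, delta)
    f = _lactate_curve(LACTATE_BASELINE, b1, b2)
    grid = np.arange(p1, pp + 0.5, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = determine_lt2(list(zip(grid, f(grid))))
    if not res.valid or not (p1 < res.lt2_power < pp):
        raise GenerationError("noise-free curve has no valid interior threshold")
    return float(res.lt2_power)


def _draw_common(rng, params: SexParams) -> dict:
    return {
        "mass": float(np.clip(rng.normal(params.mass_mean, params.mass_sd), 35.0, 110.0)),
        "height": float(rng.normal(params.height_mean, params.height_sd)),
        "age": float(np.clip(13.0 + rng.gamma(2.0, 1.5), 12.0, 21.0)),
        "vo2peak_rel": float(np.clip(
            rng.normal(params.vo2peak_rel_mean, params.vo2peak_rel_sd), 35.0, 85.0)),
        "cc_true": float(np.clip(rng.normal(params.cc_mean, params.cc_sd), 10.5, 17.0)),
        "frac_util": float(np.clip(
            rng.normal(params.frac_util_mean, params.frac_util_sd), 0.60, 0.97)),
        "clamax_true": float(np.clip(
            rng.normal(params.clamax_mean, params.clamax_sd), 0.15, 1.20)),
    }


def generate_athlete(spec: CohortSpec, index: int
                     ) -> tuple[Athlete, StepTest, SprintTest, GroundTruth]:
    """Generate one athlete with step test, sprint test and ground truth.

    Fully reproducible: the per-athlete stream is seeded from
    ``(spec.seed, index)``, so regenerating any index gives byte-identical
    output regardless of cohort size or order.
    """
    if not 0 <= index < spec.n:
        raise GenerationError(f"index {index} outside cohort of {spec.n}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, index]))

    # a drawn physiology can be infeasible (too few stages, threshold
    # outside the stage range); redraw deterministically, bounded
    for _attempt in range(25):
        try:
            sex = Sex.male if rng.random() < spec.p_male else Sex.female
            params = spec.male if sex is Sex.male else spec.female
            d = _draw_common(rng, params)
            discipline = (Discipline.triathlete if rng.random() < spec.p_triathlete
                          else Discipline.cyclist)

            vo2peak_true = d["vo2peak_rel"] * d["mass"]
            intercept = float(np.clip(rng.normal(5.0 * d["mass"], 50.0), 100.0, None))
            cc = d["cc_true"]

            # stage schedule: ~1.5 W/kg start on the 20-W grid within the
            # 40-120 W protocol window, +20 W per stage up to the first
            # stage whose steady-state demand exceeds V̇O2peak
            start = float(np.clip(
                STAGE_INCREMENT_W * _round_half_up(1.5 * d["mass"] / STAGE_INCREMENT_W),
                40.0, 120.0))
            powers = [start]
            while intercept + cc * powers[-1] <= vo2peak_true:
                powers.append(powers[-1] + STAGE_INCREMENT_W)
            if len(powers) < 5:
                raise GenerationError(
                    f"athlete {index}: only {len(powers)} stages")
            p1, pp = powers[0], powers[-1]

            if d["frac_util"] >= 1.0:
                raise GenerationError(f"athlete {index}: frac_util >= 1")
            p_target = (d["frac_util"] * vo2peak_true - intercept) / cc
            if not (p1 < p_target < pp):
                raise GenerationError(
                    f"athlete {index}: target LT2 {p_target:.0f} W outside "
                    "stage range")

            la_peak = float(rng.uniform(8.0, 12.0))
            lt2_noiseless = _dense_lt2(p1, pp, la_peak)
            break
        except GenerationError:
            continue
    else:
        raise GenerationError(
            f"athlete {index}: no feasible draw in 25 attempts — spec infeasible")
    b1, b2 = _solve_curve(p1, pp, la_peak, FIRST_STAGE_LA_EXCESS)
    la_curve = _lactate_curve(LACTATE_BASELINE, b1, b2)

    stages = []
    for i, p in enumerate(powers):
        bla = max(float(la_curve(p)) + float(rng.normal(0.0, spec.bla_sd)), 0.0)
        stages.append(Stage(index=i, power=p, start_t=i * STAGE_DURATION_S,
                            end_t=(i + 1) * STAGE_DURATION_S, bla_end=bla))

    # per-second gas exchange; the first stage is entered from a warm-up
    # that leaves the athlete one standard increment below its demand, so
    # every on-transition has the same amplitude
    n_sec = int(len(powers) * STAGE_DURATION_S)
    t = np.arange(1.0, n_sec + 1.0)
    vo2_clean = np.empty(n_sec)
    v_prev = intercept + cc * (p1 - STAGE_INCREMENT_W)
    for i, p in enumerate(powers):
        ss = min(intercept + cc * p, vo2peak_true)
        sl = slice(int(i * STAGE_DURATION_S), int((i + 1) * STAGE_DURATION_S))
        tt = t[sl] - i * STAGE_DURATION_S
        vo2_clean[sl] = ss + (v_prev - ss) * np.exp(-tt / VO2_TIME_CONSTANT_S)
        v_prev = vo2_clean[sl][-1]
    vo2 = np.clip(vo2_clean * (1.0 + rng.normal(0.0, spec.vo2_cv, n_sec)), 0.0, None)
    rer_per_stage = RER_FIRST_STAGE + (RER_PEAK - RER_FIRST_STAGE) * (
        (np.asarray(powers) - p1) / (pp - p1))
    rer_sec = np.repeat(rer_per_stage, int(STAGE_DURATION_S))
    vco2 = rer_sec * vo2

    hr_max = float((220.0 - d["age"]) * rng.uniform(0.95, 1.005))
    hr = 65.0 + (hr_max - 65.0) * np.clip(vo2_clean / vo2peak_true, 0.0, 1.0)

    athlete = Athlete(id=f"ath{index:03d}", sex=sex, age=d["age"],
                      height=d["height"], body_mass=d["mass"],
                      discipline=discipline)
    breaths = pd.DataFrame({"t": t, "vo2": vo2, "vco2": vco2, "hr": hr})
    step = StepTest(athlete=athlete, stages=stages, breaths=breaths,
                    volitional_exhaustion=True)

    # sprint: recovery lactate peaks at minute 5, 5%/min decay of the excess
    la_rest = max(float(rng.normal(1.0, 0.2)), 0.4)
    excess = d["clamax_true"] * (SPRINT_DURATION_S - spec.t_alac)
    post = []
    for minute in range(2, 10):
        if minute <= SPRINT_PEAK_MINUTE:
            val = la_rest + excess * (minute - 1) / (SPRINT_PEAK_MINUTE - 1)
        else:
            val = la_rest + excess * SPRINT_DECAY_PER_MIN ** (minute - SPRINT_PEAK_MINUTE)
        val = max(val + float(rng.normal(0.0, spec.bla_sd)), 0.0)
        post.append((minute, val))
    sprint = SprintTest(athlete_id=athlete.id, duration=SPRINT_DURATION_S,
                        la_rest=la_rest, la_post=tuple(post))

    truth = GroundTruth(
        cc_true=cc, vo2_intercept_true=intercept, vo2peak_true=vo2peak_true,
        lt2_power_noiseless=lt2_noiseless, clamax_true=d["clamax_true"],
        frac_util_target=d["frac_util"],
        frac_util_op=(intercept + cc * lt2_noiseless) / vo2peak_true,
        lactate_coeffs=(LACTATE_BASELINE, b1, b2),
    )
    return athlete, step, sprint, truth


def generate_cohort(spec: CohortSpec
                    ) -> list[tuple[Athlete, StepTest, SprintTest, GroundTruth]]:
    """Generate the full cohort; errors carry the failing index."""
    out = []
    for i in range(spec.n):
        try:
            out.append(generate_athlete(spec, i))
        except GenerationError:
            raise
        except Exception as e:  # noqa: BLE001 - annotate the index
            raise GenerationError(f"athlete {i}: {e}") from e
    return out


def write_cohort(spec: CohortSpec, out_dir) -> dict[str, Path]:
    """Generate and write the cohort as CSV fixtures plus ground_truth.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    paths: dict[str, Path] = {}
    gt_rows = []
    sprints = []
    for athlete, step, sprint, truth in cohort:
        paths.update({f"{athlete.id}_{k}": v
                      for k, v in lio.write_step_test(step, out_dir).items()})
        sprints.append(sprint)
        gt_rows.append({
            "id": athlete.id, "cc_true": truth.cc_true,
            "vo2_intercept_true": truth.vo2_intercept_true,
            "vo2peak_true": truth.vo2peak_true,
            "lt2_power_noiseless": truth.lt2_power_noiseless,
            "clamax_true": truth.clamax_true,
            "frac_util_op": truth.frac_util_op,
        })
    paths["sprints"] = lio.write_sprint_tests(sprints, out_dir / "sprints.csv")
    gt_path = out_dir / "ground_truth.csv"
    pd.DataFrame(gt_rows).to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path
    return paths
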