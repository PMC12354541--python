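"""Delimited-text readers/writers for step tests, sprint tests and reports.

All files are plain CSV.  Canonical units are enforced here: V̇O2/V̇CO2 in
mL·min⁻¹ (readers convert columns declared ``*_l_min`` to mL·min⁻¹),
power in W, lactate in mmol·L⁻¹, time in s.  Downstream modules consume
only the in-memory types — nothing re-parses files.

File layouts
------------
breath CSV   : ``t_s, vo2_ml_min, vco2_ml_min, hr_bpm`` (hr optional), one
               row per second.
lactate CSV  : ``stage, power_w, start_s, end_s, bla_mmol_l``.
athlete CSV  : ``id, sex, age_y, height_cm, mass_kg, discipline,
               volitional_exhaustion``.
sprint CSV   : ``id, duration_s, la_rest_mmol_l, minute, bla_mmol_l``
               (long form, one row per post-exercise sample).
config file  : flat ``key = value`` lines mirroring :class:`Config`.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Athlete,
    Config,
    DataError,
    Discipline,
    FormatError,
    Sex,
    SprintTest,
    Stage,
    StepTest,
)

__all__ = [
    "read_step_test",
    "write_step_test",
    "read_sprint_tests",
    "write_sprint_tests",
    "read_config",
    "write_report",
]

_BREATH_COLS = ("t_s", "vo2_ml_min", "vco2_ml_min")
_LACTATE_COLS = ("stage", "power_w", "start_s", "end_s", "bla_mmol_l")
_ATHLETE_COLS = ("id", "sex", "age_y", "height_cm", "mass_kg", "discipline",
                 "volitional_exhaustion")
_SPRINT_COLS = ("id", "duration_s", "la_rest_mmol_l", "minute", "bla_mmol_l")


def _require(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c not in df.columns:
            raise FormatError(f"{path}: missing column '{c}'")


def _read_breaths(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    # accept L·min⁻¹ exports when the header declares them
    for raw, canon in (("vo2_l_min", "vo2_ml_min"), ("vco2_l_min", "vco2_ml_min")):
        if raw in df.columns and canon not in df.columns:
            df[canon] = df[raw] * 1000.0
    _require(df, _BREATH_COLS, path)
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: breath timestamps must be strictly increasing")
    out = pd.DataFrame(
        {"t": t, "vo2": df["vo2_ml_min"].to_numpy(float),
         "vco2": df["vco2_ml_min"].to_numpy(float)}
    )
    if "hr_bpm" in df.columns:
        out["hr"] = df["hr_bpm"].to_numpy(float)
    return out


def _read_athlete(path, athlete_id: str | None = None) -> tuple[Athlete, bool]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _ATHLETE_COLS, path)
    if athlete_id is not None:
        df = df[df["id"].astype(str) == str(athlete_id)]
        if df.empty:
            raise DataError(f"{path}: no athlete with id '{athlete_id}'")
    row = df.iloc[0]
    athlete = Athlete(
        id=str(row["id"]),
        sex=Sex(str(row["sex"])),
        age=float(row["age_y"]),
        height=float(row["height_cm"]),
        body_mass=float(row["mass_kg"]),
        discipline=Discipline(str(row["discipline"])),
    )
    return athlete, bool(row["volitional_exhaustion"])


def read_step_test(breath_path, lactate_path, athlete_path,
                   athlete_id: str | None = None) -> StepTest:
    """Assemble a validated :class:`StepTest` from the three CSV files."""
    breaths = _read_breaths(breath_path)
    lac = pd.read_csv(lactate_path, float_precision="round_trip")
    _require(lac, _LACTATE_COLS, lactate_path)
    lac = lac.sort_values("stage")
    stages = [
        Stage(index=int(r["stage"]), power=float(r["power_w"]),
              start_t=float(r["start_s"]), end_t=float(r["end_s"]),
              bla_end=float(r["bla_mmol_l"]))
        for _, r in lac.iterrows()
    ]
    athlete, volitional = _read_athlete(athlete_path, athlete_id)
    return StepTest(athlete=athlete, stages=stages, breaths=breaths,
                    volitional_exhaustion=volitional)


def write_step_test(test: StepTest, out_dir, prefix: str | None = None) -> dict[str, Path]:
    """Write the breath/lactate/athlete CSVs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix if prefix is not None else test.athlete.id
    paths = {
        "breath": out_dir / f"{prefix}_breath.csv",
        "lactate": out_dir / f"{prefix}_lactate.csv",
        "athlete": out_dir / f"{prefix}_athlete.csv",
    }
    b = test.breaths
    bdf = pd.DataFrame({"t_s": b["t"], "vo2_ml_min": b["vo2"],
                        "vco2_ml_min": b["vco2"], "hr_bpm": b["hr"]})
    bdf.to_csv(paths["breath"], index=False, float_format="%.17g")
    pd.DataFrame(
        [{"stage": s.index, "power_w": s.power, "start_s": s.start_t,
          "end_s": s.end_t, "bla_mmol_l": s.bla_end} for s in test.stages]
    ).to_csv(paths["lactate"], index=False, float_format="%.17g")
    a = test.athlete
    pd.DataFrame(
        [{"id": a.id, "sex": a.sex.value, "age_y": a.age, "height_cm": a.height,
          "mass_kg": a.body_mass, "discipline": a.discipline.value,
          "volitional_exhaustion": test.volitional_exhaustion}]
    ).to_csv(paths["athlete"], index=False, float_format="%.17g")
    return paths


def read_sprint_tests(path) -> list[SprintTest]:
    """Read the long-form sprint CSV into one :class:`SprintTest` per id."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _SPRINT_COLS, path)
    tests = []
    for aid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("minute")
        dur = grp["duration_s"].iloc[0]
        rest = grp["la_rest_mmol_l"].iloc[0]
        tests.append(SprintTest(
            athlete_id=str(aid), duration=float(dur), la_rest=float(rest),
            la_post=tuple((int(m), float(v))
                          for m, v in zip(grp["minute"], grp["bla_mmol_l"])),
        ))
    return tests


def write_sprint_tests(tests, path) -> Path:
    rows = []
    for t in tests:
        for minute, bla in t.la_post:
            rows.append({"id": t.athlete_id, "duration_s": t.duration,
                         "la_rest_mmol_l": t.la_rest, "minute": minute,
                         "bla_mmol_l": bla})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_config(path=None, **overrides) -> Config:
    """Build a :class:`Config` from an optional ``key = value`` file plus
    keyword overrides (CLI flags win over file values)."""
    values: dict[str, object] = {}
    if path is not None:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: expected 'key = value', got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name: f.type for f in dataclasses.fields(Config)}
    kwargs = {}
    for key, val in values.items():
        if key not in fields:
            raise FormatError(f"unknown config key '{key}'")
        kwargs[key] = int(val) if key == "rng_seed" else float(val)
    return Config(**kwargs)


def write_report(results, out_dir) -> dict[str, Path]:
    """Write the cohort-level result tables as CSV files.

    ``results`` is the bundle produced by :func:`lt2lab.pipeline.run_pipeline`:
    descriptive statistics per sex stratum, the agreement table (one row
    per model variant and stratum), the stepwise-regression table, and
    the commonality summary.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise OSError(f"cannot write to {out_dir}: {e}") from e

    if getattr(results, "n_included", 0) == 0:
        raise DataError("no athletes")

    paths = {}
    for name, df in (
        ("descriptives", results.descriptives),
        ("agreement", results.agreement_table),
        ("regression", results.regression_table),
        ("commonality", results.commonality_table),
        ("records", results.records),
        ("exclusions", results.exclusion_table),
    ):
        if df is None:
            continue
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
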