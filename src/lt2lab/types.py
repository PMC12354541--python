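"""Shared data model for incremental step tests and sprint tests.

Canonical units are fixed at ingest and used everywhere downstream:
oxygen uptake and CO2 output in mL·min⁻¹, mechanical power in W, blood
lactate in mmol·L⁻¹, time in s.  Readers convert L·min⁻¹ inputs when the
file header declares them; no module re-parses files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "Discipline",
    "Athlete",
    "Stage",
    "StepTest",
    "SprintTest",
    "Config",
    "DataError",
    "FormatError",
    "InsufficientDataError",
]


class DataError(ValueError):
    """Input data violates an invariant (non-monotone time, count mismatch...)."""


class FormatError(ValueError):
    """A file does not match the expected column layout."""


class InsufficientDataError(DataError):
    """Too few samples/points for the requested computation."""


class Sex(str, Enum):
    male = "male"
    female = "female"


class Discipline(str, Enum):
    cyclist = "cyclist"
    triathlete = "triathlete"


@dataclass(frozen=True)
class Athlete:
    """Anthropometrics of one participant."""

    id: str
    sex: Sex
    age: float  # years
    height: float  # cm
    body_mass: float  # kg
    discipline: Discipline

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise DataError(f"athlete {self.id}: body_mass must be > 0")
        if self.height <= 0:
            raise DataError(f"athlete {self.id}: height must be > 0")
        if not (10 <= self.age <= 30):
            warnings.warn(
                f"athlete {self.id}: age {self.age:.1f} y outside the 10-30 y "
                "study context",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Stage:
    """One constant-power step of the incremental test.

    ``bla_end`` is the capillary blood lactate drawn in the last 30 s of
    the step.
    """

    index: int
    power: float  # W
    start_t: float  # s
    end_t: float  # s
    bla_end: float  # mmol·L⁻¹

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise DataError(f"stage {self.index}: end_t must exceed start_t")
        if self.bla_end < 0:
            raise DataError(f"stage {self.index}: negative lactate")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class StepTest:
    """A complete incremental step test.

    ``breaths`` is a per-second DataFrame with columns ``t`` (s), ``vo2``
    (mL·min⁻¹), ``vco2`` (mL·min⁻¹) and optionally ``hr`` (beats·min⁻¹,
    may hold NaN).  Heart rate is not required by any formula; a missing
    column only removes one exhaustion criterion.
    """

    athlete: Athlete
    stages: list[Stage]
    breaths: pd.DataFrame
    volitional_exhaustion: bool = True

    def __post_init__(self) -> None:
        powers = [s.power for s in self.stages]
        if any(b <= a for a, b in zip(powers, powers[1:])):
            raise DataError("stage powers must be strictly increasing")
        t = np.asarray(self.breaths["t"], dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or np.any(t < 0)):
            raise DataError("breath timestamps must be non-negative and strictly increasing")
        if np.any(np.asarray(self.breaths[["vo2", "vco2"]], dtype=float) < 0):
            raise DataError("vo2/vco2 must be non-negative")
        if "hr" not in self.breaths.columns:
            self.breaths = self.breaths.assign(hr=np.nan)

    @property
    def lactate_points(self) -> list[tuple[float, float]]:
        """(power, bLa) pairs, one per stage, in stage order."""
        return [(s.power, s.bla_end) for s in self.stages]

    @property
    def peak_power(self) -> float:
        return self.stages[-1].power


@dataclass(frozen=True)
class SprintTest:
    """A 15-s all-out sprint with pre/post capillary lactate sampling.

    ``la_post`` maps minute-after-exercise (typically 2..9) to bLa.
    """

    athlete_id: str
    duration: float  # s, full programmed sprint duration
    la_rest: float  # mmol·L⁻¹
    la_post: tuple[tuple[int, float], ...]  # ((minute, bla), ...)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DataError(f"sprint {self.athlete_id}: duration must be > 0")
        minutes = [m for m, _ in self.la_post]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise DataError(f"sprint {self.athlete_id}: minutes must be strictly increasing")
        if self.la_rest < 0 or any(v < 0 for _, v in self.la_post):
            raise DataError(f"sprint {self.athlete_id}: negative lactate")


@dataclass(frozen=True)
class Config:
    """Tunable analysis constants.

    Defaults follow the study protocol: first-rise slope criterion
    0.01 mmol·L⁻¹·W⁻¹ on the lactate-power cubic, 30-s moving average for
    V̇O2peak, last 60 s of each stage averaged for the submaximal
    regression, oxygen-cost evaluation at 3 W·kg⁻¹ / 75% V̇O2peak /
    90% LT2 power, and an alactic interval of 3.5 s in the ċLamax
    computation.
    """

    first_rise_slope: float = 0.01  # mmol·L⁻¹·W⁻¹
    window: float = 30.0  # s, V̇O2peak moving average
    stage_avg: float = 60.0  # s, tail of each stage to average
    cc_fix_rel_power: float = 3.0  # W·kg⁻¹
    cc_frac_vo2: float = 0.75  # fraction of V̇O2peak
    cc_frac_lt2: float = 0.90  # fraction of LT2 power
    t_alac: float = 3.5  # s
    loa_multiplier: float = 1.96
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "first_rise_slope",
            "window",
            "stage_avg",
            "cc_fix_rel_power",
            "t_alac",
            "loa_multiplier",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"Config.{name} must be positive")
        for name in ("cc_frac_vo2", "cc_frac_lt2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"Config.{name} must lie in (0, 1]")


DEFAULT_CONFIG = Config()
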