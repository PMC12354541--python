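"""Maximal lactate accumulation rate (ċLamax) from a 15-s all-out sprint.

ċLamax relates the net rise in capillary blood lactate — the highest
post-exercise value (minutes 2-9 of passive rest) minus the pre-sprint
resting value — to the effective glycolytic working time, i.e. the full
programmed sprint duration minus a theoretical alactic interval of 3.5 s
during which phosphagen stores dominate:

    ċLamax = (La_peak - La_rest) / (t_exerc - t_alac)   [mmol·L⁻¹·s⁻¹]

The peak is taken directly as the maximum of the provided samples; no
curve is fitted to the recovery series.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import Config, DEFAULT_CONFIG, DataError, SprintTest

__all__ = ["SprintResult", "clamax"]

NO_ACCUMULATION = "no-accumulation"


@dataclass(frozen=True)
class SprintResult:
    la_peak: float  # mmol·L⁻¹
    la_rest: float  # mmol·L⁻¹
    t_exerc: float  # s
    t_alac: float  # s
    clamax: float  # mmol·L⁻¹·s⁻¹
    peak_minute: int
    warnings: tuple[str, ...] = ()


def clamax(test: SprintTest, cfg: Config = DEFAULT_CONFIG) -> SprintResult:
    """Compute ċLamax for one sprint test.

    A post-exercise series that never exceeds the resting value yields
    ċLamax = 0 with a ``no-accumulation`` warning rather than a negative
    rate.
    """
    if not test.la_post:
        raise DataError(f"sprint {test.athlete_id}: no post-exercise samples")
    if test.duration <= cfg.t_alac:
        raise DataError(
            f"sprint {test.athlete_id}: duration {test.duration:.1f} s must "
            f"exceed the alactic interval {cfg.t_alac:.1f} s")
    peak_minute, la_peak = max(test.la_post, key=lambda mv: (mv[1], -mv[0]))
    warns: tuple[str, ...] = ()
    if la_peak < test.la_rest:
        rate = 0.0
        warns = (NO_ACCUMULATION,)
    else:
        rate = (la_peak - test.la_rest) / (test.duration - cfg.t_alac)
    return SprintResult(
        la_peak=float(la_peak), la_rest=test.la_rest, t_exerc=test.duration,
        t_alac=cfg.t_alac, clamax=float(rate), peak_minute=int(peak_minute),
        warnings=warns,
    )
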