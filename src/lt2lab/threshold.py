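"""Second lactate threshold (LT2) via the modified maximal-deviation method.

The per-stage blood-lactate values are plotted against power and fitted
with a third-order polynomial.  LT2 is the point of the cubic with the
maximal perpendicular distance to the chord drawn from the point of the
first rise in bLa (cubic slope reaching 0.01 mmol·L⁻¹·W⁻¹) to the last
measured data point (highest power and bLa).  The construction anchors
the chord at a curve-derived LT1 proxy rather than the first stage, which
is what distinguishes the *modified* from the classical maximal-deviation
(Dmax) threshold.

Geometry note: along a fixed chord the perpendicular distance to the
curve is the vertical deviation scaled by the constant factor
``cos(atan(m)) = 1/sqrt(1+m²)``, so the maximizer of the perpendicular
distance coincides with the maximizer of the vertical deviation; both are
characterised by the stationarity condition ``curve'(P) = chord slope``.
The implementation solves that condition exactly (quadratic roots) and
therefore inherits this invariance; see the tests for the grid-search
cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .types import Config, DEFAULT_CONFIG, InsufficientDataError

__all__ = [
    "LactateCurve",
    "ThresholdResult",
    "fit_cubic",
    "first_rise",
    "max_deviation_point",
    "determine_lt2",
    "NO_FIRST_RISE",
    "NO_DEVIATION_MAX",
    "ORDER_VIOLATION",
]

# machine-readable validity failure codes (exclusion bookkeeping)
NO_FIRST_RISE = "no-first-rise"
NO_DEVIATION_MAX = "no-deviation-max"
ORDER_VIOLATION = "order-violation"


@dataclass(frozen=True)
class LactateCurve:
    """Cubic least-squares fit of bLa (mmol·L⁻¹) against power (W).

    ``coeffs`` are ascending (c0..c3): bla(P) = c0 + c1 P + c2 P² + c3 P³.
    """

    points: tuple[tuple[float, float], ...]
    coeffs: tuple[float, float, float, float]
    residual_ss: float

    @property
    def domain(self) -> tuple[float, float]:
        return self.points[0][0], self.points[-1][0]

    def __call__(self, power):
        return npoly.polyval(power, self.coeffs)

    def derivative(self, power):
        return npoly.polyval(power, npoly.polyder(self.coeffs))

    def second_derivative(self, power):
        return npoly.polyval(power, npoly.polyder(self.coeffs, 2))


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the modified maximal-deviation determination."""

    lt2_power: float | None  # W
    lt2_bla: float | None  # mmol·L⁻¹, cubic evaluated at lt2_power
    first_rise_power: float | None  # W, LT1 anchor
    chord: tuple[tuple[float, float], tuple[float, float]] | None
    curve: LactateCurve | None
    valid: bool
    reasons: tuple[str, ...] = ()


def fit_cubic(points) -> LactateCurve:
    """Least-squares cubic of bLa on power.

    Requires at least four points with strictly increasing, distinct
    powers.  Exactly four points interpolate (zero residual) — legal but
    flagged with a warning since the fit has no redundancy.
    """
    pts = [(float(p), float(b)) for p, b in points]
    if len(pts) < 4:
        raise InsufficientDataError(
            f"cubic fit needs >= 4 lactate points, got {len(pts)}"
        )
    powers = np.array([p for p, _ in pts])
    blas = np.array([b for _, b in pts])
    if np.any(np.diff(powers) <= 0):
        raise ValueError("powers must be strictly increasing")
    if len(pts) == 4:
        warnings.warn("cubic fit to exactly 4 points interpolates (no redundancy)",
                      stacklevel=2)
    # centering-free Vandermonde solve; powers are a few hundred W at most
    coeffs, stats = npoly.polyfit(powers, blas, 3, full=True)
    resid = npoly.polyval(powers, coeffs) - blas
    return LactateCurve(points=tuple(pts), coeffs=tuple(coeffs),
                        residual_ss=float(resid @ resid))


def _real_roots(poly_desc: list[float]) -> np.ndarray:
    """Real roots of a polynomial given in descending coefficients."""
    poly = np.trim_zeros(np.asarray(poly_desc, float), "f")
    if poly.size <= 1:
        return np.array([])
    roots = np.roots(poly)
    return np.sort(roots[np.abs(roots.imag) < 1e-9].real)


def first_rise(curve: LactateCurve, slope_threshold: float = 0.01) -> float:
    """Power of the first rise in bLa: lowest power in the fit domain where
    the cubic's slope reaches ``slope_threshold`` from below (slope rising
    through the criterion).

    If the slope already exceeds the threshold at the start of the domain
    the domain start is returned.  Raises ``ValueError`` tagged
    ``no-first-rise`` when the slope never attains the threshold.
    """
    lo, hi = curve.domain
    if curve.derivative(lo) >= slope_threshold:
        return lo
    c = curve.coeffs
    # c1 + 2 c2 P + 3 c3 P² = threshold
    roots = _real_roots([3 * c[3], 2 * c[2], c[1] - slope_threshold])
    for r in roots:
        if lo <= r <= hi and curve.second_derivative(r) > 0:
            return float(r)
    raise ValueError(NO_FIRST_RISE)


def max_deviation_point(curve: LactateCurve,
                        chord_from: tuple[float, float],
                        chord_to: tuple[float, float]) -> float:
    """Power maximizing the perpendicular distance from the cubic to the
    chord, restricted to the open interval between the chord endpoints.

    Solved exactly: stationary points satisfy ``curve'(P) = chord slope``
    (a quadratic); all interior roots are compared by distance, ties going
    to the lower power.  Raises ``ValueError`` tagged ``no-deviation-max``
    if no interior stationary point exists.
    """
    (p1, b1), (p2, b2) = chord_from, chord_to
    if not p1 < p2:
        raise ValueError("chord endpoints must have increasing power")
    m = (b2 - b1) / (p2 - p1)
    c = curve.coeffs
    roots = _real_roots([3 * c[3], 2 * c[2], c[1] - m])
    interior = [float(r) for r in roots if p1 < r < p2]
    if not interior:
        raise ValueError(NO_DEVIATION_MAX)
    scale = 1.0 / math.hypot(1.0, m)

    def perp(p: float) -> float:
        return abs(curve(p) - (b1 + m * (p - p1))) * scale

    best = max(interior, key=lambda p: (perp(p), -p))
    if perp(best) <= 0.0:
        raise ValueError(NO_DEVIATION_MAX)
    return best


def determine_lt2(points, cfg: Config = DEFAULT_CONFIG) -> ThresholdResult:
    """Full modified maximal-deviation determination on per-stage
    (power, bLa) points from a completed step test.

    Composes :func:`fit_cubic` → :func:`first_rise` →
    :func:`max_deviation_point` with chord endpoint 2 fixed at the last
    *measured* data point.  ``valid`` is True only when every sub-step
    succeeds and ``first_rise_power < lt2_power < last power``; otherwise
    machine-readable failure codes are collected so that cohort assembly
    can report exclusion counts.
    """
    reasons: list[str] = []
    curve = fit_cubic(points)
    last_p, last_bla = curve.points[-1]

    fr: float | None = None
    try:
        fr = first_rise(curve, cfg.first_rise_slope)
    except ValueError as e:
        reasons.append(str(e))

    lt2 = None
    chord = None
    if fr is not None:
        if fr >= last_p:
            reasons.append(ORDER_VIOLATION)
        else:
            chord = ((fr, float(curve(fr))), (last_p, last_bla))
            try:
                lt2 = max_deviation_point(curve, chord[0], chord[1])
            except ValueError as e:
                reasons.append(str(e))

    valid = not reasons and lt2 is not None and fr is not None and fr < lt2 < last_p
    if lt2 is not None and fr is not None and not fr < lt2 < last_p:
        reasons.append(ORDER_VIOLATION)
        valid = False
    return ThresholdResult(
        lt2_power=lt2,
        lt2_bla=float(curve(lt2)) if lt2 is not None else None,
        first_rise_power=fr,
        chord=chord,
        curve=curve,
        valid=valid,
        reasons=tuple(reasons),
    )
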