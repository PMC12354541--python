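"""The physiological model of power output at the second lactate threshold.

Power at LT2 is modeled from the three classical determinants of
endurance performance — maximal oxygen uptake, its fractional
utilization at LT2, and the oxygen cost of cycling:

    modLT2 [W] = frac_util · V̇O2peak [mL·min⁻¹] / Cc [mL·min⁻¹·W⁻¹]

Fractional utilization is carried as a fraction internally (0-1) and
becomes a percentage only at I/O, which removes the 100x ambiguity of
percent notation.  Three model variants arise from the three Cc
determination intensities (fixed 3 W·kg⁻¹, 75% V̇O2peak, 90% LT2 power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .gas_exchange import EconomyResult

__all__ = ["ModelEstimate", "model_lt2", "model_all"]


@dataclass(frozen=True)
class ModelEstimate:
    """Modeled power at LT2 per Cc variant, with the inputs echoed."""

    mod_lt2_fix: float | None  # W
    mod_lt2_frac_vo2: float | None
    mod_lt2_frac_lt2: float | None
    vo2peak: float  # mL·min⁻¹
    frac_util: float  # fraction
    cc_fix: float | None  # mL·min⁻¹·W⁻¹
    cc_frac_vo2: float | None
    cc_frac_lt2: float | None


def model_lt2(frac_util: float, vo2peak: float, cc: float) -> float:
    """Modeled power at LT2 (W) = frac_util · V̇O2peak / Cc."""
    if frac_util <= 0 or vo2peak <= 0 or cc <= 0:
        raise ValueError("frac_util, vo2peak and cc must all be positive")
    if frac_util > 1.05:
        warnings.warn(f"fractional utilization {frac_util:.2f} above 1.05 — "
                      "was a percentage passed instead of a fraction?",
                      stacklevel=2)
    return frac_util * vo2peak / cc


def model_all(econ: EconomyResult, vo2peak: float) -> ModelEstimate:
    """Apply the model with each available Cc variant.

    A missing (None) Cc leaves that variant absent; the others are still
    computed.
    """
    def maybe(cc):
        return None if cc is None else model_lt2(econ.frac_util, vo2peak, cc)

    return ModelEstimate(
        mod_lt2_fix=maybe(econ.cc_fix),
        mod_lt2_frac_vo2=maybe(econ.cc_frac_vo2),
        mod_lt2_frac_lt2=maybe(econ.cc_frac_lt2),
        vo2peak=vo2peak, frac_util=econ.frac_util,
        cc_fix=econ.cc_fix, cc_frac_vo2=econ.cc_frac_vo2,
        cc_frac_lt2=econ.cc_frac_lt2,
    )
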