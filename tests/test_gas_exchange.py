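"""Gas-exchange processing: peaks, stage means, regression, economy."""

import numpy as np
import pandas as pd
import pytest

from lt2lab.gas_exchange import (
    check_exhaustion,
    economy,
    ge_at,
    stage_average,
    submax_regression,
    vo2peak,
)
from lt2lab.types import Config, InsufficientDataError, Stage


def _breaths(vo2, vco2=None, t0=1.0):
    vo2 = np.asarray(vo2, float)
    vco2 = vo2 * 0.9 if vco2 is None else np.asarray(vco2, float)
    t = np.arange(t0, t0 + len(vo2))
    return pd.DataFrame({"t": t, "vo2": vo2, "vco2": vco2})


class TestVo2Peak:
    def test_constant_series(self):
        assert vo2peak(_breaths(np.full(120, 3000.0)), 30) == 3000.0

    def test_ramp_series_hand_enumeration(self):
        # vo2(t) = t for t = 1..100; best 30-s window is 71..100, mean 85.5
        assert vo2peak(_breaths(np.arange(1.0, 101.0)), 30) == pytest.approx(85.5)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            vo2peak(_breaths(np.ones(29)), 30)

    def test_invariant_to_trailing_zeros_shorter_than_window(self):
        v = np.concatenate([np.linspace(1000, 3000, 200), np.zeros(20)])
        assert vo2peak(_breaths(v), 30) == vo2peak(_breaths(v[:200]), 30)


class TestExhaustion:
    @pytest.mark.parametrize(
        "rer,hr,age,bla,vol,count,ok",
        [
            (1.12, 196.0, 15, 9.0, True, 4, True),  # 0.95·205 = 194.75
            (1.00, None, 15, 5.0, True, 1, False),  # volitional only
            (1.10, 194.75, 15, 8.0, False, 3, True),  # boundary equality met
            (1.00, 150.0, 15, 2.0, False, 0, False),
        ],
    )
    def test_criteria_counting(self, rer, hr, age, bla, vol, count, ok):
        assert check_exhaustion(rer, hr, age, bla, vol) == (count, ok)


class TestStageAverage:
    def test_constant_stage(self):
        stage = Stage(index=0, power=100, start_t=0, end_t=180, bla_end=1.5)
        vo2, vco2 = stage_average(_breaths(np.full(180, 2000.0)), stage, 60)
        assert vo2 == 2000.0

    def test_ramp_matches_direct_summation(self):
        stage = Stage(index=0, power=100, start_t=0, end_t=180, bla_end=1.5)
        v = 100.0 * np.arange(1.0, 181.0)  # vo2 = 100·t
        vo2, _ = stage_average(_breaths(v), stage, 60)
        assert vo2 == pytest.approx(100.0 * np.mean(np.arange(121, 181)))

    def test_truncated_stage_fails_coverage(self):
        stage = Stage(index=0, power=100, start_t=0, end_t=180, bla_end=1.5)
        with pytest.raises(InsufficientDataError):
            stage_average(_breaths(np.full(30, 2000.0), t0=1.0), stage, 60)


class TestSubmaxRegression:
    def test_exact_linear_stages(self):
        means = [(i, p, 10 * p + 500, 9 * p + 450) for i, p in
                 enumerate([100, 120, 140, 160])]
        reg = submax_regression(means, lt2_power=160)
        assert reg.slope_vo2 == pytest.approx(10.0, abs=1e-9)
        assert reg.intercept_vo2 == pytest.approx(500.0, abs=1e-6)
        assert reg.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        p = np.array([100, 120, 140, 160, 180, 200.0])
        vo2 = 12 * p + 400 + rng.normal(0, 40, 6)
        vco2 = 11 * p + 350 + rng.normal(0, 40, 6)
        means = list(zip(range(6), p, vo2, vco2))
        reg = submax_regression(means, lt2_power=200)
        X = np.column_stack([np.ones(6), p])
        bo = np.linalg.solve(X.T @ X, X.T @ vo2)
        bc = np.linalg.solve(X.T @ X, X.T @ vco2)
        assert np.allclose([reg.intercept_vo2, reg.slope_vo2], bo, atol=1e-10)
        assert np.allclose([reg.intercept_vco2, reg.slope_vco2], bc, atol=1e-10)

    def test_boundary_stage_included(self):
        means = [(i, p, 10 * p + 500, 9 * p) for i, p in
                 enumerate([100, 120, 140, 160, 180])]
        reg = submax_regression(means, lt2_power=140.0)
        assert reg.stages_used == (0, 1, 2)

    def test_lt2_below_first_stage_rejected(self):
        means = [(i, p, 10 * p, 9 * p) for i, p in enumerate([100, 120, 140, 160])]
        with pytest.raises(InsufficientDataError):
            submax_regression(means, lt2_power=90)


class TestEconomy:
    @pytest.fixture
    def reg(self):
        means = [(i, p, 10 * p + 500, 9 * p + 450) for i, p in
                 enumerate([100, 130, 160, 190])]
        return submax_regression(means, lt2_power=200)

    def test_fixed_power_hand_arithmetic(self, reg):
        econ = economy(reg, vo2peak_value=3456, lt2_power=216, body_mass=59)
        assert econ.eval_powers[0] == pytest.approx(177.0)
        assert econ.cc_fix == pytest.approx(2270 / 177, abs=1e-9)

    def test_percent_vo2peak_power_hand_arithmetic(self, reg):
        econ = economy(reg, vo2peak_value=3456, lt2_power=216, body_mass=59)
        assert econ.eval_powers[1] == pytest.approx((0.75 * 3456 - 500) / 10)
        assert econ.cc_frac_vo2 == pytest.approx(2592 / 209.2, abs=1e-9)

    def test_percent_lt2_power_hand_arithmetic(self, reg):
        econ = economy(reg, vo2peak_value=3456, lt2_power=216, body_mass=59)
        assert econ.eval_powers[2] == pytest.approx(0.9 * 216)
        assert econ.cc_frac_lt2 == pytest.approx((10 * 194.4 + 500) / 194.4, abs=1e-9)

    def test_frac_util_is_predicted_vo2_over_peak(self, reg):
        econ = economy(reg, vo2peak_value=3456, lt2_power=216, body_mass=59)
        assert econ.frac_util == pytest.approx((10 * 216 + 500) / 3456)

    def test_ge_cc_product_constant_at_fixed_rer(self, reg):
        # at any intensity, GE·Cc depends only on the local RER
        econ = economy(reg, vo2peak_value=3456, lt2_power=216, body_mass=59)
        for cc, ge, p in [
            (econ.cc_fix, econ.ge_fix, econ.eval_powers[0]),
            (econ.cc_frac_vo2, econ.ge_frac_vo2, econ.eval_powers[1]),
            (econ.cc_frac_lt2, econ.ge_frac_lt2, econ.eval_powers[2]),
        ]:
            vo2 = float(reg.predict_vo2(p))
            vco2 = float(reg.predict_vco2(p))
            rer = vco2 / vo2
            # GE·Cc = 100 / [(0.550·RER + 4.471)/1000 · 69.733]: RER-only
            expected_product = 100.0 / ((0.550 * rer + 4.471) / 1000 * (4184 / 60))
            assert ge * cc == pytest.approx(expected_product, abs=1e-9)


class TestGrossEfficiency:
    def test_hand_arithmetic(self):
        # EE = 0.550·2.34 + 4.471·2.60 = 12.9116 kcal·min⁻¹ → 900.4 W
        ge = ge_at(200, 2600, 2340)
        assert ge == pytest.approx(100 * 200 / (12.9116 * 4184 / 60), abs=1e-9)
        assert ge == pytest.approx(22.21, abs=0.01)

    def test_doubling_gases_halves_ge(self):
        assert ge_at(200, 5200, 4680) == pytest.approx(ge_at(200, 2600, 2340) / 2)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            ge_at(0, 2600, 2340)


class TestZeroNoiseRecovery:
    def test_slope_and_frac_util_recovery(self, zero_noise_cohort):
        """Submaximal slope recovers the generated oxygen cost almost
        exactly; fractional utilization is recovered to ~1e-3 (median),
        limited by the mono-exponential on-kinetics undershoot of the
        stage means."""
        from lt2lab.gas_exchange import stage_average as sa
        slope_err, frac_err = [], []
        for ath, step, _, gt in zero_noise_cohort:
            means = [(s.index, s.power, *sa(step.breaths, s)) for s in step.stages]
            reg = submax_regression(means, gt.lt2_power_noiseless)
            slope_err.append(abs(reg.slope_vo2 / gt.cc_true - 1))
            vp = vo2peak(step.breaths)
            econ = economy(reg, vp, gt.lt2_power_noiseless, ath.body_mass)
            frac_err.append(abs(econ.frac_util / gt.frac_util_op - 1))
        assert max(slope_err) < 1e-3
        assert np.median(frac_err) < 1e-3
        assert max(frac_err) < 2e-3
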