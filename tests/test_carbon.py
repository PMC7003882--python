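"""Carbon-gain integration, leaf aging, LCP diagnostics, Rd sensitivity."""

import numpy as np
import pandas as pd
import pytest

from daphnegain import (AgingSchedule, HybridResponseSurface, LorentzianParams,
                        ParaboloidParams, apply_aging, identity_schedule,
                        integrate_carbon_gain, lcp_diagnostics, rd_sensitivity)
from tests.conftest import constant_day_climate

HIGH = LorentzianParams(a=8.0, k=20.0, b=15.0, l=900.0, c=800.0)


def flat_surface(value: float) -> HybridResponseSurface:
    """Surface predicting a constant in the low regime (PAR kept < 75)."""
    return HybridResponseSurface(
        low=ParaboloidParams(k=value, a=0.0, b=0.0, c=0.0, d=0.0), high=HIGH)


def par_linear_surface(intercept: float, slope: float) -> HybridResponseSurface:
    return HybridResponseSurface(
        low=ParaboloidParams(k=intercept, a=0.0, b=slope, c=0.0, d=0.0),
        high=HIGH)


class TestIntegration:
    def test_constant_unit_flux_integrates_to_86_4_mmol(self):
        climate = constant_day_climate("2006-06-10", par=20.0, temp=15.0)
        table = integrate_carbon_gain(flat_surface(1.0), climate,
                                      months=[6], window=(10, 10),
                                      sanitize=False)
        assert table.loc[0, "mean_daily_gain_raw_mmol"] == pytest.approx(86.4)
        assert table.loc[0, "n_days"] == 1

    def test_two_level_day_integrates_piecewise(self):
        # Pn = 2 for 12 h (par = 1), -0.5 for 12 h (par = 0)
        climate = constant_day_climate("2006-06-10", par=0.0, temp=15.0)
        climate.loc[:359, "par"] = 1.0
        surf = par_linear_surface(-0.5, 2.5)
        table = integrate_carbon_gain(surf, climate, months=[6],
                                      window=(10, 10), sanitize=False)
        assert table.loc[0, "mean_daily_gain_raw_mmol"] == pytest.approx(64.8)

    def test_integration_linear_in_surface(self):
        climate = constant_day_climate("2006-06-10", par=30.0, temp=18.0)
        climate["par"] = np.linspace(0, 70, 720)
        s1 = par_linear_surface(-0.3, 0.02)
        s2 = par_linear_surface(-0.1, 0.01)
        s_sum = par_linear_surface(-0.4, 0.03)
        gains = [integrate_carbon_gain(s, climate, months=[6], window=(10, 10),
                                       sanitize=False)
                 .loc[0, "mean_daily_gain_raw_mmol"]
                 for s in (s1, s2, s_sum)]
        assert gains[0] + gains[1] == pytest.approx(gains[2])

    def test_excessive_gaps_abort(self):
        climate = constant_day_climate("2006-06-10", par=20.0, temp=15.0)
        climate = climate.iloc[: int(720 * 0.9)]  # 10% of the day missing
        with pytest.raises(ValueError, match="missing"):
            integrate_carbon_gain(flat_surface(1.0), climate, months=[6],
                                  window=(10, 10))

    def test_missing_month_aborts(self):
        climate = constant_day_climate("2006-06-10", par=20.0, temp=15.0)
        with pytest.raises(ValueError, match="no samples"):
            integrate_carbon_gain(flat_surface(1.0), climate, months=[7])


class TestAging:
    def test_identity_schedule_leaves_gains_unchanged(self):
        table = pd.DataFrame({"plant_id": "p", "month": [4, 8],
                              "mean_daily_gain_raw_mmol": [50.0, -10.0],
                              "mean_daily_gross_mmol": [80.0, 30.0],
                              "mean_daily_resp_mmol": [30.0, 40.0]})
        aged = apply_aging(table, identity_schedule())
        np.testing.assert_allclose(aged["mean_daily_gain_aged_mmol"],
                                   table["mean_daily_gain_raw_mmol"])

    def test_default_schedule_reaches_30_percent_in_august(self):
        schedule = AgingSchedule()
        assert schedule.factor(10) == 1.0
        assert schedule.factor(8) == pytest.approx(0.30, abs=1e-12)

    def test_linear_schedule_five_months_after_anchor(self):
        schedule = AgingSchedule(mode="linear", monthly_decline=0.07)
        assert schedule.factor(3) == pytest.approx(0.65)

    def test_factors_nonincreasing_from_anchor(self):
        schedule = AgingSchedule()
        factors = [schedule.factor(((10 + d - 1) % 12) + 1) for d in range(11)]
        assert all(a >= b for a, b in zip(factors, factors[1:]))

    def test_aged_gain_never_exceeds_raw_for_positive_gross(self):
        table = pd.DataFrame({"plant_id": "p", "month": list(range(1, 13)),
                              "mean_daily_gain_raw_mmol": 50.0,
                              "mean_daily_gross_mmol": 80.0,
                              "mean_daily_resp_mmol": 30.0})
        aged = apply_aging(table, AgingSchedule())
        assert (aged["mean_daily_gain_aged_mmol"]
                <= aged["mean_daily_gain_raw_mmol"] + 1e-12).all()

    def test_month_outside_explicit_schedule_rejected(self):
        schedule = AgingSchedule(factors={10: 1.0, 11: 0.9})
        table = pd.DataFrame({"plant_id": "p", "month": [12],
                              "mean_daily_gain_raw_mmol": [1.0],
                              "mean_daily_gross_mmol": [2.0],
                              "mean_daily_resp_mmol": [1.0]})
        with pytest.raises(ValueError, match="outside"):
            apply_aging(table, schedule)

    def test_net_component_mode_scales_raw_gain(self):
        table = pd.DataFrame({"plant_id": "p", "month": [8],
                              "mean_daily_gain_raw_mmol": [40.0],
                              "mean_daily_gross_mmol": [90.0],
                              "mean_daily_resp_mmol": [50.0]})
        aged = apply_aging(table, AgingSchedule(), component="net")
        assert aged.loc[0, "mean_daily_gain_aged_mmol"] == pytest.approx(0.3 * 40.0)


class TestLcpDiagnostics:
    def test_permanent_darkness_gives_fraction_one(self):
        climate = constant_day_climate("2006-08-10", par=0.0, temp=25.0)
        diag = lcp_diagnostics(climate, lcp=9.2, pn=np.full(720, -0.5))
        assert diag.frac_time_below_lcp == 1.0
        assert diag.cost_ratio is None

    def test_constructed_fraction_below_lcp(self):
        climate = constant_day_climate("2006-08-10", par=0.0, temp=25.0).iloc[:100]
        climate = climate.copy()
        climate.loc[climate.index[:11], "par"] = 50.0
        pn = np.where(climate["par"] > 0, 1.0, -0.2)
        diag = lcp_diagnostics(climate, lcp=9.2, pn=pn)
        assert diag.frac_time_below_lcp == pytest.approx(0.89)

    def test_constructed_cost_ratio(self):
        # below-LCP net loss 6.2 µmol-scale units, above-LCP gain 1.0
        climate = constant_day_climate("2006-08-10", par=0.0, temp=25.0).iloc[:20]
        climate = climate.copy()
        climate.loc[climate.index[:10], "par"] = 50.0
        pn = np.empty(20)
        pn[:10] = 1.0 / (10 * 0.12)    # above-LCP: integrates to +1.0 mmol
        pn[10:] = -6.2 / (10 * 0.12)   # below-LCP: integrates to -6.2 mmol
        diag = lcp_diagnostics(climate, lcp=9.2, pn=pn, sanitize=False)
        assert diag.cost_ratio == pytest.approx(6.2)

    def test_empty_period_rejected(self):
        climate = constant_day_climate("2006-08-10", par=0.0, temp=25.0)
        with pytest.raises(ValueError):
            lcp_diagnostics(climate, lcp=9.2, pn=np.zeros(720), month=2)


class TestRdSensitivity:
    def test_uniform_offset_closed_form(self, ref_surface, year_climate):
        sweep = rd_sensitivity(ref_surface, year_climate, month=8,
                               rd_values=[0.5, 0.9])
        g1, g2 = sweep["mean_daily_gain_mmol"]
        assert g2 == pytest.approx(g1 - (0.9 - 0.5) * 86.4, abs=1e-8)

    def test_gain_monotonically_decreasing_in_rd(self, ref_surface, year_climate):
        sweep = rd_sensitivity(ref_surface, year_climate, month=8,
                               rd_values=np.linspace(0.1, 1.5, 8))
        assert sweep["mean_daily_gain_mmol"].is_monotonic_decreasing

    def test_zero_rd_with_nonnegative_light_response_gains(self):
        climate = constant_day_climate("2006-06-10", par=30.0, temp=20.0)
        surf = par_linear_surface(-0.5, 0.02)  # Pn(0, 20) = -0.5
        sweep = rd_sensitivity(surf, climate, month=6, rd_values=[0.0],
                               window=(10, 10), ref_temp=20.0)
        assert sweep.loc[0, "mean_daily_gain_mmol"] >= 0.0

    def test_negative_rd_rejected(self, ref_surface, year_climate):
        with pytest.raises(ValueError):
            rd_sensitivity(ref_surface, year_climate, month=8, rd_values=[-0.1])
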