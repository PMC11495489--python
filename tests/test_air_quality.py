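"""Aerosol equilibrium, PM response, polluted days, sub-grid heterogeneity."""

import numpy as np
import pytest

from nh3iam import control_efficiency, equilibrium_pm, pm_response, subgrid_experiment
from nh3iam.air_quality import (MW_HNO3, MW_NH3, MW_SO4, daily_pm_series,
                                dissociation_constant, polluted_day_change_pct,
                                polluted_day_frequency, weighted_summary)
from nh3iam.inventory import DomainError

T, RH = 283.0, 0.6


@pytest.fixture(scope="module")
def aq():
    from nh3iam import default_params
    return default_params()["air_quality"]


class TestEquilibrium:
    def test_no_ammonia_no_ammonium_salts(self, aq):
        s = equilibrium_pm(0.0, 10.0, 20.0, T, RH, aq)
        assert s.nh4 == 0.0 and s.no3 == 0.0
        assert s.pm25_inorganic == pytest.approx(10.0)

    def test_stoichiometric_sulfate_closure(self, aq):
        so4 = 9.606  # 0.1 umol/m3
        nh3 = 2 * (so4 / MW_SO4) * MW_NH3  # exactly 2 mol NH4 per mol SO4
        s = equilibrium_pm(nh3, so4, 0.0, T, RH, aq)
        assert s.nh3_gas == pytest.approx(0.0, abs=1e-12)
        assert s.nh4 == pytest.approx(2 * (so4 / MW_SO4) * 18.039, rel=1e-9)

    def test_mass_conservation_random(self, aq, rng):
        nh3 = rng.uniform(0, 60, 500)
        so4 = rng.uniform(0, 30, 500)
        tn = rng.uniform(0, 40, 500)
        t = rng.uniform(250, 310, 500)
        rh = rng.uniform(0.2, 0.95, 500)
        s = equilibrium_pm(nh3, so4, tn, t, rh, aq)
        assert np.allclose(s.total_n_ug_mol, nh3 / MW_NH3, rtol=1e-9)
        assert np.allclose(s.total_nitrate_ug_mol, tn / MW_HNO3, rtol=1e-9)
        assert (s.nh3_gas >= -1e-12).all() and (s.hno3_gas >= -1e-12).all()
        assert (s.nh4 >= 0).all() and (s.no3 >= 0).all()

    def test_rich_regime_insensitive_poor_regime_sensitive(self, aq):
        """|dPM/dNH3| is small above the stoichiometric crossover, large below."""
        so4, tn = 8.0, 15.0
        rich = 80.0
        pm = lambda x: float(equilibrium_pm(x, so4, tn, 278.0, 0.75, aq).pm25_inorganic)
        rich_change = abs(pm(rich) - pm(rich * 0.9)) / pm(rich)
        assert rich_change < 0.01
        poor = 2.0  # below sulfate demand
        poor_sens = abs(pm(poor) - pm(poor * 0.9)) / (0.1 * poor)
        rich_sens = abs(pm(rich) - pm(rich * 0.9)) / (0.1 * rich)
        assert poor_sens > 10 * rich_sens

    def test_negative_input_rejected(self, aq):
        with pytest.raises(DomainError):
            equilibrium_pm(-1.0, 1.0, 1.0, T, RH, aq)

    def test_unphysical_temperature_rejected(self, aq):
        with pytest.raises(DomainError):
            equilibrium_pm(1.0, 1.0, 1.0, 400.0, RH, aq)

    def test_kp_increases_with_temperature(self, aq):
        assert dissociation_constant(300.0, 0.4, aq) > dissociation_constant(270.0, 0.4, aq)

    def test_kp_suppressed_above_deliquescence(self, aq):
        assert dissociation_constant(290.0, 0.9, aq) < dissociation_constant(290.0, 0.4, aq)


class TestPMResponse:
    def test_identical_fields_zero_delta(self, small_region, small_baseline, aq):
        resp = pm_response(small_baseline, small_baseline, small_region, aq)
        assert np.allclose(resp["delta_pm"].values, 0.0)

    def test_reduction_never_increases_pm(self, small_region, small_baseline, aq, rng):
        scale = rng.uniform(0.4, 1.0, small_baseline.shape)
        scenario = small_baseline * scale
        resp = pm_response(small_baseline, scenario, small_region, aq)
        assert float(resp["delta_pm"].min()) >= -1e-9

    def test_concave_response_in_rich_cells(self, small_region, small_baseline, aq):
        """In the NH3-richest (peak-emission) cell, the 40->50% cut removes
        more PM2.5 than the first 10% cut."""
        r10 = pm_response(small_baseline, small_baseline * 0.9, small_region, aq)
        r40 = pm_response(small_baseline, small_baseline * 0.6, small_region, aq)
        r50 = pm_response(small_baseline, small_baseline * 0.5, small_region, aq)
        em = small_baseline.sum(dim=("sector", "month")).values
        idx = np.unravel_index(np.argmax(em), em.shape)
        def cell_delta(resp):
            return float(resp["delta_pm"].mean(dim="month").values[idx])
        first = cell_delta(r10)
        incremental = cell_delta(r50) - cell_delta(r40)
        assert incremental > first

    def test_grid_mismatch_rejected(self, small_region, small_baseline, aq):
        with pytest.raises(DomainError):
            pm_response(small_baseline, small_baseline.isel(row=slice(0, 6)),
                        small_region, aq)

    def test_weighted_summary_keys(self, small_region, small_baseline, aq):
        resp = pm_response(small_baseline, small_baseline * 0.7, small_region, aq)
        out = weighted_summary(resp, small_region)
        assert out["delta_pm_pop"] > 0
        assert out["pm_reduction_pct_pop"] > 0


class TestControlEfficiency:
    def test_pilot_scenario_quotient(self):
        assert control_efficiency(19.2, 48.3) == pytest.approx(0.40)

    def test_nationwide_scenario_quotient(self):
        assert control_efficiency(22.8, 58.2) == pytest.approx(0.39)

    def test_zero_pm_reduction(self):
        assert control_efficiency(0.0, 30.0) == 0.0

    def test_zero_nh3_reduction_rejected(self):
        with pytest.raises(DomainError):
            control_efficiency(5.0, 0.0)


class TestPollutedDays:
    def test_strictly_above_threshold(self):
        assert polluted_day_frequency(np.full(365, 149.9)) == 0

    def test_small_series(self):
        assert polluted_day_frequency(np.array([200.0, 100.0, 151.0])) == 2

    def test_change_pct(self):
        assert polluted_day_change_pct(100, 39) == pytest.approx(61.0)

    def test_empty_series_rejected(self):
        with pytest.raises(DomainError):
            polluted_day_frequency(np.array([]))

    def test_daily_series_shape(self, small_region, small_baseline):
        from nh3iam import default_params
        aq = default_params()["air_quality"]
        resp = pm_response(small_baseline, small_baseline, small_region, aq)
        daily = daily_pm_series(resp["pm_baseline"], small_region)
        assert daily.shape == (12, 12, 365)
        assert (daily > 0).all()


class TestSubgrid:
    ARGS = dict(livestock_flux=0.02, uniform_flux=0.004, sulfate=8.0,
                total_nitrate=15.0, t_k=278.0, rh=0.7)

    def test_uniform_has_zero_underestimation(self, aq):
        df = subgrid_experiment(**self.ARGS, params=aq, k_values=[100])
        assert df["underestimation_pct"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_deposition_all_zero(self, aq):
        df = subgrid_experiment(**self.ARGS, params=aq, k_values=[100, 25, 4, 1],
                                deposition_velocity=0.0)
        assert np.allclose(df["underestimation_pct"], 0.0)

    def test_monotone_with_concentration(self, aq):
        df = subgrid_experiment(**self.ARGS, params=aq, k_values=[100, 25, 4, 1])
        under = df.set_index("k_boxes")["underestimation_pct"]
        assert under[1] >= under[4] >= under[25] >= under[100] - 1e-12
        assert under[1] > 0.0

    def test_invalid_k_rejected(self, aq):
        with pytest.raises(DomainError):
            subgrid_experiment(**self.ARGS, params=aq, k_values=[0])
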