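"""Inventory: EF x activity arithmetic, seasonality, Monte Carlo CIs."""

import numpy as np
import pytest

from nh3iam import monte_carlo_ci, national_total_tg, sector_shares, total_inventory
from nh3iam.inventory import (DomainError, NH3_PER_N, fertilizer_emissions,
                              livestock_emissions, sector_totals)
from nh3iam.params import EmissionFactors

UNIFORM = np.full(12, 1.0 / 12)
FLAT_T = np.zeros(12)


class TestFertilizer:
    def test_zero_rate_is_zero(self):
        out = fertilizer_emissions(0.0, 1000.0, 0.12, UNIFORM, FLAT_T)
        assert np.all(out == 0)

    def test_hand_arithmetic_annual_total(self):
        # 100 kg N/ha x 1000 ha x 0.12 x 17/14 = 14571.43 kg
        out = fertilizer_emissions(100.0, 1000.0, 0.12, UNIFORM, FLAT_T)
        assert out.sum() == pytest.approx(14571.428571, rel=1e-9)

    def test_linear_in_ef(self):
        t = np.linspace(-5, 25, 12)
        one = fertilizer_emissions(50.0, 10.0, 0.05, UNIFORM, t, 0.04)
        two = fertilizer_emissions(50.0, 10.0, 0.10, UNIFORM, t, 0.04)
        assert np.allclose(two, 2.0 * one)

    def test_temperature_shifts_months_not_total(self):
        t = np.array([-10, -8, -2, 5, 12, 18, 22, 21, 15, 8, 0, -6], float)
        flat = fertilizer_emissions(100.0, 1000.0, 0.12, UNIFORM, FLAT_T, 0.04)
        warm = fertilizer_emissions(100.0, 1000.0, 0.12, UNIFORM, t, 0.04)
        assert warm.sum() == pytest.approx(flat.sum(), rel=1e-12)
        assert warm[6] > flat[6]  # July gains mass
        assert warm[0] < flat[0]

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            fertilizer_emissions(-1.0, 1.0, 0.1, UNIFORM, FLAT_T)


class TestLivestock:
    def test_zero_pig_units(self):
        out = livestock_emissions(0.0, 7.2, {"livestock_grazing": 0.3}, "free_range")
        assert np.all(out["livestock_grazing"] == 0)

    def test_hand_arithmetic_single_stage(self):
        # 1000 pu x 7.2 kg N x 0.3 x 17/14 = 2622.857 kg/yr
        out = livestock_emissions(1000.0, 7.2, {"livestock_grazing": 0.3}, "free_range")
        assert out["livestock_grazing"].sum() == pytest.approx(2622.857142857, rel=1e-9)

    def test_zero_stage_fractions(self):
        out = livestock_emissions(1000.0, 7.2, {"livestock_spreading": 0.0}, "free_range")
        assert np.all(out["livestock_spreading"] == 0)

    def test_unknown_class_rejected(self):
        with pytest.raises(DomainError):
            livestock_emissions(1.0, 7.2, {}, "medium")

    def test_free_range_has_no_housing(self):
        with pytest.raises(DomainError):
            livestock_emissions(1.0, 7.2, {"livestock_housing": 0.1}, "free_range")

    def test_stage_sum_bounded_by_excreted_n(self):
        stages = {"livestock_housing": 0.15, "livestock_storage": 0.09,
                  "livestock_spreading": 0.118}
        out = livestock_emissions(1000.0, 7.2, stages, "large_scale")
        total = sum(v.sum() for v in out.values())
        assert total <= 1000.0 * 7.2 * NH3_PER_N + 1e-9


class TestTotalInventory:
    def test_sector_shares_sum_to_100(self, small_baseline):
        assert sector_shares(small_baseline).sum() == pytest.approx(100.0, abs=1e-4)

    def test_everything_non_negative(self, small_baseline):
        assert float(small_baseline.min()) >= 0.0

    def test_independent_national_summation(self, small_region, factors, small_baseline):
        """National total re-derived directly from cells and farms."""
        cells = small_region.cells
        fert = (cells["n_rate"] * cells["cropland_ha"]).sum() * factors.fertilizer_ef * NH3_PER_N / 1e6
        from nh3iam.synthetic_data import farm_pig_units
        pu = farm_pig_units(small_region.farms)
        live = 0.0
        for cls in ("free_range", "large_scale"):
            cls_pu = pu[small_region.farms["farm_class"] == cls].sum()
            frac = sum(factors.stage_fractions[cls].values())
            live += cls_pu * factors.excretion_n_kg_per_pu * frac * NH3_PER_N / 1e6
        expected = fert + live + factors.other_total_gg
        assert float(small_baseline.sum()) == pytest.approx(expected, rel=1e-9)

    def test_summer_exceeds_winter(self, small_baseline):
        jja = float(small_baseline.sel(month=[6, 7, 8]).sum())
        djf = float(small_baseline.sel(month=[12, 1, 2]).sum())
        assert jja > djf

    def test_zero_efs_give_zero(self, small_region, factors):
        zero = EmissionFactors(
            fertilizer_ef=0.0,
            fertilizer_monthly_weights=factors.fertilizer_monthly_weights,
            excretion_n_kg_per_pu=0.0,
            temperature_sensitivity=0.0,
            stage_fractions={k: {s: 0.0 for s in v}
                             for k, v in factors.stage_fractions.items()},
            other_total_gg=0.0,
        )
        field = total_inventory(small_region, zero)
        assert float(field.sum()) == 0.0

    def test_activity_linearity(self, small_region, factors, small_baseline):
        """Doubling all activity (cropland, heads, other) doubles every value."""
        import copy
        fixture = copy.deepcopy(small_region)
        fixture.cells["cropland_ha"] *= 2.0
        head_cols = [c for c in fixture.farms.columns if c.startswith("heads_")]
        fixture.farms[head_cols] *= 2.0
        doubled_factors = EmissionFactors(
            fertilizer_ef=factors.fertilizer_ef,
            fertilizer_monthly_weights=factors.fertilizer_monthly_weights,
            excretion_n_kg_per_pu=factors.excretion_n_kg_per_pu,
            temperature_sensitivity=factors.temperature_sensitivity,
            stage_fractions=factors.stage_fractions,
            other_total_gg=2.0 * factors.other_total_gg,
        )
        field = total_inventory(fixture, doubled_factors)
        assert np.allclose(field.values, 2.0 * small_baseline.values, rtol=1e-9)


class TestMonteCarlo:
    def test_zero_uncertainty_degenerate(self, small_region, factors, small_baseline):
        no_unc = EmissionFactors(
            fertilizer_ef=factors.fertilizer_ef,
            fertilizer_monthly_weights=factors.fertilizer_monthly_weights,
            excretion_n_kg_per_pu=factors.excretion_n_kg_per_pu,
            temperature_sensitivity=factors.temperature_sensitivity,
            stage_fractions=factors.stage_fractions,
            other_total_gg=factors.other_total_gg,
            uncertainty_gsd={},
        )
        mc = monte_carlo_ci(small_region, no_unc, n_draws=200, seed=5, field=small_baseline)
        assert mc.p05 == pytest.approx(mc.mean, rel=1e-12)
        assert mc.p95 == pytest.approx(mc.mean, rel=1e-12)

    def test_seed_reproducibility(self, small_region, factors, small_baseline):
        a = monte_carlo_ci(small_region, factors, n_draws=300, seed=9, field=small_baseline)
        b = monte_carlo_ci(small_region, factors, n_draws=300, seed=9, field=small_baseline)
        assert (a.p05, a.p95, a.mean) == (b.p05, b.p95, b.mean)

    def test_single_factor_matches_lognormal_quantiles(self, small_region, factors, small_baseline):
        """Fertilizer-only toy inventory vs closed-form log-normal quantiles."""
        single = EmissionFactors(
            fertilizer_ef=factors.fertilizer_ef,
            fertilizer_monthly_weights=factors.fertilizer_monthly_weights,
            excretion_n_kg_per_pu=0.0,
            temperature_sensitivity=0.0,
            stage_fractions={k: {s: 0.0 for s in v}
                             for k, v in factors.stage_fractions.items()},
            other_total_gg=0.0,
            uncertainty_gsd={"fertilizer_ef": 1.2},
        )
        field = total_inventory(small_region, single)
        base = float(field.sum()) / 1000.0
        mc = monte_carlo_ci(small_region, single, n_draws=10_000, seed=3, field=field)
        z = 1.6448536269514722
        assert mc.p05 == pytest.approx(base * np.exp(-z * np.log(1.2)), rel=0.01)
        assert mc.p95 == pytest.approx(base * np.exp(z * np.log(1.2)), rel=0.01)

    def test_too_few_draws_rejected(self, small_region, factors, small_baseline):
        with pytest.raises(DomainError):
            monte_carlo_ci(small_region, factors, n_draws=1, seed=0, field=small_baseline)
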