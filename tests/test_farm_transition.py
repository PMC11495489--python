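"""Transition rules: pig-unit algebra, consolidation, N-rate decline, reallocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nh3iam import consolidate_parcels, n_rate_after, pig_units, reallocate_livestock
from nh3iam.farm_transition import (AllocationError, DomainError,
                                    large_scale_fraction, mean_parcel_size,
                                    transition_region)
from nh3iam.synthetic_data import SPECIES, farm_pig_units

EDGES = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0]


class TestPigUnits:
    def test_dairy_cattle_factor(self):
        assert pig_units({"dairy_cattle": 10}) == pytest.approx(100.0)

    def test_empty_is_zero(self):
        assert pig_units({}) == 0.0

    def test_poultry_and_sheep(self):
        # 60 broilers x 1/60 + 3 sheep x 1/3 = 2 pig units
        assert pig_units({"broiler_poultry": 60, "sheep_goats": 3}) == pytest.approx(2.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(DomainError):
            pig_units({"llama": 5})

    def test_negative_heads_rejected(self):
        with pytest.raises(DomainError):
            pig_units({"swine": -1})


class TestConsolidation:
    def test_steep_cell_unchanged(self):
        hist = np.array([10.0, 20.0, 30.0, 5.0, 1.0, 0.0])
        out = consolidate_parcels(hist, EDGES, slope=10.0)
        assert np.array_equal(out, hist)

    def test_flat_cell_merges_below_threshold(self):
        # mass at 1-2 ha (100) and 2-5 ha (50) -> all in 2-5 ha
        hist = np.array([0.0, 0.0, 100.0, 50.0, 0.0, 0.0])
        out = consolidate_parcels(hist, EDGES, slope=2.0)
        assert np.array_equal(out, [0, 0, 0, 150.0, 0, 0])
        assert large_scale_fraction(out, EDGES) == pytest.approx(1.0)

    def test_negative_slope_rejected(self):
        with pytest.raises(DomainError):
            consolidate_parcels(np.zeros(6), EDGES, slope=-1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e5), min_size=6, max_size=6),
           st.floats(0.0, 12.0))
    def test_cropland_conserved(self, masses, slope):
        hist = np.array(masses)
        out = consolidate_parcels(hist, EDGES, slope=slope)
        assert out.sum() == pytest.approx(hist.sum(), rel=1e-12, abs=1e-9)

    def test_large_scale_fraction_never_decreases(self, rng):
        for _ in range(100):
            hist = rng.uniform(0, 1000, 6)
            slope = rng.uniform(0, 12)
            before = large_scale_fraction(hist, EDGES)
            after = large_scale_fraction(consolidate_parcels(hist, EDGES, slope), EDGES)
            assert after >= before - 1e-12


class TestNRate:
    def test_unchanged_histogram_keeps_rate(self):
        hist = np.array([10.0, 20.0, 30.0, 5.0, 1.0, 0.0])
        assert n_rate_after(hist, hist, EDGES, 150.0, -0.3) == 150.0

    def test_power_law_multiplier(self):
        """Size ratio 4 at elasticity -0.27 -> multiplier 4^-0.27 = 0.688."""
        edges = [0.0, 1.0, 2.0, 4.0, 8.0]
        before = np.array([0.0, 100.0, 0.0, 0.0])   # mean 1.5 ha
        after = np.array([0.0, 0.0, 0.0, 100.0])    # mean 6.0 ha
        rate = n_rate_after(before, after, edges, 100.0, -0.27)
        assert rate == pytest.approx(100.0 * 4.0 ** -0.27, rel=1e-9)
        assert rate == pytest.approx(68.78, abs=0.01)

    def test_zero_elasticity_no_change(self):
        before = np.array([0.0, 0.0, 100.0, 0.0, 0.0, 0.0])
        after = np.array([0.0, 0.0, 0.0, 0.0, 100.0, 0.0])
        assert n_rate_after(before, after, EDGES, 123.0, 0.0) == pytest.approx(123.0)

    def test_positive_elasticity_rejected(self):
        hist = np.array([0.0, 0.0, 100.0, 0.0, 0.0, 0.0])
        with pytest.raises(DomainError):
            n_rate_after(hist, hist, EDGES, 100.0, 0.5)

    def test_floor_applies(self):
        before = np.array([100.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        after = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 100.0])
        rate = n_rate_after(before, after, EDGES, 100.0, -2.0, floor=80.0)
        assert rate == 80.0

    def test_empty_histogram_rejected(self):
        with pytest.raises(DomainError):
            mean_parcel_size(np.zeros(6), EDGES)


def _farm_frame(records):
    cols = ["farm_id", "cell_id", "farm_class"] + [f"heads_{s}" for s in SPECIES]
    rows = []
    for i, (cell, cls, swine) in enumerate(records):
        row = dict.fromkeys(cols, 0.0)
        row.update(farm_id=i, cell_id=cell, farm_class=cls, heads_swine=swine)
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


class TestReallocation:
    def test_proportional_split(self):
        farms = _farm_frame([(0, "free_range", 1000.0),
                             (0, "large_scale", 300.0),
                             (1, "large_scale", 100.0)])
        province = pd.Series({0: 0, 1: 0})
        out = reallocate_livestock(farms, province, reallocation_fraction=1.0)
        pu = farm_pig_units(out)
        assert pu[1] == pytest.approx(300.0 + 750.0)
        assert pu[2] == pytest.approx(100.0 + 250.0)
        assert pu[0] == pytest.approx(0.0)

    def test_no_free_range_unchanged(self):
        farms = _farm_frame([(0, "large_scale", 500.0)])
        out = reallocate_livestock(farms, pd.Series({0: 0}), 1.0)
        pd.testing.assert_frame_equal(out, farms)

    def test_new_farm_created_when_no_destination(self):
        farms = _farm_frame([(0, "free_range", 1000.0)])
        out = reallocate_livestock(farms, pd.Series({0: 0}), 1.0)
        assert (out["farm_class"] == "large_scale").sum() == 1
        assert farm_pig_units(out).sum() == pytest.approx(1000.0)

    def test_per_province_conservation_random(self, rng):
        records = []
        cell = 0
        for _ in range(200):
            cls = "free_range" if rng.random() < 0.6 else "large_scale"
            records.append((cell, cls, float(rng.uniform(10, 5000))))
            cell += 1
        farms = _farm_frame(records)
        province = pd.Series({c: c % 50 for c in range(cell)})
        out = reallocate_livestock(farms, province, 0.885)
        before = farm_pig_units(farms).groupby(farms["cell_id"].map(province)).sum()
        after = farm_pig_units(out).groupby(out["cell_id"].map(province)).sum()
        pd.testing.assert_series_equal(before, after, rtol=1e-12)


class TestTransitionRegion:
    def test_cropland_conserved(self, small_region, params):
        result = transition_region(small_region, params["transition"])
        before = small_region.cells["cropland_ha"].sum()
        after = result.fixture.cells["cropland_ha"].sum()
        assert after == pytest.approx(before, rel=1e-12)
        mass_after = result.fixture.cells[small_region.parcel_columns].sum().sum()
        assert mass_after == pytest.approx(before, rel=1e-9)

    def test_rates_never_increase(self, small_region, params):
        result = transition_region(small_region, params["transition"])
        assert (result.fixture.cells["n_rate"] <= small_region.cells["n_rate"] + 1e-9).all()

    def test_national_n_rate_reduction_calibration(self, default_region, params):
        """Mean N application rate falls by ~31% under full consolidation."""
        result = transition_region(default_region, params["transition"])
        assert result.n_rate_reduction_pct == pytest.approx(31.0, abs=2.0)

    def test_large_scale_livestock_share_after(self, default_region, params):
        result = transition_region(default_region, params["transition"])
        assert result.large_scale_pu_share_after == pytest.approx(0.928, abs=0.01)

    def test_pilot_mask_leaves_outside_unchanged(self, small_region, params):
        cells = small_region.cells
        mask = cells["is_pilot"].to_numpy(dtype=bool)
        result = transition_region(small_region, params["transition"], cell_mask=mask)
        outside = ~mask
        pd.testing.assert_frame_equal(
            result.fixture.cells.loc[outside, ["n_rate"] + small_region.parcel_columns],
            cells.loc[outside, ["n_rate"] + small_region.parcel_columns],
        )
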