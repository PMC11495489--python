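"""Smallholder -> large-scale transition rules.

Three deterministic rules stand in for the survey-based machinery of the
original national analysis:

* parcel consolidation: in cells flat enough for mechanization (slope <=
  6 degrees), all parcel mass below the 2 ha large-scale threshold merges
  into the smallest bin at or above it; cropland is conserved exactly,
* N application rate decline: a power law in the mean parcel size ratio
  with a calibrated (negative) elasticity and an agronomic floor,
* livestock reallocation: a configured fraction of free-range pig units in
  each province moves to that province's large-scale farms in proportion to
  existing capacity; pig-unit totals are conserved exactly per province.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ConfigurationError
from .synthetic_data import (SPECIES, RegionFixture, farm_pig_units,
                             parcel_bin_labels)

PIG_UNIT_FACTORS = {
    "swine": 1.0,
    "dairy_cattle": 10.0,
    "beef_cattle": 5.0,
    "sheep_goats": 1.0 / 3.0,
    "layer_poultry": 1.0 / 15.0,
    "broiler_poultry": 1.0 / 60.0,
}


class DomainError(ValueError):
    pass


class AllocationError(RuntimeError):
    """A province has free-range animals but no feasible destination farm."""


def pig_units(heads_by_species: dict[str, float],
              factors: dict[str, float] | None = None) -> float:
    """Convert per-species head counts to pig units."""
    factors = PIG_UNIT_FACTORS if factors is None else factors
    total = 0.0
    for species, heads in heads_by_species.items():
        if species not in factors:
            raise DomainError(f"unknown species {species!r}")
        if heads < 0:
            raise DomainError(f"negative head count for {species}")
        total += heads * factors[species]
    return total


def consolidate_parcels(histogram: np.ndarray, bin_edges, slope: float,
                        slope_max: float = 6.0,
                        size_threshold: float = 2.0) -> np.ndarray:
    """Merge sub-threshold parcel mass into the first bin >= the threshold.

    Cells steeper than ``slope_max`` are left unchanged. Total cropland mass
    is conserved exactly.
    """
    if slope < 0:
        raise DomainError("slope must be non-negative")
    hist = np.asarray(histogram, dtype=float).copy()
    edges = np.asarray(bin_edges, dtype=float)
    if hist.shape[0] != edges.shape[0] - 1:
        raise DomainError("histogram length must match bin count")
    if slope > slope_max:
        return hist
    lower = edges[:-1]
    upper = edges[1:]
    small = upper <= size_threshold
    candidates = np.nonzero(lower >= size_threshold)[0]
    if candidates.size == 0:
        raise DomainError("no parcel bin at or above the consolidation threshold")
    target = candidates[0]
    moved = hist[small].sum()
    hist[small] = 0.0
    hist[target] += moved
    return hist


def large_scale_fraction(histogram: np.ndarray, bin_edges,
                         size_threshold: float = 2.0) -> float:
    """Cropland mass share in parcels at or above the size threshold."""
    hist = np.asarray(histogram, dtype=float)
    lower = np.asarray(bin_edges, dtype=float)[:-1]
    total = hist.sum()
    if total <= 0:
        return 0.0
    return float(hist[lower >= size_threshold].sum() / total)


def mean_parcel_size(histogram: np.ndarray, bin_edges) -> float:
    """Area-per-parcel mean implied by the histogram (mass / implied count)."""
    hist = np.asarray(histogram, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mass = hist.sum()
    if mass <= 0:
        raise DomainError("empty histogram has no mean parcel size")
    counts = np.divide(hist, mids, out=np.zeros_like(hist), where=mids > 0)
    n = counts.sum()
    if n <= 0:
        raise DomainError("zero implied parcel count")
    return float(mass / n)


def n_rate_after(hist_before: np.ndarray, hist_after: np.ndarray, bin_edges,
                 old_rate: float, elasticity: float,
                 floor: float = 0.0) -> float:
    """Post-consolidation N rate: old_rate x (size ratio)^elasticity, floored."""
    if elasticity > 0:
        raise DomainError("elasticity must be <= 0 (larger farms use less N/ha)")
    if np.allclose(hist_before, hist_after):
        return old_rate
    ratio = mean_parcel_size(hist_after, bin_edges) / mean_parcel_size(hist_before, bin_edges)
    return max(old_rate * ratio ** elasticity, floor)


def reallocate_livestock(farms: pd.DataFrame, province_of_cell: pd.Series,
                         reallocation_fraction: float = 1.0) -> pd.DataFrame:
    """Move free-range pig units to large-scale farms within each province.

    The moved fraction is distributed proportionally to existing large-farm
    capacity; provinces with free-range animals but no large farm get one new
    farm point at the cell with the most free-range pig units. Per-province
    pig-unit totals are conserved exactly.
    """
    if not (0.0 <= reallocation_fraction <= 1.0):
        raise DomainError("reallocation_fraction must be in [0, 1]")
    farms = farms.copy().reset_index(drop=True)
    if len(farms) == 0 or reallocation_fraction == 0.0:
        return farms
    province = farms["cell_id"].map(province_of_cell)
    if province.isna().any():
        raise DomainError("every farm must map to a province")
    pu = farm_pig_units(farms)
    head_cols = [f"heads_{s}" for s in SPECIES]
    new_rows = []
    next_id = int(farms["farm_id"].max()) + 1 if len(farms) else 0
    for prov, idx in farms.groupby(province).groups.items():
        idx = list(idx)
        sub = farms.loc[idx]
        fr_idx = [i for i in idx if sub.loc[i, "farm_class"] == "free_range"]
        ls_idx = [i for i in idx if sub.loc[i, "farm_class"] == "large_scale"]
        movable = float(pu.loc[fr_idx].sum()) * reallocation_fraction
        if movable <= 0:
            continue
        # shrink free-range farms uniformly
        for i in fr_idx:
            farms.loc[i, head_cols] = farms.loc[i, head_cols].to_numpy(dtype=float) * (
                1.0 - reallocation_fraction
            )
        if ls_idx:
            capacity = pu.loc[ls_idx].to_numpy(dtype=float)
            if capacity.sum() <= 0:
                raise AllocationError(
                    f"province {prov} has zero large-farm capacity for reallocation"
                )
            added = movable * capacity / capacity.sum()
            for i, extra in zip(ls_idx, added):
                heads = farms.loc[i, head_cols].to_numpy(dtype=float)
                species_i = int(np.argmax(heads))
                factor = PIG_UNIT_FACTORS[SPECIES[species_i]]
                heads[species_i] += extra / factor
                farms.loc[i, head_cols] = heads
        else:
            # seed one new large farm at the densest free-range cell
            donor = pu.loc[fr_idx].idxmax()
            row = {"farm_id": next_id, "cell_id": farms.loc[donor, "cell_id"],
                   "farm_class": "large_scale"}
            for col in head_cols:
                row[col] = 0.0
            row["heads_swine"] = movable  # swine factor is 1
            new_rows.append(row)
            next_id += 1
    if new_rows:
        farms = pd.concat([farms, pd.DataFrame(new_rows)], ignore_index=True)
    return farms


@dataclass(frozen=True)
class TransitionResult:
    fixture: RegionFixture
    mean_n_rate_before: float
    mean_n_rate_after: float
    large_scale_crop_fraction_before: float
    large_scale_crop_fraction_after: float
    large_scale_pu_share_before: float
    large_scale_pu_share_after: float

    @property
    def n_rate_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.mean_n_rate_after / self.mean_n_rate_before)


def transition_region(fixture: RegionFixture, params: dict,
                      cell_mask: np.ndarray | None = None) -> TransitionResult:
    """Apply the full transition to a region (optionally only inside a mask).

    ``cell_mask`` is a boolean array over cell ids; provinces intersecting the
    mask get livestock reallocation (the pilot mask is province-aligned so
    this is exact).
    """
    edges = np.asarray(fixture.parcel_size_bins)
    labels = parcel_bin_labels(edges)
    cells = fixture.cells.copy()
    n_cells = len(cells)
    if cell_mask is None:
        cell_mask = np.ones(n_cells, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)

    hist = cells[labels].to_numpy(dtype=float)
    slope = cells["slope_deg"].to_numpy(dtype=float)
    crop = cells["cropland_ha"].to_numpy(dtype=float)
    rate = cells["n_rate"].to_numpy(dtype=float)

    slope_max = float(params["slope_max_deg"])
    threshold = float(params["size_threshold_ha"])
    elasticity = float(params["n_rate_elasticity"])
    floor = float(params["n_rate_floor"])

    lsf_before = _weighted_lsf(hist, edges, crop, threshold)
    mean_rate_before = float(np.sum(rate * crop) / crop.sum()) if crop.sum() else 0.0

    new_hist = hist.copy()
    new_rate = rate.copy()
    for i in range(n_cells):
        if not cell_mask[i] or crop[i] <= 0:
            continue
        merged = consolidate_parcels(hist[i], edges, slope[i], slope_max, threshold)
        new_rate[i] = n_rate_after(hist[i], merged, edges, rate[i], elasticity, floor)
        new_hist[i] = merged

    cells[labels] = new_hist
    cells["n_rate"] = new_rate

    province = fixture.cells.set_index("cell_id")["province_id"]
    masked_provinces = set(fixture.cells.loc[cell_mask, "province_id"].unique())
    in_scope = fixture.farms["cell_id"].map(province).isin(masked_provinces)
    farms_in = fixture.farms[in_scope]
    farms_out = fixture.farms[~in_scope]
    moved = reallocate_livestock(farms_in, province,
                                 float(params["reallocation_fraction"]))
    farms = pd.concat([moved, farms_out], ignore_index=True)

    new_fixture = RegionFixture(cells=cells, farms=farms,
                                monthly_met=fixture.monthly_met,
                                daily_met=fixture.daily_met,
                                parcel_size_bins=fixture.parcel_size_bins)
    lsf_after = _weighted_lsf(new_hist, edges, crop, threshold)
    mean_rate_after = float(np.sum(new_rate * crop) / crop.sum()) if crop.sum() else 0.0
    return TransitionResult(
        fixture=new_fixture,
        mean_n_rate_before=mean_rate_before,
        mean_n_rate_after=mean_rate_after,
        large_scale_crop_fraction_before=lsf_before,
        large_scale_crop_fraction_after=lsf_after,
        large_scale_pu_share_before=_pu_share(fixture.farms),
        large_scale_pu_share_after=_pu_share(farms),
    )


def _weighted_lsf(hist: np.ndarray, edges, crop: np.ndarray, threshold: float) -> float:
    lower = np.asarray(edges)[:-1]
    mass_large = hist[:, lower >= threshold].sum()
    total = hist.sum()
    return float(mass_large / total) if total > 0 else 0.0


def _pu_share(farms: pd.DataFrame) -> float:
    if len(farms) == 0:
        return 0.0
    pu = farm_pig_units(farms)
    total = pu.sum()
    if total <= 0:
        return 0.0
    return float(pu[farms["farm_class"] == "large_scale"].sum() / total)
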