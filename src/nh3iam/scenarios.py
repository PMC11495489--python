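"""Abatement scenario construction.

Each scenario is a set of measures applied to the gridded inventory:

* demand-side measures (reduced food loss and waste) scale sectoral activity
  directly, before anything else,
* technology measures follow the adoption-weighted reduction rule
  ``E_r = (1 - a) E + a E (1 - eta) = E (1 - a eta)``, applied measure by
  measure, with the per-cell adoption ``a`` resolved from the farm structure
  (smallholder vs large-scale rates weighted by the local large-scale share),
* large-scale regimes first rebuild the inventory from the transitioned farm
  structure (consolidated parcels, reduced N rates, reallocated livestock),
  optionally only inside the pilot-province mask.

Reductions are always reported against the untransitioned baseline field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from .params import ConfigurationError, EmissionFactors
from .farm_transition import transition_region
from .inventory import (FARM_CLASSES, LIVESTOCK_SECTORS, SECTORS,
                        DomainError, cell_pig_units_by_class, total_inventory)
from .synthetic_data import RegionFixture, parcel_bin_labels


def apply_measure(emissions, adoption, eta):
    """Adoption-weighted emission after one measure: E (1 - a eta)."""
    emissions = np.asarray(emissions, dtype=float)
    adoption = np.asarray(adoption, dtype=float)
    eta_arr = np.asarray(eta, dtype=float)
    if np.any(emissions < 0):
        raise DomainError("emissions must be non-negative")
    if np.any((adoption < 0) | (adoption > 1)):
        raise DomainError("adoption must lie in [0, 1]")
    if np.any((eta_arr < 0) | (eta_arr > 1)):
        raise DomainError("mitigation efficiency must lie in [0, 1]")
    return emissions * (1.0 - adoption * eta_arr)


def combine_measures(etas) -> float:
    """Multiplicative-survival combined efficiency: 1 - prod(1 - eta_i)."""
    combined = 1.0
    for eta in etas:
        if not (0.0 <= eta <= 1.0):
            raise DomainError(f"eta out of [0, 1]: {eta}")
        combined *= 1.0 - eta
    return 1.0 - combined


@dataclass
class ScenarioResult:
    name: str
    baseline: xr.DataArray        # E, pre-intervention
    emissions: xr.DataArray       # E_r
    masks: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def reduction_pct(self, mask: np.ndarray | None = None,
                      sectors=None) -> float:
        return reduction_summary_value(self.baseline, self.emissions, mask, sectors)


def reduction_summary_value(baseline: xr.DataArray, emissions: xr.DataArray,
                            mask: np.ndarray | None = None, sectors=None) -> float:
    """Percentage reduction 100 (1 - sum E_r / sum E) over a mask and sectors."""
    b, e = baseline, emissions
    if sectors is not None:
        b = b.sel(sector=list(sectors))
        e = e.sel(sector=list(sectors))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DomainError("empty region mask")
        m = xr.DataArray(mask, dims=("row", "col"))
        b = b.where(m, 0.0)
        e = e.where(m, 0.0)
    denom = float(b.sum())
    if denom <= 0:
        raise DomainError("baseline emissions are zero over the mask")
    return 100.0 * (1.0 - float(e.sum()) / denom)


def region_masks(fixture: RegionFixture) -> dict[str, np.ndarray]:
    """Standard report masks: national and the pilot provinces."""
    return {
        "national": np.ones(fixture.shape, dtype=bool),
        "pilot": fixture.grid("is_pilot").astype(bool),
    }


def _crop_adoption_grid(fixture: RegionFixture, adoption: dict) -> np.ndarray:
    """Per-cell crop adoption: smallholder/large rates mixed by the local
    large-scale parcel-mass share."""
    edges = np.asarray(fixture.parcel_size_bins)
    labels = parcel_bin_labels(edges)
    hist = fixture.cells[labels].to_numpy(dtype=float)
    lower = edges[:-1]
    total = hist.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lsf = np.where(total > 0, hist[:, lower >= 2.0].sum(axis=1) / total, 0.0)
    a = (adoption["crop_smallholder"] * (1.0 - lsf)
         + adoption["crop_large"] * lsf)
    return _to_grid(fixture, a)


def _livestock_adoption_grids(fixture: RegionFixture, factors: EmissionFactors,
                              adoption: dict) -> dict[str, np.ndarray]:
    """Per-sector adoption grids for livestock stages.

    Housing and storage are exclusively large-scale; grazing exclusively
    free-range; spreading mixes both classes, weighted by each class's
    spreading emission in the cell.
    """
    pu = cell_pig_units_by_class(fixture)
    a_small = adoption["livestock_smallholder"]
    a_large = adoption["livestock_large"]
    frac = factors.stage_fractions
    grids = {}
    for sector in LIVESTOCK_SECTORS:
        w = np.zeros((len(pu), 2))  # emission weight per class
        for j, cls in enumerate(FARM_CLASSES):
            w[:, j] = pu[cls].to_numpy() * frac.get(cls, {}).get(sector, 0.0)
        tot = w.sum(axis=1)
        a_cls = np.array([a_small, a_large])
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(tot > 0, (w * a_cls).sum(axis=1) / np.where(tot > 0, tot, 1.0),
                         a_small)
        grids[sector] = _to_grid(fixture, a)
    return grids


def _to_grid(fixture: RegionFixture, per_cell: np.ndarray) -> np.ndarray:
    out = np.zeros(fixture.shape)
    out[fixture.cells["row"].to_numpy(), fixture.cells["col"].to_numpy()] = per_cell
    return out


def apply_measures_to_field(field: xr.DataArray, fixture: RegionFixture,
                            factors: EmissionFactors, catalog: dict,
                            measure_ids, adoption: dict) -> xr.DataArray:
    """Apply a measure list (demand-side first, then technology) to a field."""
    unknown = [m for m in measure_ids if m not in catalog]
    if unknown:
        raise ConfigurationError(f"unknown measure id(s): {unknown}")
    out = field.copy(deep=True)
    measures = {m: catalog[m] for m in measure_ids}
    crop_adoption = _crop_adoption_grid(fixture, adoption)
    live_adoption = _livestock_adoption_grids(fixture, factors, adoption)

    for phase_demand in (True, False):
        for mid, spec in measures.items():
            if bool(spec.get("demand_side", False)) != phase_demand:
                continue
            eta = float(spec["eta"])
            for sector in spec["sectors"]:
                if sector not in SECTORS:
                    raise ConfigurationError(f"measure {mid} targets unknown sector {sector}")
                if sector == "other" and not phase_demand:
                    raise ConfigurationError(
                        f"measure {mid}: technology measures apply only to "
                        "agricultural sectors")
                sel = out.sel(sector=sector).values  # (row, col, month)
                if phase_demand:
                    a = 1.0  # demand-side measures scale activity outright
                elif sector == "fertilizer":
                    a = crop_adoption[:, :, None]
                else:
                    a = live_adoption[sector][:, :, None]
                out.loc[{"sector": sector}] = apply_measure(sel, a, eta)
    return out


def build_scenario(name: str, fixture: RegionFixture, baseline: xr.DataArray,
                   factors: EmissionFactors, params: dict) -> ScenarioResult:
    """Build one named scenario from the full parameter set."""
    scen_defs = params["scenarios"]
    if name not in scen_defs:
        raise ConfigurationError(f"unknown scenario {name!r}")
    spec = scen_defs[name]
    catalog = params["measures"]
    adoption = params["adoption_rates"]
    masks = region_masks(fixture)

    if spec.get("regime", "current") == "large_scale":
        mask_name = spec.get("region_mask", "all")
        cell_mask = None
        if mask_name == "pilot":
            pilot_grid = masks["pilot"]
            cell_mask = pilot_grid[fixture.cells["row"].to_numpy(),
                                   fixture.cells["col"].to_numpy()]
        transition = transition_region(fixture, params["transition"], cell_mask)
        work_fixture = transition.fixture
        work_field = total_inventory(work_fixture, factors)
    else:
        work_fixture = fixture
        work_field = baseline

    reduced = apply_measures_to_field(work_field, work_fixture, factors,
                                      catalog, spec.get("measures", []), adoption)
    # measures and transition may only reduce; numerical guard for the bound
    reduced = xr.DataArray(np.minimum(reduced.values, baseline.values),
                           dims=baseline.dims, coords=baseline.coords,
                           name=baseline.name, attrs=baseline.attrs)
    return ScenarioResult(name=name, baseline=baseline, emissions=reduced, masks=masks)


def build_all_scenarios(fixture: RegionFixture, baseline: xr.DataArray,
                        factors: EmissionFactors, params: dict) -> dict[str, ScenarioResult]:
    return {name: build_scenario(name, fixture, baseline, factors, params)
            for name in params["scenarios"]}


def reduction_table(fixture: RegionFixture, baseline: xr.DataArray,
                    factors: EmissionFactors, params: dict,
                    results: dict[str, ScenarioResult] | None = None) -> pd.DataFrame:
    """Scenario/measure reduction table: rows = scenarios and single measures,
    columns = region masks, values = combined reduction (%)."""
    masks = region_masks(fixture)
    if results is None:
        results = build_all_scenarios(fixture, baseline, factors, params)
    rows = {}
    for name, res in results.items():
        rows[name] = {m: res.reduction_pct(mask) for m, mask in masks.items()}
    adoption = params["adoption_rates"]
    for mid in params["measures"]:
        single = apply_measures_to_field(baseline, fixture, factors,
                                         params["measures"], [mid], adoption)
        rows[f"measure:{mid}"] = {
            m: reduction_summary_value(baseline, single, mask)
            for m, mask in masks.items()
        }
    frame = pd.DataFrame(rows).T
    return frame.round(1)
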