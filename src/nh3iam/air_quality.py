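"""Reduced-form inorganic aerosol response to NH3 emissions.

A one-box steady state per grid cell replaces chemical-transport modelling:
local gas concentration = emission flux / dilution velocity, plus a single
regional background term. Inorganic PM2.5 then follows sulfate-first
neutralization with a temperature/RH-dependent ammonium nitrate equilibrium:

* NH3 neutralizes sulfate first (up to 2 mol NH4+ per mol SO42-; below that
  demand the aerosol is ammonium bisulfate-like and all NH3 is particulate),
* remaining NH3 and HNO3 form NH4NO3 only while their mixing-ratio product
  exceeds the dissociation constant Kp(T, RH), ln Kp linear in 1/T with a
  deliquescence reduction above the DRH.

This preserves the NH3-rich/NH3-poor regime distinction that drives the
non-linear PM2.5 response to NH3 cuts, the control-efficiency metric, the
polluted-day statistics, and the sub-grid heterogeneity experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .inventory import DomainError, SECTORS
from .synthetic_data import DAYS_IN_MONTH, DAY_MONTH, MONTHS, RegionFixture

MW_NH3 = 17.031
MW_HNO3 = 63.01
MW_SO4 = 96.06
MW_NH4 = 18.039
MW_NO3 = 62.004
R_GAS = 8.314  # J/mol/K
P_ATM = 101325.0  # Pa


def dissociation_constant(t_k, rh, params: dict) -> np.ndarray:
    """NH4NO3 dissociation constant Kp in ppb^2 at (T, RH)."""
    t_k = np.asarray(t_k, dtype=float)
    rh = np.asarray(rh, dtype=float)
    ln_kp = params["kp_a"] - params["kp_b"] / t_k - params["kp_c"] * np.log(t_k / 298.0)
    kp = np.exp(ln_kp)
    drh = params["deliquescence_rh"]
    wet = np.clip((rh - drh) / (1.0 - drh), 0.0, 1.0)
    factor = np.clip(1.0 - params["rh_kp_reduction"] * wet, 0.05, 1.0)
    return kp * factor


@dataclass
class AerosolState:
    """Gas/particle partition of one air parcel (all in ug/m3)."""

    nh3_gas: np.ndarray
    hno3_gas: np.ndarray
    sulfate: np.ndarray
    nh4: np.ndarray
    no3: np.ndarray
    pm25_inorganic: np.ndarray
    t_k: np.ndarray
    rh: np.ndarray

    @property
    def total_n_ug_mol(self) -> np.ndarray:
        """Total reduced nitrogen in umol/m3 (gas NH3 + particulate NH4)."""
        return self.nh3_gas / MW_NH3 + self.nh4 / MW_NH4

    @property
    def total_nitrate_ug_mol(self) -> np.ndarray:
        return self.hno3_gas / MW_HNO3 + self.no3 / MW_NO3


def equilibrium_pm(total_nh3, sulfate, total_nitrate, t_k, rh,
                   params: dict | None = None) -> AerosolState:
    """Partition total NH3 / sulfate / total nitrate into gas and particle.

    Inputs are ug/m3: ``total_nh3`` as NH3, ``sulfate`` as SO4^2-,
    ``total_nitrate`` as HNO3-equivalent. Conserves total reduced N and
    total nitrate exactly.
    """
    if params is None:
        from .params import default_params
        params = default_params()["air_quality"]
    total_nh3 = np.asarray(total_nh3, dtype=float)
    sulfate = np.asarray(sulfate, dtype=float)
    total_nitrate = np.asarray(total_nitrate, dtype=float)
    t_k = np.asarray(t_k, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(total_nh3 < 0) or np.any(sulfate < 0) or np.any(total_nitrate < 0):
        raise DomainError("concentrations must be non-negative")
    if np.any((t_k < 230.0) | (t_k > 330.0)):
        raise DomainError("temperature outside the physical range 230-330 K")

    nh3_mol = total_nh3 / MW_NH3            # umol/m3
    so4_mol = sulfate / MW_SO4
    tn_mol = total_nitrate / MW_HNO3

    # step 1: sulfate neutralization, up to 2 NH4 per SO4
    nh4_sulfate = np.minimum(nh3_mol, 2.0 * so4_mol)
    free_nh3 = nh3_mol - nh4_sulfate

    # step 2: NH4NO3 formation while the mixing-ratio product exceeds Kp
    kp = dissociation_constant(t_k, rh, params)
    ppb_per_umol = R_GAS * t_k / P_ATM * 1e3  # a mixing ratio is mass-independent
    a = free_nh3 * ppb_per_umol
    b = tn_mol * ppb_per_umol
    # solve (a - x)(b - x) = kp for the condensed amount x (in ppb)
    s = a + b
    x = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * (a * b - kp), 0.0)))
    x = np.clip(x, 0.0, np.minimum(a, b))
    x = np.where(a * b > kp, x, 0.0)
    nh4no3_mol = x / ppb_per_umol

    nh4_mol = nh4_sulfate + nh4no3_mol
    no3_mol = nh4no3_mol
    nh3_gas_mol = nh3_mol - nh4_mol
    hno3_mol = tn_mol - no3_mol

    nh4 = nh4_mol * MW_NH4
    no3 = no3_mol * MW_NO3
    pm_inorganic = sulfate + nh4 + no3
    return AerosolState(
        nh3_gas=nh3_gas_mol * MW_NH3,
        hno3_gas=hno3_mol * MW_HNO3,
        sulfate=sulfate,
        nh4=nh4,
        no3=no3,
        pm25_inorganic=pm_inorganic,
        t_k=t_k,
        rh=rh,
    )


# ---------------------------------------------------------------------------
# gridded response
# ---------------------------------------------------------------------------

def _pop_density_norm(fixture: RegionFixture) -> np.ndarray:
    pop = fixture.grid("population")
    peak = pop.max()
    return pop / peak if peak > 0 else pop


def ambient_fields(fixture: RegionFixture, params: dict) -> xr.Dataset:
    """Monthly sulfate, total nitrate and non-inorganic PM fields (ug/m3)."""
    dens = _pop_density_norm(fixture)
    month = np.arange(1, MONTHS + 1)
    summer = np.cos(2 * np.pi * (month - 7) / 12)
    so4 = ((params["sulfate_base"] + params["sulfate_pop_scale"] * dens)[:, :, None]
           * (1.0 + params["sulfate_summer_amplitude"] * summer[None, None, :]))
    tn = ((params["nitrate_base"] + params["nitrate_pop_scale"] * dens)[:, :, None]
          * (1.0 - params["nitrate_winter_amplitude"] * summer[None, None, :]))
    other = ((params["pm_other_base"] + params["pm_other_pop_scale"] * dens)[:, :, None]
             * (1.0 - params["pm_other_winter_amplitude"] * summer[None, None, :]))
    coords = {"row": np.arange(dens.shape[0]), "col": np.arange(dens.shape[1]),
              "month": month}
    return xr.Dataset(
        {"sulfate": (("row", "col", "month"), so4),
         "total_nitrate": (("row", "col", "month"), tn),
         "pm_other": (("row", "col", "month"), other)},
        coords=coords,
    )


def nh3_concentration(emission_field: xr.DataArray, fixture: RegionFixture,
                      params: dict) -> np.ndarray:
    """Monthly NH3 gas supply (ug/m3) from the one-box steady state."""
    area_m2 = fixture.cells["area_ha"].iloc[0] * 1e4 if len(fixture.cells) else 1.0
    total = emission_field.sum(dim="sector").values  # (row, col, month), Gg/month
    seconds = DAYS_IN_MONTH * 86400.0
    flux = total * 1e15 / seconds[None, None, :] / area_m2  # ug m-2 s-1
    local = flux / params["dilution_velocity"]
    regional = local.mean(axis=(0, 1), keepdims=True)
    return (1.0 - params["background_mixing"]) * local + params["background_mixing"] * regional


def pm_response(baseline_field: xr.DataArray, scenario_field: xr.DataArray,
                fixture: RegionFixture, params: dict) -> xr.Dataset:
    """Monthly PM2.5 under baseline and scenario emissions, and their delta.

    Returns a Dataset with ``pm_baseline``, ``pm_scenario``, ``delta_pm``
    (ug/m3, dims row/col/month).
    """
    if baseline_field.shape != scenario_field.shape:
        raise DomainError("baseline and scenario fields must share the grid")
    amb = ambient_fields(fixture, params)
    t_k = fixture.monthly_met["t2m"].values + 273.15
    rh = fixture.monthly_met["rh"].values
    pm = {}
    for label, field in (("baseline", baseline_field), ("scenario", scenario_field)):
        nh3 = nh3_concentration(field, fixture, params)
        state = equilibrium_pm(nh3, amb["sulfate"].values,
                               amb["total_nitrate"].values, t_k, rh, params)
        pm[label] = state.pm25_inorganic + amb["pm_other"].values
    coords = dict(amb.coords)
    ds = xr.Dataset(
        {"pm_baseline": (("row", "col", "month"), pm["baseline"]),
         "pm_scenario": (("row", "col", "month"), pm["scenario"]),
         "delta_pm": (("row", "col", "month"), pm["baseline"] - pm["scenario"])},
        coords=coords,
    )
    ds.attrs["units"] = "ug/m3"
    return ds


def weighted_summary(response: xr.Dataset, fixture: RegionFixture,
                     mask: np.ndarray | None = None) -> dict[str, float]:
    """Annual population- and area-weighted PM summaries over a mask."""
    pop = fixture.grid("population")
    if mask is None:
        mask = np.ones_like(pop, dtype=bool)
    annual_b = response["pm_baseline"].mean(dim="month").values
    annual_s = response["pm_scenario"].mean(dim="month").values
    w_pop = np.where(mask, pop, 0.0)
    w_area = mask.astype(float)
    out = {}
    for wname, w in (("pop", w_pop), ("area", w_area)):
        wsum = w.sum()
        pb = float((annual_b * w).sum() / wsum)
        ps = float((annual_s * w).sum() / wsum)
        out[f"pm_baseline_{wname}"] = pb
        out[f"pm_scenario_{wname}"] = ps
        out[f"delta_pm_{wname}"] = pb - ps
        out[f"pm_reduction_pct_{wname}"] = 100.0 * (pb - ps) / pb if pb > 0 else 0.0
    return out


def control_efficiency(pct_pm_reduction: float, pct_nh3_reduction: float) -> float:
    """PM2.5 control efficiency: % PM2.5 decrease per % NH3 decrease."""
    if pct_nh3_reduction <= 0:
        raise DomainError("NH3 reduction must be positive")
    return round(pct_pm_reduction / pct_nh3_reduction, 2)


def daily_pm_series(response_var: xr.DataArray, fixture: RegionFixture) -> np.ndarray:
    """Daily PM2.5 (row, col, day): monthly mean scaled by the stagnation
    multiplier from the daily meteorology."""
    stag = fixture.daily_met["stagnation"].values
    monthly = response_var.values[:, :, DAY_MONTH]
    return monthly * stag


def polluted_day_frequency(daily_pm: np.ndarray, threshold: float = 150.0) -> int:
    """Count of (cell, day) entries strictly above the threshold."""
    daily_pm = np.asarray(daily_pm, dtype=float)
    if daily_pm.size == 0:
        raise DomainError("empty daily PM series")
    return int((daily_pm > threshold).sum())


def polluted_day_change_pct(baseline_days: int, scenario_days: int) -> float:
    if baseline_days <= 0:
        raise DomainError("no polluted days in the baseline")
    return 100.0 * (1.0 - scenario_days / baseline_days)


def subgrid_experiment(livestock_flux: float, uniform_flux: float,
                       sulfate: float, total_nitrate: float,
                       t_k: float, rh: float, params: dict,
                       k_values=None, deposition_velocity: float | None = None) -> pd.DataFrame:
    """5-km box heterogeneity experiment inside one coarse cell.

    Livestock NH3 flux (ug m-2 s-1, coarse-cell mean) is packed into ``k`` of
    ``n_boxes`` boxes; within each box, NH3 above the local stoichiometric
    saturation deposits at ``deposition_velocity`` in competition with the
    local ventilation. Surviving NH3 from all boxes mixes before the
    coarse-cell equilibrium, so with zero deposition the result is exactly
    the uniform case. Returns the mean PM2.5 and the percentage
    underestimation of the livestock PM contribution relative to uniform.
    """
    sub = params["subgrid"]
    n_boxes = int(sub["n_boxes"])
    if k_values is None:
        k_values = [n_boxes, 25, 4, 1]
    v_dep = sub["deposition_velocity"] if deposition_velocity is None else deposition_velocity
    v_loc = sub["local_dilution_velocity"]
    v_coarse = params["dilution_velocity"]

    # local saturation: NH3 demand of sulfate + nitrate at box scale (ug/m3)
    demand_mol = 2.0 * sulfate / MW_SO4 + total_nitrate / MW_HNO3
    c_sat = demand_mol * MW_NH3 * sub["saturation_margin"]

    def surviving_flux(k: int) -> float:
        if not (1 <= k <= n_boxes):
            raise DomainError(f"k must be in [1, {n_boxes}]")
        per_box = livestock_flux * n_boxes / k + uniform_flux
        c_local = per_box / v_loc
        excess = max(0.0, c_local - c_sat)
        retained = min(c_local, c_sat) + excess * v_loc / (v_loc + v_dep)
        flux_out = retained * v_loc
        # unoccupied boxes carry only the uniform background
        c_bg = uniform_flux / v_loc
        excess_bg = max(0.0, c_bg - c_sat)
        retained_bg = min(c_bg, c_sat) + excess_bg * v_loc / (v_loc + v_dep)
        flux_bg = retained_bg * v_loc
        return (k * flux_out + (n_boxes - k) * flux_bg) / n_boxes

    def coarse_pm(mean_flux: float) -> float:
        nh3 = mean_flux / v_coarse
        state = equilibrium_pm(nh3, sulfate, total_nitrate, t_k, rh, params)
        return float(state.pm25_inorganic)

    pm_no_livestock = coarse_pm(surviving_flux_background(uniform_flux, c_sat, v_loc, v_dep))
    records = []
    pm_uniform = coarse_pm(surviving_flux(n_boxes))
    delta_uniform = pm_uniform - pm_no_livestock
    for k in k_values:
        pm_k = coarse_pm(surviving_flux(k))
        delta_k = pm_k - pm_no_livestock
        under = 0.0
        if delta_uniform > 0:
            under = 100.0 * (delta_uniform - delta_k) / delta_uniform
        records.append({"k_boxes": k, "pm25_mean": pm_k,
                        "underestimation_pct": under})
    return pd.DataFrame.from_records(records)


def surviving_flux_background(uniform_flux: float, c_sat: float,
                              v_loc: float, v_dep: float) -> float:
    c_bg = uniform_flux / v_loc
    excess = max(0.0, c_bg - c_sat)
    return (min(c_bg, c_sat) + excess * v_loc / (v_loc + v_dep)) * v_loc
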