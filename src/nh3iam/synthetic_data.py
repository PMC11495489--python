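"""Seeded synthetic study region standing in for the national datasets.

The generator emulates the statistical structure the downstream analysis
relies on, not real geography: a rectangular grid of cells with spatially
autocorrelated cropland, livestock and population hotspots; provinces from a
nearest-seed tessellation; a pilot subset of provinces covering ~21% of the
land area but a configurable majority of agricultural activity; per-cell
parcel-size histograms, terrain slope, N application rates; point-source
livestock farms split into free-range and large-scale classes; and monthly
plus daily meteorology for seasonal allocation and polluted-day statistics.

Cell (0, 0) is the north-west corner; indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, stats

from .params import ConfigurationError, RegionConfig

MONTHS = 12
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
N_DAYS = int(DAYS_IN_MONTH.sum())
#: month index (0-based) for each day of the year
DAY_MONTH = np.repeat(np.arange(MONTHS), DAYS_IN_MONTH)

SPECIES = ("swine", "dairy_cattle", "beef_cattle", "sheep_goats",
           "layer_poultry", "broiler_poultry")
CAUSES = ("copd", "lung_cancer", "ihd", "stroke")


def parcel_bin_labels(edges) -> list[str]:
    return [f"parcel_ha_{lo:g}_{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]


def parcel_bin_midpoints(edges) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class RegionFixture:
    """In-memory synthetic region: cell table, farm table, meteorology."""

    cells: pd.DataFrame
    farms: pd.DataFrame
    monthly_met: xr.Dataset
    daily_met: xr.Dataset
    parcel_size_bins: tuple[float, ...]

    @property
    def shape(self) -> tuple[int, int]:
        if len(self.cells) == 0:
            return (0, 0)
        return (int(self.cells["row"].max()) + 1, int(self.cells["col"].max()) + 1)

    @property
    def parcel_columns(self) -> list[str]:
        return parcel_bin_labels(self.parcel_size_bins)

    def grid(self, column: str) -> np.ndarray:
        """A cell-table column reshaped onto the (row, col) grid."""
        n_rows, n_cols = self.shape
        out = np.zeros((n_rows, n_cols))
        out[self.cells["row"].to_numpy(), self.cells["col"].to_numpy()] = (
            self.cells[column].to_numpy()
        )
        return out

    @classmethod
    def empty(cls, parcel_size_bins=(0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0)) -> "RegionFixture":
        bins = tuple(float(b) for b in parcel_size_bins)
        cell_cols = _cell_columns(bins)
        farm_cols = _farm_columns()
        return cls(
            cells=pd.DataFrame(columns=cell_cols),
            farms=pd.DataFrame(columns=farm_cols),
            monthly_met=xr.Dataset(),
            daily_met=xr.Dataset(),
            parcel_size_bins=bins,
        )


def _cell_columns(bins) -> list[str]:
    return (
        ["cell_id", "row", "col", "province_id", "is_pilot", "area_ha",
         "cropland_ha", "slope_deg", "n_rate", "population"]
        + [f"mortality_{c}" for c in CAUSES]
        + parcel_bin_labels(bins)
    )


def _farm_columns() -> list[str]:
    return ["farm_id", "cell_id", "farm_class"] + [f"heads_{s}" for s in SPECIES]


def _smooth_field(rng: np.random.Generator, shape, passes: int, size: int = 5) -> np.ndarray:
    """White noise box-blurred into a spatially autocorrelated [0, 1] field."""
    field = rng.random(shape)
    for _ in range(passes):
        field = ndimage.uniform_filter(field, size=size, mode="nearest")
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (field - lo) / (hi - lo)


def _scale_to_share(raw: np.ndarray, pilot: np.ndarray, total: float,
                    share: float, cap: np.ndarray | None = None) -> np.ndarray:
    """Scale a non-negative field so it sums to ``total`` with the pilot cells
    carrying ``share`` of it, optionally respecting a per-cell cap."""
    out = raw.astype(float).copy()
    targets = {True: share * total, False: (1.0 - share) * total}
    for flag, target in targets.items():
        mask = pilot == flag
        if cap is not None and cap[mask].sum() < target:
            raise ConfigurationError(
                "cropland_total_ha: per-cell caps cannot accommodate the "
                "configured national total (grid too small for the target)"
            )
        group_sum = out[mask].sum()
        if group_sum <= 0:
            if target > 0:
                out[mask] = target / max(mask.sum(), 1)
        else:
            out[mask] *= target / group_sum
        if cap is not None:
            # Push mass clipped by the cap back onto uncapped cells.
            for _ in range(25):
                over = np.minimum(out, cap)
                deficit = target - over[mask].sum()
                if deficit <= 1e-9 * max(target, 1.0):
                    out[mask] = over[mask]
                    break
                room = (cap - over)[mask]
                free = room > 1e-12
                if not free.any():
                    out[mask] = over[mask]
                    break
                add = np.zeros_like(room)
                weights = over[mask][free] + 1e-12
                add[free] = deficit * weights / weights.sum()
                new = over[mask] + add
                out[mask] = new
    return out


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(q, cdf, v))


def _parcel_mass_shares(config: RegionConfig) -> np.ndarray:
    """Cropland mass share per parcel bin from a truncated log-normal.

    Parcel *counts* follow LN(ln median, sigma); the area-weighted (mass)
    distribution is then LN(ln median + sigma^2, sigma). Shares are CDF
    differences over the configured bin edges, renormalized over the
    truncated range so they sum to one.
    """
    mu = np.log(config.parcel_lognorm_median) + config.parcel_lognorm_sigma**2
    dist = stats.lognorm(s=config.parcel_lognorm_sigma, scale=np.exp(mu))
    edges = np.asarray(config.parcel_size_bins)
    cdf = dist.cdf(edges)
    shares = np.diff(cdf)
    return shares / shares.sum()


def generate_region(config: RegionConfig, seed: int | None = None) -> RegionFixture:
    """Generate a deterministic synthetic region for a given (config, seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    shape = (config.n_rows, config.n_cols)
    n_cells = config.n_rows * config.n_cols
    rows, cols = np.divmod(np.arange(n_cells), config.n_cols)

    # --- provinces: nearest-seed tessellation -------------------------------
    seed_rows = rng.uniform(0, config.n_rows, config.n_provinces)
    seed_cols = rng.uniform(0, config.n_cols, config.n_provinces)
    d2 = (rows[:, None] - seed_rows[None, :]) ** 2 + (cols[:, None] - seed_cols[None, :]) ** 2
    province_id = d2.argmin(axis=1)

    # --- autocorrelated intensity fields ------------------------------------
    passes = config.smoothing_passes
    hotspot = _smooth_field(rng, shape, passes) ** 2  # skewed: few strong hotspots
    crop_raw = (0.7 * hotspot + 0.3 * _smooth_field(rng, shape, passes)).ravel()
    live_raw = (0.6 * hotspot + 0.4 * _smooth_field(rng, shape, passes) ** 2).ravel()
    pop_raw = (0.6 * hotspot + 0.4 * _smooth_field(rng, shape, passes)).ravel()
    nrate_field = _smooth_field(rng, shape, passes).ravel()

    # --- pilot provinces: densest until the area target is met --------------
    if config.pilot_provinces is not None:
        pilot_set = set(config.pilot_provinces)
    else:
        density = np.zeros(config.n_provinces)
        counts = np.zeros(config.n_provinces)
        np.add.at(density, province_id, crop_raw + live_raw)
        np.add.at(counts, province_id, 1.0)
        with np.errstate(invalid="ignore"):
            density = np.where(counts > 0, density / np.maximum(counts, 1), 0.0)
        pilot_set, area = set(), 0
        for pid in np.argsort(density)[::-1]:
            if area / n_cells >= config.pilot_area_target:
                break
            pilot_set.add(int(pid))
            area += int(counts[pid])
    is_pilot = np.isin(province_id, sorted(pilot_set))

    # --- scale fields to national totals and the pilot activity share -------
    cap = np.full(n_cells, config.cell_area_ha * config.cropland_fraction_range[1])
    cropland = _scale_to_share(crop_raw, is_pilot, config.cropland_total_ha,
                               config.pilot_emission_share, cap=cap)
    floor = config.cell_area_ha * config.cropland_fraction_range[0]
    cropland = np.maximum(cropland, floor)
    cropland *= config.cropland_total_ha / cropland.sum()
    pig_units = _scale_to_share(live_raw, is_pilot, config.livestock_total_pig_units,
                                config.pilot_emission_share)
    population = pop_raw * config.population_total / pop_raw.sum()

    # --- slope, calibrated to the cropland-weighted exceedance target -------
    slope = rng.lognormal(mean=0.0, sigma=config.slope_lognorm_sigma, size=n_cells)
    q = _weighted_quantile(slope, cropland, 1.0 - config.slope_exceedance_target)
    slope *= config.slope_threshold_deg / q

    # --- N application rate: smooth variation, cropland-weighted mean -------
    n_rate = 1.0 + config.n_rate_rel_spread * (2.0 * nrate_field - 1.0)
    n_rate *= config.mean_n_rate / (np.sum(n_rate * cropland) / cropland.sum())

    # --- parcel histograms ---------------------------------------------------
    shares = _parcel_mass_shares(config)
    parcel_mass = cropland[:, None] * shares[None, :]

    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "row": rows,
        "col": cols,
        "province_id": province_id,
        "is_pilot": is_pilot.astype(int),
        "area_ha": np.full(n_cells, config.cell_area_ha),
        "cropland_ha": cropland,
        "slope_deg": slope,
        "n_rate": n_rate,
        "population": population,
    })
    for cause in CAUSES:
        cells[f"mortality_{cause}"] = config.baseline_mortality[cause]
    for j, label in enumerate(parcel_bin_labels(config.parcel_size_bins)):
        cells[label] = parcel_mass[:, j]

    farms = _generate_farms(rng, config, pig_units)

    monthly_met = _monthly_met(rng, config)
    daily_met = _daily_met(rng, config, monthly_met)

    return RegionFixture(
        cells=cells,
        farms=farms,
        monthly_met=monthly_met,
        daily_met=daily_met,
        parcel_size_bins=config.parcel_size_bins,
    )


def _threshold_pu(config: RegionConfig) -> dict[str, float]:
    # Default large-scale head thresholds expressed in pig units; kept local to
    # farm generation (the transition module owns the authoritative config).
    heads = {"swine": 500, "dairy_cattle": 100, "beef_cattle": 200,
             "sheep_goats": 1500, "layer_poultry": 7500, "broiler_poultry": 30000}
    factors = {"swine": 1.0, "dairy_cattle": 10.0, "beef_cattle": 5.0,
               "sheep_goats": 1 / 3, "layer_poultry": 1 / 15, "broiler_poultry": 1 / 60}
    return {s: heads[s] * factors[s] for s in SPECIES}


def _generate_farms(rng: np.random.Generator, config: RegionConfig,
                    pig_units: np.ndarray) -> pd.DataFrame:
    """One aggregate free-range point per occupied cell plus large-scale
    point-source farms; pig-unit totals conserved exactly."""
    factors = {"swine": 1.0, "dairy_cattle": 10.0, "beef_cattle": 5.0,
               "sheep_goats": 1 / 3, "layer_poultry": 1 / 15, "broiler_poultry": 1 / 60}
    thresholds = _threshold_pu(config)
    species = list(SPECIES)
    shares = np.array([config.species_pu_shares[s] for s in species])

    records: list[dict] = []
    farm_id = 0
    for cell_id, pu in enumerate(pig_units):
        if pu <= 0:
            continue
        fr_pu = pu * config.free_range_fraction
        ls_pu = pu - fr_pu
        ls_left = ls_pu
        cell_large: list[dict] = []
        if ls_pu > 0:
            n_farms = max(1, int(round(ls_pu / config.typical_large_farm_pu)))
            splits = rng.dirichlet(np.full(n_farms, 4.0)) * ls_pu
            for part in splits:
                sp = species[rng.choice(len(species), p=shares)]
                if part < thresholds[sp]:
                    sp = "swine"  # lowest pig-unit threshold
                if part < thresholds[sp]:
                    continue  # too small for any large-scale class
                rec = {"farm_id": farm_id, "cell_id": cell_id, "farm_class": "large_scale"}
                for s in species:
                    rec[f"heads_{s}"] = part / factors[sp] if s == sp else 0.0
                cell_large.append(rec)
                farm_id += 1
                ls_left -= part
        records.extend(cell_large)
        fr_total = fr_pu + ls_left  # residual sub-threshold mass stays free-range
        if fr_total > 0:
            if config.free_range_fraction == 0.0 and cell_large:
                # no free-range class allowed: fold the residual into the
                # largest point source (still above its class threshold)
                rec = cell_large[-1]
                for s in species:
                    if rec[f"heads_{s}"] > 0:
                        rec[f"heads_{s}"] += fr_total / factors[s]
                        break
            elif config.free_range_fraction > 0.0:
                rec = {"farm_id": farm_id, "cell_id": cell_id, "farm_class": "free_range"}
                for s, share in zip(species, shares):
                    rec[f"heads_{s}"] = fr_total * share / factors[s]
                records.append(rec)
                farm_id += 1
    farms = pd.DataFrame.from_records(records, columns=_farm_columns())
    return farms


def _monthly_met(rng: np.random.Generator, config: RegionConfig) -> xr.Dataset:
    met = config.met
    n_rows, n_cols = config.n_rows, config.n_cols
    month = np.arange(1, MONTHS + 1)
    seasonal = np.cos(2 * np.pi * (month - 7) / 12)
    lat = (2.0 * np.arange(n_rows) / max(n_rows - 1, 1) - 1.0)  # -1 north .. +1 south
    t2m = (met["t_mean_c"]
           + met["t_lat_amplitude_c"] * lat[:, None, None]
           + met["t_seasonal_amplitude_c"] * seasonal[None, None, :])
    t2m = np.broadcast_to(t2m, (n_rows, n_cols, MONTHS)).copy()
    rh_pert = 0.05 * (2 * _smooth_field(rng, (n_rows, n_cols), config.smoothing_passes) - 1)
    rh = np.clip(met["rh_mean"] + met["rh_seasonal_amplitude"] * seasonal[None, None, :]
                 + rh_pert[:, :, None], 0.2, 0.95)
    return xr.Dataset(
        {
            "t2m": (("row", "col", "month"), t2m, {"units": "degC"}),
            "rh": (("row", "col", "month"), rh, {"units": "1"}),
        },
        coords={"row": np.arange(n_rows), "col": np.arange(n_cols), "month": month},
    )


def _daily_met(rng: np.random.Generator, config: RegionConfig,
               monthly: xr.Dataset) -> xr.Dataset:
    """Daily temperature and ventilation as monthly mean + AR(1) anomalies.

    The synoptic anomaly is regional (shared across cells) with a smooth
    per-cell amplitude; the ventilation multiplier is a unit-mean lognormal
    of the same anomaly, so stagnation episodes are spatially coherent.
    """
    met = config.met
    phi, sd = met["daily_ar1"], met["daily_t_sd_c"]
    innov = rng.normal(0.0, 1.0, N_DAYS)
    z = np.empty(N_DAYS)
    z[0] = innov[0]
    for d in range(1, N_DAYS):
        z[d] = phi * z[d - 1] + np.sqrt(1 - phi**2) * innov[d]
    amp = 0.8 + 0.4 * _smooth_field(rng, (config.n_rows, config.n_cols),
                                    config.smoothing_passes)
    t_monthly = monthly["t2m"].values[:, :, DAY_MONTH]
    t_daily = t_monthly + sd * amp[:, :, None] * z[None, None, :]
    sigma = met["daily_ventilation_sigma"]
    # stagnation multiplier: >1 on stagnant (warm-anomaly) days, unit mean
    stag = np.exp(sigma * amp[:, :, None] * z[None, None, :]
                  - 0.5 * (sigma * amp[:, :, None]) ** 2)
    return xr.Dataset(
        {
            "t2m_daily": (("row", "col", "day"), t_daily, {"units": "degC"}),
            "stagnation": (("row", "col", "day"), stag, {"units": "1"}),
        },
        coords={"row": np.arange(config.n_rows), "col": np.arange(config.n_cols),
                "day": np.arange(1, N_DAYS + 1)},
    )


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(fixture: RegionFixture, directory: str | Path) -> dict[str, Path]:
    """Write the fixture as cells.csv, farms.csv and fields.nc (NetCDF3).

    Round-trips losslessly through :func:`read_fixture`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create fixture directory {directory}: {exc}") from exc
    paths = {
        "cells": directory / "cells.csv",
        "farms": directory / "farms.csv",
        "fields": directory / "fields.nc",
    }
    fixture.cells.to_csv(paths["cells"], index=False)
    fixture.farms.to_csv(paths["farms"], index=False)
    fields = xr.merge([fixture.monthly_met, fixture.daily_met])
    fields.attrs["parcel_size_bins"] = list(fixture.parcel_size_bins)
    fields.to_netcdf(paths["fields"], engine="scipy")
    return paths


def read_fixture(directory: str | Path) -> RegionFixture:
    """Read a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    cells = pd.read_csv(directory / "cells.csv")
    farms = pd.read_csv(directory / "farms.csv")
    if "farm_class" in farms.columns:
        farms["farm_class"] = farms["farm_class"].astype(object)
    with xr.open_dataset(directory / "fields.nc", engine="scipy") as ds:
        fields = ds.load()
    bins = tuple(float(b) for b in np.atleast_1d(fields.attrs.get(
        "parcel_size_bins", [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0])))
    monthly_vars = [v for v in fields.data_vars if "month" in fields[v].dims]
    daily_vars = [v for v in fields.data_vars if "day" in fields[v].dims]
    monthly = fields[monthly_vars] if monthly_vars else xr.Dataset()
    daily = fields[daily_vars] if daily_vars else xr.Dataset()
    return RegionFixture(cells=cells, farms=farms, monthly_met=monthly,
                         daily_met=daily, parcel_size_bins=bins)


def farm_pig_units(farms: pd.DataFrame) -> pd.Series:
    """Pig units per farm from the per-species head columns."""
    factors = {"swine": 1.0, "dairy_cattle": 10.0, "beef_cattle": 5.0,
               "sheep_goats": 1 / 3, "layer_poultry": 1 / 15, "broiler_poultry": 1 / 60}
    if len(farms) == 0:
        return pd.Series(dtype=float)
    total = sum(farms[f"heads_{s}"].astype(float) * f for s, f in factors.items())
    return total
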