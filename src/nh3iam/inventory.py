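"""Gridded, seasonal, sectoral NH3 emission inventory with Monte Carlo CIs.

Emissions follow an emission-factor x activity formulation:

* fertilizer: applied N (rate x cropland) x volatilization fraction,
* livestock: pig units x N excretion x per-stage volatilization fraction,
  with farm-class-specific stage sets (free-range animals have no housing or
  storage stages),
* other: a single aggregate non-agricultural term allocated by population.

NH3-N is converted to NH3 with the molar mass ratio 17/14. The monthly
allocation of each agricultural sector is modulated exponentially by the
local temperature anomaly and renormalized, which yields the observed
summer-maximum seasonality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .params import ConfigurationError, EmissionFactors
from .synthetic_data import MONTHS, RegionFixture, farm_pig_units

NH3_PER_N = 17.0 / 14.0
KG_PER_GG = 1.0e6

SECTORS = (
    "fertilizer",
    "livestock_housing",
    "livestock_storage",
    "livestock_spreading",
    "livestock_grazing",
    "other",
)
LIVESTOCK_SECTORS = SECTORS[1:5]
FARM_CLASSES = ("free_range", "large_scale")


class DomainError(ValueError):
    """Raised for physically invalid operation inputs."""


def monthly_modulation(weights: np.ndarray, temperature: np.ndarray,
                       sensitivity: float) -> np.ndarray:
    """Renormalized monthly weights modulated by the temperature anomaly.

    ``temperature`` may be (12,) or (..., 12); the anomaly is taken against
    the local annual mean so the annual total is preserved exactly.
    """
    weights = np.asarray(weights, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    anom = temperature - temperature.mean(axis=-1, keepdims=True)
    w = weights * np.exp(sensitivity * anom)
    return w / w.sum(axis=-1, keepdims=True)


def fertilizer_emissions(n_rate: float, cropland: float, ef: float,
                         monthly_weights, temperature,
                         temperature_sensitivity: float = 0.0) -> np.ndarray:
    """Per-month NH3 mass (kg) from fertilizer application on one cell.

    Annual total is exactly ``n_rate * cropland * ef * 17/14``.
    """
    if n_rate < 0:
        raise DomainError(f"negative N application rate: {n_rate}")
    if not (0.0 <= ef <= 1.0):
        raise DomainError(f"fertilizer EF must be in [0, 1], got {ef}")
    weights = np.asarray(monthly_weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise DomainError("monthly weights must sum to 1")
    annual = n_rate * cropland * ef * NH3_PER_N
    w = monthly_modulation(weights, np.asarray(temperature, float), temperature_sensitivity)
    return annual * w


def livestock_emissions(pig_units: float, excretion_n: float,
                        stage_fractions: dict[str, float], farm_class: str,
                        monthly_weights=None, temperature=None,
                        temperature_sensitivity: float = 0.0) -> dict[str, np.ndarray]:
    """Per-stage, per-month NH3 mass (kg) for one farm or cell aggregate.

    Stage emission = pig_units x excretion_n x stage_fraction x 17/14; free
    range farms carry no housing/storage stages.
    """
    if farm_class not in FARM_CLASSES:
        raise DomainError(f"unknown farm class {farm_class!r}")
    if pig_units < 0:
        raise DomainError("pig units must be non-negative")
    if farm_class == "free_range":
        banned = {"livestock_housing", "livestock_storage"} & set(stage_fractions)
        if banned:
            raise DomainError(f"free-range farms cannot emit from {sorted(banned)}")
    if monthly_weights is None:
        monthly_weights = np.full(MONTHS, 1.0 / MONTHS)
    if temperature is None:
        temperature = np.zeros(MONTHS)
    w = monthly_modulation(np.asarray(monthly_weights, float),
                           np.asarray(temperature, float), temperature_sensitivity)
    out = {}
    for stage, frac in stage_fractions.items():
        annual = pig_units * excretion_n * frac * NH3_PER_N
        out[stage] = annual * w
    return out


def cell_pig_units_by_class(fixture: RegionFixture) -> pd.DataFrame:
    """Pig units per (cell, farm_class), indexed by cell_id."""
    farms = fixture.farms
    n_cells = len(fixture.cells)
    out = pd.DataFrame(0.0, index=np.arange(n_cells), columns=list(FARM_CLASSES))
    if len(farms) == 0:
        return out
    pu = farm_pig_units(farms)
    grouped = pu.groupby([farms["cell_id"], farms["farm_class"]]).sum()
    for (cell_id, cls), val in grouped.items():
        out.loc[cell_id, cls] = val
    return out


def total_inventory(fixture: RegionFixture, factors: EmissionFactors) -> xr.DataArray:
    """EmissionField: NH3 in Gg/month with dims (row, col, sector, month)."""
    n_rows, n_cols = fixture.shape
    cells = fixture.cells
    temp = fixture.monthly_met["t2m"].values  # (row, col, month)
    values = np.zeros((n_rows, n_cols, len(SECTORS), MONTHS))
    r = cells["row"].to_numpy()
    c = cells["col"].to_numpy()

    # fertilizer
    annual_fert = (cells["n_rate"].to_numpy() * cells["cropland_ha"].to_numpy()
                   * factors.fertilizer_ef * NH3_PER_N) / KG_PER_GG
    w_fert = monthly_modulation(np.asarray(factors.fertilizer_monthly_weights),
                                temp[r, c, :], factors.temperature_sensitivity)
    values[r, c, SECTORS.index("fertilizer"), :] = annual_fert[:, None] * w_fert

    # livestock, by class and stage; uniform base calendar, temperature-modulated
    pu = cell_pig_units_by_class(fixture)
    w_live = monthly_modulation(np.full(MONTHS, 1.0 / MONTHS), temp[r, c, :],
                                factors.temperature_sensitivity)
    for cls in FARM_CLASSES:
        stage_fracs = factors.stage_fractions.get(cls, {})
        class_pu = pu[cls].to_numpy()
        for stage, frac in stage_fracs.items():
            annual = class_pu * factors.excretion_n_kg_per_pu * frac * NH3_PER_N / KG_PER_GG
            values[r, c, SECTORS.index(stage), :] += annual[:, None] * w_live

    # other: aggregate non-agricultural term, population-allocated, aseasonal
    pop = cells["population"].to_numpy()
    pop_share = pop / pop.sum() if pop.sum() > 0 else np.zeros_like(pop)
    values[r, c, SECTORS.index("other"), :] = (
        factors.other_total_gg * pop_share[:, None] / MONTHS
    )

    field = xr.DataArray(
        values,
        dims=("row", "col", "sector", "month"),
        coords={"row": np.arange(n_rows), "col": np.arange(n_cols),
                "sector": list(SECTORS), "month": np.arange(1, MONTHS + 1)},
        name="nh3_emissions",
        attrs={"units": "Gg NH3/month"},
    )
    return field


def sector_totals(field: xr.DataArray) -> pd.Series:
    """Annual national totals per sector in Gg/yr."""
    return field.sum(dim=("row", "col", "month")).to_series()


def sector_shares(field: xr.DataArray) -> pd.Series:
    """Sector shares of the national annual total, in percent."""
    totals = sector_totals(field)
    return 100.0 * totals / totals.sum()


def national_total_tg(field: xr.DataArray) -> float:
    return float(field.sum()) / 1000.0


def seasonal_totals_tg(field: xr.DataArray) -> dict[str, float]:
    """Seasonal national totals (Tg): DJF / MAM / JJA / SON."""
    seasons = {"DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11)}
    return {name: float(field.sel(month=list(months)).sum()) / 1000.0
            for name, months in seasons.items()}


@dataclass(frozen=True)
class MonteCarloResult:
    mean: float       # Tg/yr
    p05: float
    p95: float
    n_draws: int
    seed: int

    def __post_init__(self):
        if not (self.p05 <= self.mean + 1e-12 and self.mean <= self.p95 + 1e-12):
            raise DomainError("Monte Carlo percentiles must bracket the mean")


def monte_carlo_ci(fixture: RegionFixture, factors: EmissionFactors,
                   n_draws: int = 1000, seed: int = 0,
                   field: xr.DataArray | None = None) -> MonteCarloResult:
    """90% CI of the national total under independent log-normal EF perturbation.

    Each factor group (fertilizer EF, N excretion, each volatilization stage,
    the non-agricultural aggregate) receives an independent median-1
    log-normal multiplier; by linearity the national total is re-assembled
    from perturbed sector subtotals, so draws are cheap.
    """
    if n_draws < 2:
        raise DomainError("n_draws must be at least 2")
    if field is None:
        field = total_inventory(fixture, factors)
    totals = sector_totals(field) / 1000.0  # Tg
    gsd = factors.uncertainty_gsd
    rng = np.random.default_rng(seed)

    def draw(g: float) -> np.ndarray:
        if g <= 1.0:
            return np.ones(n_draws)
        return rng.lognormal(mean=0.0, sigma=np.log(g), size=n_draws)

    m_fert = draw(gsd.get("fertilizer_ef", 1.0))
    m_excr = draw(gsd.get("excretion_n", 1.0))
    m_other = draw(gsd.get("other", 1.0))
    draws = totals["fertilizer"] * m_fert + totals["other"] * m_other
    for stage in LIVESTOCK_SECTORS:
        m_stage = draw(gsd.get("stage_fractions", 1.0))
        draws = draws + totals[stage] * m_excr * m_stage
    p05, p95 = np.percentile(draws, [5.0, 95.0])
    mean = float(draws.mean())
    return MonteCarloResult(mean=mean, p05=float(min(p05, mean)),
                            p95=float(max(p95, mean)), n_draws=n_draws, seed=seed)


def summary_frame(field: xr.DataArray) -> pd.DataFrame:
    """Sector summary (annual Gg, share %) as a tidy frame for reports."""
    totals = sector_totals(field)
    shares = sector_shares(field)
    return pd.DataFrame({"annual_gg": totals, "share_pct": shares})
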