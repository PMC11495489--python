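"""PM2.5-attributable mortality via the GEMM hazard-ratio curves.

The hazard ratio for each cause of death follows the log-linear-logistic
GEMM form

    HR(z) = exp( theta * log(z/alpha + 1) / (1 + exp(-(z - mu)/nu)) ),
    z = max(0, PM2.5 - counterfactual),

with a 2.4 ug/m3 counterfactual below which no excess risk is attributed.
Attributable deaths per cell and cause are
population x baseline rate x (1 - 1/HR); avoided deaths are differences of
attributable deaths between a reference and a scenario exposure surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inventory import DomainError
from .synthetic_data import CAUSES, RegionFixture


def gemm_hazard_ratio(pm, cause_params: dict, counterfactual: float = 2.4) -> np.ndarray:
    """GEMM hazard ratio at exposure ``pm`` (ug/m3) for one cause."""
    pm = np.asarray(pm, dtype=float)
    if not np.all(np.isfinite(pm)):
        raise DomainError("PM2.5 exposure must be finite")
    if np.any(pm < 0):
        raise DomainError("PM2.5 exposure must be non-negative")
    z = np.maximum(0.0, pm - counterfactual)
    theta = cause_params["theta"]
    alpha = cause_params["alpha"]
    mu = cause_params["mu"]
    nu = cause_params["nu"]
    log_term = np.log(z / alpha + 1.0)
    logistic = 1.0 / (1.0 + np.exp(-(z - mu) / nu))
    return np.exp(theta * log_term * logistic)


def attributable_deaths(pm_grid: np.ndarray, population: np.ndarray,
                        mortality_rates: dict[str, np.ndarray],
                        gemm_params: dict) -> pd.DataFrame:
    """Per-cause attributable deaths on the grid.

    Returns a frame with per-cause columns of deaths/yr per cell (flattened
    row-major) plus a ``baseline_<cause>`` column; rounding is left to report
    time.
    """
    pm = np.asarray(pm_grid, dtype=float).ravel()
    pop = np.asarray(population, dtype=float).ravel()
    if np.any(pop < 0):
        raise DomainError("population must be non-negative")
    if pm.shape != pop.shape:
        raise DomainError("PM and population grids are misaligned")
    counterfactual = gemm_params["counterfactual"]
    out = {}
    for cause in CAUSES:
        rate = np.asarray(mortality_rates[cause], dtype=float).ravel()
        if np.any(rate < 0):
            raise DomainError(f"negative baseline mortality rate for {cause}")
        if rate.shape != pm.shape:
            rate = np.full_like(pm, float(rate))
        hr = gemm_hazard_ratio(pm, gemm_params["causes"][cause], counterfactual)
        baseline = pop * rate
        out[f"baseline_{cause}"] = baseline
        out[f"attributable_{cause}"] = baseline * (1.0 - 1.0 / hr)
    return pd.DataFrame(out)


def mortality_table(pm_annual: np.ndarray, fixture: RegionFixture,
                    gemm_params: dict) -> pd.DataFrame:
    """Attributable-mortality table for a fixture and an annual PM surface."""
    rates = {c: fixture.grid(f"mortality_{c}").ravel() for c in CAUSES}
    pop = fixture.grid("population")
    return attributable_deaths(pm_annual, pop, rates, gemm_params)


def total_attributable(table: pd.DataFrame) -> float:
    cols = [f"attributable_{c}" for c in CAUSES]
    return float(table[cols].to_numpy().sum())


def avoided_deaths(reference: pd.DataFrame, scenario: pd.DataFrame) -> float:
    """Total avoided deaths/yr: reference minus scenario attributable deaths."""
    if reference.shape != scenario.shape or list(reference.columns) != list(scenario.columns):
        raise DomainError("mortality tables are misaligned")
    return total_attributable(reference) - total_attributable(scenario)
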