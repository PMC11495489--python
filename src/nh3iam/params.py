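"""Parameter loading and validation.

All tunable constants live in ``data/params.yml`` (shipped with the package)
and are loaded into plain nested dicts; user YAML files may override any
subset (deep merge). Light dataclass views are provided for the pieces with
invariants worth checking early.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented invariant."""


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_params() -> dict:
    """Load the packaged default parameter set as a nested dict."""
    text = resources.files("nh3iam.data").joinpath("params.yml").read_text()
    return yaml.safe_load(text)


def load_params(path: str | Path | None = None) -> dict:
    """Default parameters, deep-merged with an optional user YAML override."""
    params = default_params()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, Mapping):
            raise ConfigurationError(f"parameter file {path} must map keys to values")
        params = _deep_merge(params, override)
    return params


def scaled_region(block: Mapping[str, Any], n_rows: int, n_cols: int,
                  n_provinces: int | None = None) -> dict:
    """A coarser variant of a region block: fewer, larger cells covering the
    same national land area, so national totals stay attainable."""
    out = dict(block)
    old_cells = int(block["n_rows"]) * int(block["n_cols"])
    new_cells = n_rows * n_cols
    out.update(n_rows=n_rows, n_cols=n_cols,
               cell_area_ha=float(block["cell_area_ha"]) * old_cells / new_cells)
    if n_provinces is not None:
        out["n_provinces"] = n_provinces
        out["pilot_provinces"] = None
    return out


def _require_fraction(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)


@dataclass(frozen=True)
class RegionConfig:
    """Validated view of the ``region`` parameter block."""

    n_rows: int
    n_cols: int
    cell_area_ha: float
    n_provinces: int
    pilot_area_target: float
    pilot_emission_share: float
    cropland_total_ha: float
    cropland_fraction_range: tuple[float, float]
    slope_lognorm_sigma: float
    slope_exceedance_target: float
    slope_threshold_deg: float
    parcel_size_bins: tuple[float, ...]
    parcel_lognorm_median: float
    parcel_lognorm_sigma: float
    mean_n_rate: float
    n_rate_rel_spread: float
    livestock_total_pig_units: float
    free_range_fraction: float
    species_pu_shares: dict[str, float]
    typical_large_farm_pu: float
    population_total: float
    baseline_mortality: dict[str, float]
    met: dict[str, float]
    smoothing_passes: int
    seed: int
    pilot_provinces: tuple[int, ...] | None = None

    @classmethod
    def from_dict(cls, block: Mapping[str, Any]) -> "RegionConfig":
        b = dict(block)
        try:
            lo, hi = b["cropland_fraction_range"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError("cropland_fraction_range must be a [lo, hi] pair") from exc
        _require_fraction(lo, "cropland_fraction_range[0]")
        _require_fraction(hi, "cropland_fraction_range[1]")
        if lo > hi:
            raise ConfigurationError("cropland_fraction_range must be ordered lo <= hi")
        for name in ("pilot_area_target", "pilot_emission_share", "free_range_fraction"):
            _require_fraction(b[name], name)
        if b["cell_area_ha"] <= 0:
            raise ConfigurationError("cell_area_ha must be positive")
        if b["n_rows"] <= 0 or b["n_cols"] <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        bins = tuple(float(x) for x in b["parcel_size_bins"])
        if sorted(bins) != list(bins) or len(bins) < 2:
            raise ConfigurationError("parcel_size_bins must be a sorted edge list")
        shares = {k: float(v) for k, v in b["species_pu_shares"].items()}
        if abs(sum(shares.values()) - 1.0) > 1e-6:
            raise ConfigurationError("species_pu_shares must sum to 1")
        pilot = b.get("pilot_provinces")
        if pilot is not None:
            pilot = tuple(int(p) for p in pilot)
            if any(p < 0 or p >= b["n_provinces"] for p in pilot):
                raise ConfigurationError("pilot_provinces must be valid province ids")
        return cls(
            n_rows=int(b["n_rows"]),
            n_cols=int(b["n_cols"]),
            cell_area_ha=float(b["cell_area_ha"]),
            n_provinces=int(b["n_provinces"]),
            pilot_area_target=float(b["pilot_area_target"]),
            pilot_emission_share=float(b["pilot_emission_share"]),
            cropland_total_ha=float(b["cropland_total_ha"]),
            cropland_fraction_range=(float(lo), float(hi)),
            slope_lognorm_sigma=float(b["slope_lognorm_sigma"]),
            slope_exceedance_target=_require_fraction(
                b["slope_exceedance_target"], "slope_exceedance_target"
            ),
            slope_threshold_deg=float(b["slope_threshold_deg"]),
            parcel_size_bins=bins,
            parcel_lognorm_median=float(b["parcel_lognorm_median"]),
            parcel_lognorm_sigma=float(b["parcel_lognorm_sigma"]),
            mean_n_rate=float(b["mean_n_rate"]),
            n_rate_rel_spread=float(b["n_rate_rel_spread"]),
            livestock_total_pig_units=float(b["livestock_total_pig_units"]),
            free_range_fraction=float(b["free_range_fraction"]),
            species_pu_shares=shares,
            typical_large_farm_pu=float(b["typical_large_farm_pu"]),
            population_total=float(b["population_total"]),
            baseline_mortality={k: float(v) for k, v in b["baseline_mortality"].items()},
            met=dict(b["met"]),
            smoothing_passes=int(b.get("smoothing_passes", 4)),
            seed=int(b.get("seed", 0)),
            pilot_provinces=pilot,
        )


@dataclass(frozen=True)
class EmissionFactors:
    """Validated view of the ``emission_factors`` block."""

    fertilizer_ef: float
    fertilizer_monthly_weights: tuple[float, ...]
    excretion_n_kg_per_pu: float
    temperature_sensitivity: float
    stage_fractions: dict[str, dict[str, float]]
    other_total_gg: float
    uncertainty_gsd: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, block: Mapping[str, Any]) -> "EmissionFactors":
        b = dict(block)
        ef = _require_fraction(b["fertilizer_ef"], "fertilizer_ef")
        weights = tuple(float(w) for w in b["fertilizer_monthly_weights"])
        if len(weights) != 12:
            raise ConfigurationError("fertilizer_monthly_weights needs 12 entries")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("fertilizer_monthly_weights must sum to 1")
        stages = {
            cls_name: {k: _require_fraction(v, f"stage_fractions.{cls_name}.{k}") for k, v in d.items()}
            for cls_name, d in b["stage_fractions"].items()
        }
        for cls_name, d in stages.items():
            if sum(d.values()) > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"stage_fractions for {cls_name} sum above 1 (N conservation)"
                )
        return cls(
            fertilizer_ef=ef,
            fertilizer_monthly_weights=weights,
            excretion_n_kg_per_pu=float(b["excretion_n_kg_per_pu"]),
            temperature_sensitivity=float(b["temperature_sensitivity"]),
            stage_fractions=stages,
            other_total_gg=float(b["other_total_gg"]),
            uncertainty_gsd={k: float(v) for k, v in b.get("uncertainty_gsd", {}).items()},
        )
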