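"""Configured, logged, resumable pipeline over the analysis stages.

Stages: generate -> inventory -> transition -> scenario -> airq -> health ->
econ. Every stage writes its outputs plus a manifest (hash of the relevant
parameters, the stage seed and the upstream file hashes); a stage is skipped
when its manifest matches, so re-runs with an unchanged configuration are
no-ops. All randomness flows from the single top-level seed via named
substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import air_quality, econ, health, inventory, scenarios
from .farm_transition import transition_region
from .params import EmissionFactors, RegionConfig
from .synthetic_data import RegionFixture, generate_region, read_fixture, write_fixture

log = logging.getLogger("nh3iam")

STAGES = ("generate", "inventory", "transition", "scenario", "airq", "health", "econ")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Named deterministic substream seed, kept below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class Pipeline:
    """Orchestrates the full integrated assessment into an output directory."""

    def __init__(self, params: dict, out_dir: str | Path, seed: int = 42,
                 scenario_names: list[str] | None = None):
        self.params = params
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.scenario_names = scenario_names or list(params["scenarios"])
        self._fixture: RegionFixture | None = None
        self._baseline: xr.DataArray | None = None
        self._results: dict[str, scenarios.ScenarioResult] | None = None
        self._responses: dict[str, xr.Dataset] | None = None
        self._avoided: dict[str, float] | None = None

    # -- manifest helpers ----------------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.out / f"{stage}.manifest.json"

    def _fresh(self, stage: str, inputs_hash: str, outputs: list[Path]) -> bool:
        mpath = self._manifest_path(stage)
        if not mpath.exists():
            return False
        try:
            manifest = json.loads(mpath.read_text())
        except json.JSONDecodeError:
            return False
        if manifest.get("inputs_hash") != inputs_hash:
            return False
        for rec in manifest.get("outputs", []):
            p = Path(rec["path"])
            if not p.exists() or _hash_file(p) != rec["sha256"]:
                return False
        return all(p.exists() for p in outputs)

    def _write_manifest(self, stage: str, inputs_hash: str, outputs: list[Path]) -> None:
        manifest = {
            "stage": stage,
            "seed": stage_seed(self.seed, stage),
            "inputs_hash": inputs_hash,
            "outputs": [{"path": str(p), "sha256": _hash_file(p)} for p in outputs],
        }
        self._manifest_path(stage).write_text(json.dumps(manifest, indent=1, sort_keys=True))

    # -- stages ---------------------------------------------------------------

    def run_generate(self) -> RegionFixture:
        stage = "generate"
        fixture_dir = self.out / "fixture"
        outputs = [fixture_dir / n for n in ("cells.csv", "farms.csv", "fields.nc")]
        ihash = _hash_obj({"region": self.params["region"],
                           "seed": stage_seed(self.seed, stage)})
        if self._fresh(stage, ihash, outputs):
            log.info("generate: cached, skipping")
            if self._fixture is None:
                self._fixture = read_fixture(fixture_dir)
            return self._fixture
        log.info("generate: building synthetic region")
        try:
            config = RegionConfig.from_dict(self.params["region"])
            fixture = generate_region(config, seed=stage_seed(self.seed, stage))
            write_fixture(fixture, fixture_dir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, outputs)
        self._fixture = fixture
        return fixture

    def run_inventory(self) -> xr.DataArray:
        stage = "inventory"
        fixture = self.run_generate()
        outputs = [self.out / "inventory.nc", self.out / "sector_summary.csv",
                   self.out / "monte_carlo.json"]
        ihash = _hash_obj({
            "factors": self.params["emission_factors"],
            "seed": stage_seed(self.seed, stage),
            "fixture": [_hash_file(self.out / "fixture" / n)
                        for n in ("cells.csv", "farms.csv", "fields.nc")],
        })
        if self._fresh(stage, ihash, outputs):
            log.info("inventory: cached, skipping")
            if self._baseline is None:
                with xr.open_dataset(outputs[0], engine="scipy") as ds:
                    self._baseline = ds["nh3_emissions"].load()
            return self._baseline
        log.info("inventory: computing gridded NH3 emissions")
        try:
            factors = EmissionFactors.from_dict(self.params["emission_factors"])
            field = inventory.total_inventory(fixture, factors)
            field.to_dataset(name="nh3_emissions").to_netcdf(outputs[0], engine="scipy")
            inventory.summary_frame(field).to_csv(outputs[1])
            mc = inventory.monte_carlo_ci(fixture, factors, n_draws=1000,
                                          seed=stage_seed(self.seed, stage), field=field)
            seasons = inventory.seasonal_totals_tg(field)
            outputs[2].write_text(json.dumps({
                "total_tg": inventory.national_total_tg(field),
                "mean_tg": mc.mean, "p05_tg": mc.p05, "p95_tg": mc.p95,
                "n_draws": mc.n_draws, "seasonal_tg": seasons,
            }, indent=1, sort_keys=True))
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, outputs)
        self._baseline = field
        return field

    def run_transition(self) -> dict:
        stage = "transition"
        fixture = self.run_generate()
        out_json = self.out / "transition_summary.json"
        ihash = _hash_obj({"transition": self.params["transition"],
                           "fixture": _hash_file(self.out / "fixture" / "cells.csv")})
        if self._fresh(stage, ihash, [out_json]):
            log.info("transition: cached, skipping")
            return json.loads(out_json.read_text())
        log.info("transition: consolidating parcels, reallocating livestock")
        try:
            result = transition_region(fixture, self.params["transition"])
            summary = {
                "mean_n_rate_before": result.mean_n_rate_before,
                "mean_n_rate_after": result.mean_n_rate_after,
                "n_rate_reduction_pct": result.n_rate_reduction_pct,
                "large_scale_crop_fraction_before": result.large_scale_crop_fraction_before,
                "large_scale_crop_fraction_after": result.large_scale_crop_fraction_after,
                "large_scale_pu_share_before": result.large_scale_pu_share_before,
                "large_scale_pu_share_after": result.large_scale_pu_share_after,
            }
            out_json.write_text(json.dumps(summary, indent=1, sort_keys=True))
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, [out_json])
        return summary

    def _scenario_results(self) -> dict[str, scenarios.ScenarioResult]:
        if self._results is None:
            fixture = self.run_generate()
            baseline = self.run_inventory()
            factors = EmissionFactors.from_dict(self.params["emission_factors"])
            self._results = {
                name: scenarios.build_scenario(name, fixture, baseline, factors, self.params)
                for name in self.scenario_names
            }
        return self._results

    def run_scenario(self) -> Path:
        stage = "scenario"
        fixture = self.run_generate()
        baseline = self.run_inventory()
        table_path = self.out / "scenario_reductions.csv"
        nc_paths = [self.out / f"scenario_{name}.nc" for name in self.scenario_names]
        ihash = _hash_obj({
            "measures": self.params["measures"],
            "adoption": self.params["adoption_rates"],
            "scenarios": {k: self.params["scenarios"][k] for k in self.scenario_names},
            "transition": self.params["transition"],
            "inventory": _hash_file(self.out / "inventory.nc"),
        })
        if self._fresh(stage, ihash, nc_paths + [table_path]):
            log.info("scenario: cached, skipping")
            return table_path
        log.info("scenario: applying abatement measures")
        try:
            factors = EmissionFactors.from_dict(self.params["emission_factors"])
            results = self._scenario_results()
            for name, res in results.items():
                res.emissions.to_dataset(name="nh3_emissions").to_netcdf(
                    self.out / f"scenario_{name}.nc", engine="scipy")
            table = scenarios.reduction_table(fixture, baseline, factors,
                                              self.params, results)
            table.to_csv(table_path)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, nc_paths + [table_path])
        return table_path

    def _scenario_responses(self) -> dict[str, xr.Dataset]:
        if self._responses is None:
            fixture = self.run_generate()
            baseline = self.run_inventory()
            aq = self.params["air_quality"]
            self._responses = {
                name: air_quality.pm_response(baseline, res.emissions, fixture, aq)
                for name, res in self._scenario_results().items()
            }
        return self._responses

    def run_airq(self) -> Path:
        stage = "airq"
        self.run_scenario()
        fixture = self.run_generate()
        summary_path = self.out / "airq_summary.csv"
        nc_paths = [self.out / f"delta_pm_{name}.nc" for name in self.scenario_names]
        ihash = _hash_obj({
            "air_quality": self.params["air_quality"],
            "scenario_fields": [_hash_file(self.out / f"scenario_{n}.nc")
                                for n in self.scenario_names],
        })
        if self._fresh(stage, ihash, nc_paths + [summary_path]):
            log.info("airq: cached, skipping")
            return summary_path
        log.info("airq: computing PM2.5 response")
        try:
            aq = self.params["air_quality"]
            rows = []
            responses = self._scenario_responses()
            for name, response in responses.items():
                response.to_netcdf(self.out / f"delta_pm_{name}.nc", engine="scipy")
                summary = air_quality.weighted_summary(response, fixture)
                nh3_red = self._scenario_results()[name].reduction_pct()
                summary["nh3_reduction_pct"] = nh3_red
                summary["control_efficiency"] = air_quality.control_efficiency(
                    summary["pm_reduction_pct_pop"], nh3_red)
                base_days = air_quality.polluted_day_frequency(
                    air_quality.daily_pm_series(response["pm_baseline"], fixture),
                    aq["polluted_day_threshold"])
                scen_days = air_quality.polluted_day_frequency(
                    air_quality.daily_pm_series(response["pm_scenario"], fixture),
                    aq["polluted_day_threshold"])
                summary["polluted_days_baseline"] = base_days
                summary["polluted_days_scenario"] = scen_days
                summary["polluted_day_change_pct"] = (
                    air_quality.polluted_day_change_pct(base_days, scen_days)
                    if base_days else 0.0)
                rows.append(pd.Series(summary, name=name))
            pd.DataFrame(rows).to_csv(summary_path)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, nc_paths + [summary_path])
        return summary_path

    def run_health(self) -> Path:
        stage = "health"
        self.run_airq()
        fixture = self.run_generate()
        out_path = self.out / "health_summary.csv"
        ihash = _hash_obj({
            "gemm": self.params["gemm"],
            "deltas": [_hash_file(self.out / f"delta_pm_{n}.nc")
                       for n in self.scenario_names],
        })
        if self._fresh(stage, ihash, [out_path]):
            log.info("health: cached, skipping")
            df = pd.read_csv(out_path, index_col=0)
            self._avoided = df["avoided_deaths"].to_dict()
            return out_path
        log.info("health: GEMM attributable mortality")
        try:
            gemm = self.params["gemm"]
            responses = self._scenario_responses()
            first = next(iter(responses.values()))
            pm_base = first["pm_baseline"].mean(dim="month").values
            ref_table = health.mortality_table(pm_base, fixture, gemm)
            rows = []
            self._avoided = {}
            for name, response in responses.items():
                pm_scen = response["pm_scenario"].mean(dim="month").values
                scen_table = health.mortality_table(pm_scen, fixture, gemm)
                avoided = health.avoided_deaths(ref_table, scen_table)
                self._avoided[name] = avoided
                rows.append(pd.Series({
                    "attributable_baseline": health.total_attributable(ref_table),
                    "attributable_scenario": health.total_attributable(scen_table),
                    "avoided_deaths": avoided,
                }, name=name))
            pd.DataFrame(rows).to_csv(out_path)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, [out_path])
        return out_path

    def run_econ(self) -> Path:
        stage = "econ"
        self.run_health()
        ref_path = self.out / "cost_benefit_reference.csv"
        comp_path = self.out / "cost_benefit_computed.csv"
        ihash = _hash_obj({
            "econ": self.params["econ"],
            "health": _hash_file(self.out / "health_summary.csv"),
        })
        if self._fresh(stage, ihash, [ref_path, comp_path]):
            log.info("econ: cached, skipping")
            return ref_path
        log.info("econ: cost-benefit ledgers")
        try:
            ep = self.params["econ"]
            catalog = ep["catalog"]
            ref_ledgers, comp_ledgers = {}, {}
            for name in self.scenario_names:
                if name not in catalog:
                    continue
                ref_deaths = float(catalog[name]["reference_avoided_deaths"])
                ref_ledgers[name] = econ.build_ledger(name, ref_deaths, ep)
                comp_deaths = max(0.0, float(self._avoided.get(name, 0.0)))
                comp_ledgers[name] = econ.build_ledger(name, comp_deaths, ep)
            econ.table2_frame(ref_ledgers).to_csv(ref_path, index=False)
            econ.table2_frame(comp_ledgers).to_csv(comp_path, index=False)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        self._write_manifest(stage, ihash, [ref_path, comp_path])
        return ref_path

    def run_all(self) -> dict[str, Path]:
        """Run every stage; returns the primary output path per stage."""
        self.run_generate()
        self.run_inventory()
        self.run_transition()
        self.run_scenario()
        self.run_airq()
        self.run_health()
        self.run_econ()
        return {
            "fixture": self.out / "fixture",
            "inventory": self.out / "inventory.nc",
            "transition": self.out / "transition_summary.json",
            "scenario": self.out / "scenario_reductions.csv",
            "airq": self.out / "airq_summary.csv",
            "health": self.out / "health_summary.csv",
            "econ": self.out / "cost_benefit_reference.csv",
        }
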