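#!/usr/bin/env python
"""Build the synthetic study region and summarize its structure.

The region stands in for the national gridded datasets: autocorrelated
cropland/livestock/population hotspots, provinces with a high-density pilot
subset, parcel-size histograms, terrain slope, and meteorology. National
totals are calibrated to the 2016 accounts (134.9 Mha cropland, 1.6e9 pig
units, 197.8 kg N/ha mean application rate).
"""

from pathlib import Path

from nh3iam import load_params
from nh3iam.pipeline import Pipeline
from nh3iam.synthetic_data import farm_pig_units, read_fixture

OUT = Path("results/pipeline")


def main() -> None:
    params = load_params()
    pipe = Pipeline(params, OUT, seed=42)
    pipe.run_generate()
    fixture = read_fixture(OUT / "fixture")

    cells = fixture.cells
    pu = farm_pig_units(fixture.farms)
    fr = pu[fixture.farms["farm_class"] == "free_range"].sum()
    pilot = cells["is_pilot"] == 1
    w = cells["cropland_ha"]
    print(f"grid: {fixture.shape[0]} x {fixture.shape[1]} cells, "
          f"{cells['area_ha'].iloc[0]/1e4:.0f} kha per cell")
    print(f"cropland: {w.sum()/1e6:.1f} Mha "
          f"({100*w[cells.slope_deg > 6].sum()/w.sum():.1f}% on slopes > 6 deg)")
    print(f"livestock: {pu.sum()/1e9:.2f} billion pig units "
          f"({100*fr/pu.sum():.1f}% free-range)")
    print(f"mean N rate: {(cells.n_rate*w).sum()/w.sum():.1f} kg N/ha")
    print(f"pilot provinces: {100*pilot.mean():.1f}% of area, "
          f"{100*w[pilot].sum()/w.sum():.1f}% of cropland")
    print(f"fixture written to {OUT/'fixture'}")


if __name__ == "__main__":
    main()
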