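"""Fit the biome-climate model and map where past societies could live.

Simulates dated pollen sites whose biome labels follow a known multinomial
model of mean annual temperature and precipitation, refits that model,
reports classification accuracy and Cohen's kappa, projects per-slice biome
maps, and turns them into per-culture habitat maps via the association
table (hunter-gatherers retreat to the densest forest, metallurgical
societies spread over nearly everything).
"""

import numpy as np

from urheimat.biome import (classification_metrics, fit_multinomial,
                            load_society_biome_table, project_biome_map,
                            society_map)
from urheimat.simulate import (SimConfig, bayes_accuracy,
                               simulate_climate_series, simulate_pollen_sites)

cfg = SimConfig(seed=31)
grids = simulate_climate_series(cfg)
sites = simulate_pollen_sites(grids, cfg)
print(f"{len(sites)} dated pollen/land-cover sites across "
      f"{len(grids)} climate slices")

model = fit_multinomial(sites)
metrics = classification_metrics(model, sites)
print(f"\nbiome-climate model: accuracy {metrics['accuracy']:.2f}, "
      f"Cohen's kappa {metrics['cohen_kappa']:.3f}")
print(f"Bayes accuracy of the generating model: "
      f"{bayes_accuracy(grids, cfg):.2f} (the fitted model cannot beat this)")
for biome, acc in metrics["per_class_accuracy"].items():
    print(f"  {biome:9s} {acc:.2f}")

table = load_society_biome_table()
grid = grids[len(grids) // 2]
raster = project_biome_map(model, grid)
print(f"\nslice at {grid.time_bp:.0f} BP:")
for culture in ("HG", "N", "CA", "BA", "IA"):
    area = society_map(raster, model.classes, grid.time_bp, culture,
                       table).values.sum()
    print(f"  {culture:2s} habitat: {area:4d} of {np.prod(grid.shape)} cells")
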