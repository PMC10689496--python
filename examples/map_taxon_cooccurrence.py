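"""Map where a set of taxa could co-occur under a past climate.

Simulates a smooth two-variable climate grid and three taxa with nested
climatic niches, fits a MaxEnt suitability model per taxon from presence
and background points, binarizes each map at the maxSSS threshold and
multiplies the binary ranges.  The printed cell counts shrink as taxa are
intersected; the final map is the candidate co-occurrence area (the
homeland-search surface of the full pipeline).
"""

import numpy as np

from urheimat.niche import (binarize, cooccurrence, fit_maxent,
                            maxsss_threshold, project_suitability,
                            sample_background, suitability_of,
                            thin_one_per_pixel)
from urheimat.simulate import (SimConfig, SpeciesResponse,
                               simulate_climate_series,
                               simulate_taxon_occurrences)

cfg = SimConfig(seed=22)
cfg.climate.n_time_slices = 1
cfg.species.n_presences = 500
cfg.species.responses = {
    "broad": SpeciesResponse(8.0, 6.0, 1700.0, 600.0),
    "mid": SpeciesResponse(8.0, 4.5, 1700.0, 450.0),
    "narrow": SpeciesResponse(8.0, 3.5, 1700.0, 350.0),
}
grid = simulate_climate_series(cfg)[0]
background = sample_background(grid, 1000, seed=23)

binary_maps = []
for taxon in cfg.species.responses:
    occ = simulate_taxon_occurrences(grid, cfg, taxon)
    thinned = thin_one_per_pixel(occ.cells, grid, taxon)
    model = fit_maxent(thinned, background, grid)
    smap = project_suitability(model, grid)
    thr = maxsss_threshold(
        suitability_of(model, grid.climate_at(thinned.cells)),
        suitability_of(model, grid.climate_at(background.cells)))
    bmap = binarize(smap, thr)
    binary_maps.append(bmap)
    print(f"{taxon:7s}: {len(thinned.cells):3d} cells after thinning, "
          f"maxSSS threshold {thr:.3f}, range {bmap.values.sum()} cells")

co = cooccurrence(binary_maps)
print(f"\nco-occurrence of all three taxa: {co.values.sum()} of "
      f"{np.prod(grid.shape)} cells")
print("(ranges are nested by construction, so the intersection ~ the")
print(" narrowest taxon's range)")
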