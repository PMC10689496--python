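"""MaxEnt niche modelling, thresholding and range algebra."""

import numpy as np
import pytest

from urheimat.niche import (BinaryMap, ClimateGrid, MaxEntModel, OccurrenceSet,
                            SuitabilityMap, binarize, combine_period,
                            cooccurrence, fit_maxent, maxsss_threshold,
                            project_suitability, read_ascii_grid,
                            sample_background, suitability_of,
                            thin_one_per_pixel, write_ascii_grid)
from urheimat.simulate import (SimConfig, SpeciesResponse,
                               simulate_climate_series,
                               simulate_taxon_occurrences, true_suitability)


@pytest.fixture(scope="module")
def grid() -> ClimateGrid:
    cfg = SimConfig(seed=21)
    cfg.climate.n_time_slices = 1
    return simulate_climate_series(cfg)[0]


def test_thinning_cases(grid):
    points = np.array([[3, 4]] * 5 + [[5, 6]])
    occ = thin_one_per_pixel(points, grid)
    assert len(occ.cells) == 2
    assert occ.source_count == 6
    distinct = np.array([[1, 1], [2, 2], [3, 3]])
    assert len(thin_one_per_pixel(distinct, grid).cells) == 3
    with pytest.raises(ValueError, match="outside"):
        thin_one_per_pixel(np.array([[-5, -5]]), grid)


def test_thinning_matches_dedup_oracle(grid):
    rng = np.random.default_rng(0)
    points = rng.integers(0, 12, size=(300, 2))
    occ = thin_one_per_pixel(points, grid)
    oracle = sorted({(int(r), int(c)) for r, c in points})
    assert [tuple(p) for p in occ.cells] == oracle


def test_background_sampling(grid):
    n_valid = len(grid.valid_cells())
    occ = sample_background(grid, 1000, seed=1)
    assert len({tuple(c) for c in occ.cells}) == 1000
    assert np.array_equal(sample_background(grid, 1000, seed=1).cells, occ.cells)
    everything = sample_background(grid, n_valid, seed=2)
    assert len(everything.cells) == n_valid
    with pytest.raises(ValueError, match="background"):
        sample_background(grid, n_valid + 1, seed=3)


def test_maxent_null_model_is_flat(grid):
    """Presences drawn uniformly from the background leave ~no signal."""
    rng = np.random.default_rng(5)
    valid = grid.valid_cells()
    pres = OccurrenceSet("null", valid[rng.choice(len(valid), 200, replace=False)])
    bg = sample_background(grid, 800, seed=6)
    model = fit_maxent(pres, bg, grid)
    assert np.max(np.abs(model.weights)) < 0.1
    smap = project_suitability(model, grid)
    vals = smap.values[~np.isnan(smap.values)]
    assert vals.max() / vals.min() < 1.5
    assert np.std(vals) / np.mean(vals) < 0.05


def test_maxent_warm_decile_signal(grid):
    warm_cut = np.quantile(grid.mat, 0.9)
    cells = np.argwhere(grid.mat >= warm_cut)
    pres = OccurrenceSet("warm", cells[:150])
    bg = sample_background(grid, 800, seed=7)
    model = fit_maxent(pres, bg, grid)
    smap = project_suitability(model, grid)
    warm_mean = smap.values[grid.mat >= warm_cut].mean()
    assert warm_mean > np.nanmean(smap.values)


def test_maxent_objective_monotone(grid):
    cells = np.argwhere(grid.mat >= np.quantile(grid.mat, 0.8))
    pres = OccurrenceSet("warm", cells[:100])
    bg = sample_background(grid, 500, seed=8)
    model = fit_maxent(pres, bg, grid)
    trace = np.array(model.objective_trace)
    assert (np.diff(trace) <= 1e-9).all()


def test_maxent_rejects_degenerate_predictors():
    flat = ClimateGrid(mat=np.full((10, 10), 5.0), ap=np.full((10, 10), 100.0))
    pres = OccurrenceSet("x", np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5]]))
    bg = OccurrenceSet("bg", np.argwhere(np.ones((10, 10), dtype=bool)))
    with pytest.raises(ValueError, match="degenerate"):
        fit_maxent(pres, bg, flat)


def test_projection_identity_and_mask(grid):
    cells = np.argwhere(grid.ap >= np.quantile(grid.ap, 0.8))
    pres = OccurrenceSet("wet", cells[:100])
    bg = sample_background(grid, 500, seed=9)
    model = fit_maxent(pres, bg, grid)
    smap = project_suitability(model, grid)
    direct = suitability_of(model, grid.climate_at(pres.cells))
    assert np.allclose(direct, smap.values[pres.cells[:, 0], pres.cells[:, 1]])

    masked = ClimateGrid(mat=grid.mat, ap=grid.ap,
                         mask=np.eye(grid.shape[0], grid.shape[1], dtype=bool))
    smap2 = project_suitability(model, masked)
    assert np.isnan(smap2.values[0, 0])


def test_maxent_model_json_roundtrip(grid):
    cells = np.argwhere(grid.ap >= np.quantile(grid.ap, 0.8))
    model = fit_maxent(OccurrenceSet("wet", cells[:80]),
                       sample_background(grid, 400, seed=10), grid)
    clone = MaxEntModel.from_json(model.to_json())
    clim = grid.climate_at(cells[:20])
    assert np.allclose(suitability_of(model, clim), suitability_of(clone, clim))


def test_maxsss_examples():
    assert maxsss_threshold([0.9, 0.8], [0.1, 0.2]) == 0.8
    assert maxsss_threshold([0.5], [0.5, 0.5]) == 0.5
    with pytest.raises(ValueError, match="empty"):
        maxsss_threshold([], [0.1])


def test_maxsss_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(25):
        pres = rng.random(rng.integers(3, 30))
        bg = rng.random(rng.integers(3, 60))
        best, best_score = None, -np.inf
        for thr in np.unique(pres):
            score = (pres >= thr).mean() + (bg < thr).mean()
            if score > best_score + 1e-12:  # ties keep the lowest threshold
                best, best_score = thr, score
        assert maxsss_threshold(pres, bg) == best


def _suit(vals):
    vals = np.asarray(vals, dtype=float)
    return SuitabilityMap(values=vals, mask=np.zeros(vals.shape, dtype=bool))


def test_binarize_limits_and_monotone():
    rng = np.random.default_rng(12)
    s = _suit(rng.random((8, 8)))
    assert binarize(s, 0.0).values.sum() == 64
    assert binarize(s, 1.0 + 1e-9).values.sum() == 0
    lo, hi = binarize(s, 0.3), binarize(s, 0.6)
    assert ((hi.values == 1) <= (lo.values == 1)).all()
    assert binarize(s, 0.5).values.sum() == (s.values >= 0.5).sum()


def test_cooccurrence_is_logical_and():
    rng = np.random.default_rng(13)
    maps = [BinaryMap(values=rng.integers(0, 2, (6, 6)),
                      mask=np.zeros((6, 6), dtype=bool)) for _ in range(4)]
    co = cooccurrence(maps)
    oracle = np.logical_and.reduce([m.values.astype(bool) for m in maps])
    assert np.array_equal(co.values.astype(bool), oracle)
    # area non-increasing in the number of intersected taxa
    areas = [cooccurrence(maps[:k]).values.sum() for k in range(2, 5)]
    assert all(a >= b for a, b in zip(areas, areas[1:]))
    with pytest.raises(ValueError, match="two"):
        cooccurrence(maps[:1])


def test_combine_period_rules():
    a = BinaryMap(values=np.array([[1, 0], [0, 0]]), mask=np.zeros((2, 2), bool))
    b = BinaryMap(values=np.array([[0, 1], [0, 0]]), mask=np.zeros((2, 2), bool))
    union = combine_period([a, b], "union")
    assert union.values.tolist() == [[1, 1], [0, 0]]
    inter = combine_period([a, a], "intersection")
    assert np.array_equal(inter.values, a.values)
    rng = np.random.default_rng(14)
    slices = [BinaryMap(values=rng.integers(0, 2, (5, 5)),
                        mask=np.zeros((5, 5), bool)) for _ in range(4)]
    freq = combine_period(slices, "frequency", frequency=0.5)
    stack = np.stack([s.values for s in slices])
    majority = (stack.sum(axis=0) >= 2).astype(int)
    assert np.array_equal(freq.values, majority)
    with pytest.raises(ValueError, match="empty"):
        combine_period([])


def test_ascii_grid_roundtrip(grid, tmp_path):
    path = tmp_path / "mat.asc"
    write_ascii_grid(grid.mat, path, origin=(10.0, 20.0), cellsize=0.5)
    arr, origin, cellsize, mask = read_ascii_grid(path)
    assert origin == (10.0, 20.0) and cellsize == 0.5
    assert np.allclose(arr, grid.mat, atol=1e-4, rtol=1e-4)


def test_end_to_end_range_recovery():
    """Fitted, binarized ranges of synthetic taxa overlap the true ranges:
    the co-occurrence map's Jaccard with the true intersection is >= 0.5."""
    cfg = SimConfig(seed=22)
    cfg.climate.n_time_slices = 1
    cfg.species.n_presences = 500
    cfg.species.responses = {
        "broad": SpeciesResponse(8.0, 6.0, 1700.0, 600.0),
        "mid": SpeciesResponse(8.0, 4.5, 1700.0, 450.0),
        "narrow": SpeciesResponse(8.0, 3.5, 1700.0, 350.0),
    }
    grid = simulate_climate_series(cfg)[0]
    bg = sample_background(grid, 1000, seed=23)

    fitted_maps, true_maps = [], []
    for taxon, resp in cfg.species.responses.items():
        occ = simulate_taxon_occurrences(grid, cfg, taxon)
        thinned = thin_one_per_pixel(occ.cells, grid, taxon)
        model = fit_maxent(thinned, bg, grid)
        smap = project_suitability(model, grid)
        thr = maxsss_threshold(
            suitability_of(model, grid.climate_at(thinned.cells)),
            suitability_of(model, grid.climate_at(bg.cells)))
        fitted_maps.append(binarize(smap, thr))

        true_s = true_suitability(grid, resp)
        true_thr = maxsss_threshold(
            true_s[thinned.cells[:, 0], thinned.cells[:, 1]],
            true_s[bg.cells[:, 0], bg.cells[:, 1]])
        true_maps.append(BinaryMap(values=(true_s >= true_thr).astype(int),
                                   mask=grid.mask.copy()))

    fitted_co = cooccurrence(fitted_maps).values.astype(bool)
    true_co = cooccurrence(true_maps).values.astype(bool)
    jaccard = (fitted_co & true_co).sum() / max((fitted_co | true_co).sum(), 1)
    assert jaccard >= 0.5
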