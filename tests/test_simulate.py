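"""Synthetic-data generators: contracts, determinism, distributional oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from urheimat.cognates import MISSING, PRESENT
from urheimat.popgen import hudson_fst
from urheimat.simulate import (ClimateConfig, SimConfig, SpeciesResponse,
                               simulate_climate_series, simulate_cognate_matrix,
                               simulate_dated_tree, simulate_genotype_data,
                               simulate_pollen_sites, simulate_taxon_occurrences,
                               true_suitability)


# -- dated trees -------------------------------------------------------------


def test_tree_construction_contract():
    cfg = SimConfig(seed=11)
    tree = simulate_dated_tree(cfg)
    tips = tree.tips()
    assert len(tips) == 5  # 4 extant + 1 extinct
    ages = sorted(t.age for t in tips)
    assert ages[:4] == [0.0] * 4 and ages[4] == 900.0
    for parent, child in tree.branches():
        assert parent.age > child.age


def test_tree_determinism():
    a = simulate_dated_tree(SimConfig(seed=5)).newick()
    b = simulate_dated_tree(SimConfig(seed=5)).newick()
    assert a == b
    c = simulate_dated_tree(SimConfig(seed=6)).newick()
    assert a != c


def test_tree_rejects_bad_rates():
    cfg = SimConfig(seed=1)
    with pytest.raises(ValueError):
        cfg.tree.birth_rate = -1.0
        cfg.tree.__post_init__()


def test_yule_mean_root_age_matches_closed_form():
    """Present is the moment the tree reaches n tips plus an exponential
    hold, so the Yule mean root age is (1/lam)(sum_{k=2}^{n-1} 1/k + 1/n)."""
    lam, n = 1e-3, 6
    cfg = SimConfig(seed=42)
    cfg.tree.birth_rate = lam
    cfg.tree.death_rate = 0.0
    cfg.tree.n_extant_tips = n
    cfg.tree.extinct_tip_age = None
    ages = []
    for seed in range(300):
        cfg.seed = seed
        ages.append(simulate_dated_tree(cfg).root.age)
    expected = (sum(1.0 / k for k in range(2, n)) + 1.0 / n) / lam
    se = np.std(ages) / np.sqrt(len(ages))
    assert abs(np.mean(ages) - expected) < 4 * se


# -- cognates ----------------------------------------------------------------


def test_cognate_counts_near_study_scale(reference_tree):
    m = simulate_cognate_matrix(reference_tree, SimConfig(seed=1))
    assert m.n_concepts == 251
    assert m.n_data_columns == 736


def test_cognate_no_missing_when_fraction_zero(reference_tree):
    cfg = SimConfig(seed=2)
    cfg.cognates.missing_fraction = 0.0
    cfg.cognates.n_concepts = 30
    m = simulate_cognate_matrix(reference_tree, cfg)
    assert (m.cells != MISSING).all()
    # observability: every column has at least one presence
    assert (m.cells == PRESENT).any(axis=0).all()


def test_cognate_zero_rate_gives_constant_columns(reference_tree):
    cfg = SimConfig(seed=3)
    cfg.cognates.clock_rate = 1e-12
    cfg.cognates.missing_fraction = 0.0
    cfg.cognates.n_concepts = 20
    m = simulate_cognate_matrix(reference_tree, cfg)
    assert (m.cells == PRESENT).all()


# -- climate -----------------------------------------------------------------


def test_climate_within_ranges_and_deterministic():
    cfg = SimConfig(seed=9)
    cfg.climate.n_time_slices = 3
    grids = simulate_climate_series(cfg)
    assert len(grids) == 3
    for g in grids:
        assert g.mat.min() >= -15.0 and g.mat.max() <= 30.0
        assert g.ap.min() >= 0.0 and g.ap.max() <= 3000.0
    again = simulate_climate_series(cfg)
    for a, b in zip(grids, again):
        assert np.array_equal(a.mat, b.mat) and np.array_equal(a.ap, b.ap)


def test_climate_smoothness_limit_constant():
    cfg = SimConfig(seed=9)
    cfg.climate.smoothness = 1e6
    cfg.climate.n_time_slices = 1
    g = simulate_climate_series(cfg)[0]
    assert np.ptp(g.mat) < 1e-6 * max(1.0, abs(g.mat.mean()))


def test_climate_spatial_autocorrelation():
    cfg = SimConfig(seed=10)
    cfg.climate.n_time_slices = 1
    g = simulate_climate_series(cfg)[0]
    # neighboring cells are far more alike than distant ones
    d_neighbor = np.abs(np.diff(g.mat, axis=1)).mean()
    rng = np.random.default_rng(0)
    flat = g.mat.ravel()
    idx = rng.integers(len(flat), size=(2000, 2))
    d_random = np.abs(flat[idx[:, 0]] - flat[idx[:, 1]]).mean()
    assert d_neighbor < 0.5 * d_random


def test_climate_rejects_degenerate_range():
    cfg = SimConfig(seed=1)
    with pytest.raises(ValueError, match="degenerate"):
        cfg.climate.temp_range = (5.0, 5.0)
        cfg.climate.__post_init__()


# -- species occurrences -----------------------------------------------------


def test_occurrence_count_exact():
    cfg = SimConfig(seed=4)
    cfg.species.n_presences = 200
    grid = simulate_climate_series(cfg)[0]
    occ = simulate_taxon_occurrences(grid, cfg, "taxon_a")
    assert len(occ.cells) == 200
    assert occ.source_count == 200


def test_occurrence_narrow_response_concentrates():
    cfg = SimConfig(seed=4)
    cfg.species.responses["narrow"] = SpeciesResponse(8.0, 0.15, 1600.0, 12.0)
    cfg.species.n_presences = 150
    grid = simulate_climate_series(cfg)[0]
    occ = simulate_taxon_occurrences(grid, cfg, "narrow")
    clim = grid.climate_at(occ.cells)
    assert np.abs(clim[:, 0] - 8.0).max() < 1.5


def test_occurrence_frequency_tracks_suitability():
    """Cell occupancy frequency rank-correlates with true suitability."""
    cfg = SimConfig(seed=8)
    cfg.species.n_presences = 2000
    grid = simulate_climate_series(cfg)[0]
    occ = simulate_taxon_occurrences(grid, cfg, "taxon_a")
    counts = np.zeros(grid.shape)
    for r, c in occ.cells:
        counts[r, c] += 1
    s = true_suitability(grid, cfg.species.responses["taxon_a"])
    # compare on cells with non-negligible suitability mass
    mask = s > np.quantile(s, 0.5)
    rho = spearmanr(counts[mask], s[mask]).statistic
    assert rho > 0.5


# -- pollen ------------------------------------------------------------------


def test_pollen_site_count_and_determinism():
    cfg = SimConfig(seed=6)
    cfg.climate.n_time_slices = 4
    grids = simulate_climate_series(cfg)
    sites = simulate_pollen_sites(grids, cfg)
    assert len(sites) == 1134
    again = simulate_pollen_sites(grids, cfg)
    assert [(s.row, s.col, s.date_bp, s.biome) for s in sites] == \
           [(s.row, s.col, s.date_bp, s.biome) for s in again]
    for s in sites[:50]:
        assert grids[0].time_bp >= s.date_bp >= grids[-1].time_bp


def test_pollen_overwhelming_intercept_dominates():
    cfg = SimConfig(seed=6)
    cfg.climate.n_time_slices = 2
    coeff = np.zeros((8, 3))
    coeff[1, 0] = 25.0  # Steppe intercept dwarfs everything
    cfg.pollen.true_coefficients = coeff
    cfg.pollen.n_sites = 1000
    grids = simulate_climate_series(cfg)
    sites = simulate_pollen_sites(grids, cfg)
    frac = np.mean([s.biome == "Steppe" for s in sites])
    assert frac >= 0.99


def test_pollen_rejects_bad_coefficient_shape():
    cfg = SimConfig(seed=1)
    with pytest.raises(ValueError, match="8x3"):
        cfg.pollen.true_coefficients = np.zeros((3, 3))
        cfg.pollen.__post_init__()


# -- genotypes ---------------------------------------------------------------


def test_genotype_no_missing_when_rate_zero():
    cfg = SimConfig(seed=12)
    cfg.genotypes.n_modern_per_pop = 20
    cfg.genotypes.n_ancient = 10
    cfg.genotypes.n_snps = 300
    cfg.genotypes.ancient_missing_rate = 0.0
    g = simulate_genotype_data(cfg)
    assert (g.calls != 9).all()


def test_genotype_fst_zero_shares_frequencies():
    """With FST 0 the only between-population variance is binomial sampling."""
    cfg = SimConfig(seed=13)
    cfg.genotypes.fst = 0.0
    cfg.genotypes.n_pops = 2
    cfg.genotypes.n_modern_per_pop = 100
    cfg.genotypes.n_ancient = 2
    cfg.genotypes.n_snps = 2000
    g = simulate_genotype_data(cfg)
    assert np.array_equal(g.true_pop_freqs[0], g.true_pop_freqs[1])
    a = g.calls[:100].astype(float)
    b = g.calls[100:200].astype(float)
    diff_var = ((a.mean(axis=0) - b.mean(axis=0)) / 2.0) ** 2
    p = g.true_pop_freqs[0]
    # Var(p1_hat - p2_hat) = 2 * p(1-p) / (2n) for two samples of n diploids
    expected = 2 * p * (1 - p) / (2 * 100)
    assert abs(diff_var.mean() / expected.mean() - 1.0) < 0.15


def test_genotype_hudson_fst_recovery():
    cfg = SimConfig(seed=14)
    cfg.genotypes.fst = 0.1
    cfg.genotypes.n_pops = 2
    cfg.genotypes.n_modern_per_pop = 60
    cfg.genotypes.n_ancient = 2
    cfg.genotypes.n_snps = 5000
    g = simulate_genotype_data(cfg)
    est = hudson_fst(g.calls[:60], g.calls[60:120])
    assert 0.07 <= est <= 0.13


def test_genotype_rejects_bad_fst():
    cfg = SimConfig(seed=1)
    with pytest.raises(ValueError):
        cfg.genotypes.fst = 1.0
        cfg.genotypes.__post_init__()
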