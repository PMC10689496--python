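"""Genotype normalization, PCA and least-squares projection."""

import numpy as np
import pytest

from urheimat.popgen import (MISSING, GenotypeMatrix, fit_pca, hudson_fst,
                             lsq_project, normalize_genotypes, pca_report,
                             project_individuals, read_eigenstrat,
                             write_eigenstrat)
from urheimat.simulate import SimConfig, simulate_genotype_data


def _geno_cfg(seed, **kw):
    cfg = SimConfig(seed=seed)
    g = cfg.genotypes
    g.n_pops = kw.get("n_pops", 2)
    g.n_modern_per_pop = kw.get("n_modern_per_pop", 50)
    g.n_ancient = kw.get("n_ancient", 20)
    g.n_snps = kw.get("n_snps", 2000)
    g.fst = kw.get("fst", 0.1)
    g.ancient_missing_rate = kw.get("ancient_missing_rate", 0.5)
    g.admixed_fraction = kw.get("admixed_fraction", 0.0)
    return cfg


def test_normalization_drops_monomorphic_and_centers():
    calls = np.array([
        [0, 2, 1, 0],
        [0, 1, 2, 0],
        [0, 0, 1, 0],
        [0, 2, 0, 0],
    ], dtype=np.int8)
    g = GenotypeMatrix(individual_ids=[f"i{k}" for k in range(4)],
                       populations=["p"] * 4, roles=["modern-reference"] * 4,
                       snp_ids=["s1", "s2", "s3", "s4"], calls=calls)
    normalized, keep, p, norms = normalize_genotypes(g)
    assert list(keep) == [1, 2]  # all-0 columns dropped
    assert np.max(np.abs(normalized.mean(axis=0) -
                         (- (2 * p - calls[:, keep].mean(axis=0)) / norms))) < 1e-12


def test_normalization_hand_computed_3x2():
    """p_hat = (1 + sum)/(2 + 2n); value = (call - 2p)/sqrt(p(1-p))."""
    calls = np.array([[0, 2], [1, 1], [2, 1]], dtype=np.int8)
    g = GenotypeMatrix(individual_ids=["a", "b", "c"], populations=["p"] * 3,
                       roles=["modern-reference"] * 3, snp_ids=["s1", "s2"],
                       calls=calls)
    normalized, keep, p, norms = normalize_genotypes(g)
    p_expected = np.array([(1 + 3) / (2 + 6), (1 + 4) / (2 + 6)])
    assert np.allclose(p, p_expected)
    expected = (calls - 2 * p_expected) / np.sqrt(p_expected * (1 - p_expected))
    assert np.allclose(normalized, expected)


def test_pca_orthonormal_and_ordered():
    g = simulate_genotype_data(_geno_cfg(41))
    model = fit_pca(g, k=5)
    gram = model.loadings.T @ model.loadings
    assert np.max(np.abs(gram - np.eye(5))) < 1e-8
    assert (np.diff(model.eigenvalues) <= 1e-9).all()
    with pytest.raises(ValueError, match="k too large"):
        fit_pca(g, k=1000)


def test_pca_separates_two_populations():
    g = simulate_genotype_data(_geno_cfg(42, n_snps=5000))
    model = fit_pca(g, k=2)
    normalized, keep, _, _ = normalize_genotypes(g)
    scores = normalized @ model.loadings
    pc1_a, pc1_b = scores[:50, 0], scores[50:, 0]
    assert max(pc1_a.min(), pc1_b.min()) > min(pc1_a.max(), pc1_b.max()) or \
        max(pc1_b.min(), pc1_a.min()) > min(pc1_b.max(), pc1_a.max())


def test_projection_identity_without_missingness():
    g = simulate_genotype_data(_geno_cfg(43, ancient_missing_rate=0.0))
    model = fit_pca(g, k=4)
    snp_index = np.array([g.snp_ids.index(s) for s in model.snp_ids])
    row = g.calls[-1, snp_index]
    coords, used = lsq_project(model, row)
    y = (row - 2 * model.freqs) / model.norms
    assert used == len(model.snp_ids)
    assert np.max(np.abs(coords - model.loadings.T @ y)) < 1e-10


def test_projection_with_half_masking_stays_close():
    """A duplicated reference individual with 50% masked calls projects
    within 10% of the reference PC1 range of its unmasked position."""
    g = simulate_genotype_data(_geno_cfg(44, n_snps=5000, n_ancient=2,
                                         ancient_missing_rate=0.0))
    model = fit_pca(g, k=2)
    normalized, keep, _, _ = normalize_genotypes(g)
    scores = normalized @ model.loadings
    pc1_range = np.ptp(scores[:, 0])

    snp_index = np.array([g.snp_ids.index(s) for s in model.snp_ids])
    rng = np.random.default_rng(0)
    row = g.calls[0, snp_index].copy()  # a modern-reference individual
    full_coords, _ = lsq_project(model, row)
    masked = row.copy()
    masked[rng.random(len(masked)) < 0.5] = MISSING
    masked_coords, used = lsq_project(model, masked)
    assert used < len(masked)
    drift = np.abs(masked_coords[:2] - full_coords[:2]).max()
    assert drift < 0.10 * pc1_range


def test_projection_all_missing_errors():
    g = simulate_genotype_data(_geno_cfg(45))
    model = fit_pca(g, k=2)
    with pytest.raises(ValueError, match="no usable"):
        lsq_project(model, np.full(len(model.snp_ids), MISSING))


def test_masking_never_inflates_projection_norm():
    """Averaged over maskings, least-squares coordinates shrink toward the
    origin relative to the unmasked projection."""
    g = simulate_genotype_data(_geno_cfg(46, n_snps=3000,
                                         ancient_missing_rate=0.0))
    model = fit_pca(g, k=2)
    snp_index = np.array([g.snp_ids.index(s) for s in model.snp_ids])
    rng = np.random.default_rng(1)
    row = g.calls[0, snp_index]
    full_norm = np.linalg.norm(lsq_project(model, row)[0])
    norms = []
    for _ in range(100):
        masked = row.copy()
        masked[rng.random(len(masked)) < 0.6] = MISSING
        norms.append(np.linalg.norm(lsq_project(model, masked)[0]))
    assert np.mean(norms) <= full_norm * 1.05


def test_ancient_individuals_land_near_their_population():
    """Projected ancients from population k sit nearest the centroid of
    modern population k on PC1-2 in >= 90% of cases at 50% missingness."""
    g = simulate_genotype_data(_geno_cfg(47, n_pops=3, n_modern_per_pop=60,
                                         n_ancient=60, n_snps=4000,
                                         ancient_missing_rate=0.5))
    model = fit_pca(g, k=2)
    normalized, keep, _, _ = normalize_genotypes(g)
    scores = normalized @ model.loadings
    centroids = {f"pop{k}": scores[k * 60:(k + 1) * 60].mean(axis=0)
                 for k in range(3)}
    proj = project_individuals(model, g)
    hits = 0
    for pop, xy in zip(proj.populations, proj.coords):
        nearest = min(centroids, key=lambda c: np.linalg.norm(xy - centroids[c]))
        hits += nearest == pop
    assert hits / len(proj.populations) >= 0.9


def test_admixed_individuals_project_between_centroids():
    g = simulate_genotype_data(_geno_cfg(48, n_pops=2, n_modern_per_pop=60,
                                         n_ancient=40, n_snps=4000,
                                         ancient_missing_rate=0.3,
                                         admixed_fraction=1.0))
    model = fit_pca(g, k=2)
    normalized, _, _, _ = normalize_genotypes(g)
    scores = normalized @ model.loadings
    c0, c1 = scores[:60].mean(axis=0), scores[60:].mean(axis=0)
    lo = np.minimum(c0, c1)
    hi = np.maximum(c0, c1)
    pad = 0.1 * np.linalg.norm(c1 - c0)  # box expanded by 10% of the segment
    proj = project_individuals(model, g)
    inside = [((xy >= lo - pad) & (xy <= hi + pad)).all() for xy in proj.coords]
    assert np.mean(inside) >= 0.9


def test_report_row_counts():
    """Study-scale bookkeeping: 969 reference + 563 projected -> 1532 rows."""
    cfg = _geno_cfg(49, n_pops=3, n_modern_per_pop=323, n_ancient=563,
                    n_snps=500, ancient_missing_rate=0.3)
    g = simulate_genotype_data(cfg)
    model = fit_pca(g, k=2)
    report = pca_report(model, g)
    assert len(report) == 1532
    assert (report.role == "modern-reference").sum() == 969
    assert (report.role == "projected").sum() == 563
    assert set(report.columns) >= {"id", "population", "role", "PC1", "PC2",
                                   "snps_used"}


def test_eigenstrat_roundtrip(tmp_path):
    g = simulate_genotype_data(_geno_cfg(50, n_modern_per_pop=10, n_ancient=5,
                                         n_snps=200))
    prefix = str(tmp_path / "panel")
    write_eigenstrat(g, prefix)
    back = read_eigenstrat(prefix)
    assert back.individual_ids == g.individual_ids
    assert back.populations == g.populations
    assert back.roles == g.roles
    assert np.array_equal(back.calls, g.calls)


def test_hudson_fst_zero_for_same_population():
    g = simulate_genotype_data(_geno_cfg(51, fst=0.0, n_snps=4000))
    est = hudson_fst(g.calls[:50], g.calls[50:100])
    assert abs(est) < 0.01
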