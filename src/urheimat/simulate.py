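"""Synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its downstream stage
assumes: cognate matrices simulated on a known dated tree under the chosen
gain/loss model, smooth autocorrelated climate fields, taxa sampled from
known Gaussian climate responses, pollen sites drawn from a known
multinomial biome-climate model, and multi-population genotypes with
Balding-Nichols differentiation and ancient-style missingness.  Defaults
mirror the study conditions (5 languages incl. one extinct at 900 BP, 251
concepts / ~736 cognate sets, 1134 pollen and 1229 archaeological sites,
969 modern + 563 projected genomes).  A config seed fully determines every
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter

from .biome import BIOMES, CULTURES, CultureSiteRecord, PollenSite, SocietyBiomeTable
from .cognates import ABSENT, MISSING, PRESENT, CognateMatrix
from .niche import ClimateGrid, OccurrenceSet
from .popgen import GenotypeMatrix
from .trees import DatedTree, TreeNode

# stream offsets so each generator draws from its own substream of the seed
_STREAM = {"tree": 1, "cognates": 2, "climate": 3, "species": 4, "pollen": 5,
           "genotypes": 6, "cultures": 7}


# -- configuration -----------------------------------------------------------


@dataclass
class TreeConfig:
    n_extant_tips: int = 4
    birth_rate: float = 1.0e-4          # per lineage-year
    death_rate: float = 0.0
    extinct_tip_age: float | None = 900.0
    retry_cap: int = 1000

    def __post_init__(self):
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be non-negative")
        if self.n_extant_tips < 2:
            raise ValueError("need at least 2 extant tips")


@dataclass
class CognateConfig:
    n_concepts: int = 251
    mean_sets_per_concept: float = 736.0 / 251.0
    exact_total: bool = True            # repair draws to n_concepts*mean columns
    model: str = "covarion"             # ctmc | covarion
    clock_rate: float = 2.0e-4          # substitutions per year
    freq_present: float = 0.5
    covarion_switch: float = 0.3
    covarion_alpha: float = 0.3
    missing_fraction: float = 0.02
    concept_rate_sigma: float = 0.0     # lognormal sd of per-concept rates
    branch_rate_sigma: float = 0.0      # lognormal sd of per-branch rates

    def __post_init__(self):
        if self.n_concepts < 1 or self.mean_sets_per_concept < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must lie in [0,1]")


@dataclass
class ClimateConfig:
    grid_rows: int = 40
    grid_cols: int = 40
    n_time_slices: int = 10
    temp_range: tuple[float, float] = (-15.0, 30.0)
    precip_range: tuple[float, float] = (0.0, 3000.0)
    smoothness: float = 4.0             # correlation length in cells
    time_span: tuple[float, float] = (15000.0, 1500.0)  # years BP, old -> young
    ar_coeff: float = 0.8               # temporal AR(1) between slices

    def __post_init__(self):
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.n_time_slices < 1:
            raise ValueError("need at least one time slice")
        for lo, hi in (self.temp_range, self.precip_range):
            if lo >= hi:
                raise ValueError("degenerate range (min >= max)")


@dataclass
class SpeciesResponse:
    mat_optimum: float
    mat_width: float
    ap_optimum: float
    ap_width: float


@dataclass
class SpeciesConfig:
    responses: dict[str, SpeciesResponse] = field(default_factory=lambda: {
        "taxon_a": SpeciesResponse(8.0, 5.0, 1800.0, 500.0),
        "taxon_b": SpeciesResponse(10.0, 6.0, 1600.0, 600.0),
        "taxon_c": SpeciesResponse(9.0, 7.0, 1700.0, 700.0),
    })
    n_presences: int = 500


def _default_pollen_coefficients() -> np.ndarray:
    # rows follow BIOMES order; columns (intercept, z_mat, z_ap) on the
    # standardized climate scale; forest classes load increasingly on
    # precipitation, open/cold classes on temperature.  The slope scale is
    # calibrated so the true model's own (Bayes) classification accuracy
    # sits near the mid-70% level a biome-climate classifier attains on
    # real pollen data.
    base = np.array([
        [0.0, 1.5, -3.0],    # Desert
        [0.5, 0.5, -1.5],    # Steppe
        [0.0, -3.0, -1.0],   # Tundra
        [-1.0, -4.5, 0.0],   # Glacier
        [0.5, 0.5, 0.3],     # 5-25% AP
        [0.3, 0.7, 1.0],     # 25-50% AP
        [0.0, 0.8, 1.8],     # 50-75% AP
        [-0.3, 0.9, 2.6],    # >75% AP
    ])
    base[:, 1:] *= 2.5
    return base


@dataclass
class PollenConfig:
    true_coefficients: np.ndarray = field(default_factory=_default_pollen_coefficients)
    n_sites: int = 1134

    def __post_init__(self):
        self.true_coefficients = np.asarray(self.true_coefficients, dtype=float)
        if self.true_coefficients.shape != (len(BIOMES), 3):
            raise ValueError(
                f"true_coefficients must be {len(BIOMES)}x3 (biome x intercept,mat,ap)"
            )


@dataclass
class GenotypeConfig:
    n_pops: int = 3
    n_modern_per_pop: int = 323         # 3 x 323 = 969 reference individuals
    n_ancient: int = 563                # 478 ancient + 85 linguistically explicit
    n_snps: int = 5000
    fst: float = 0.1
    ancient_missing_rate: float = 0.5
    admixed_fraction: float = 0.0       # ancients drawn 50/50 from two pops

    def __post_init__(self):
        if self.n_pops < 2 or self.n_snps < 100:
            raise ValueError("need n_pops >= 2 and n_snps >= 100")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0,1)")
        if not 0 <= self.ancient_missing_rate <= 1:
            raise ValueError("ancient_missing_rate must lie in [0,1]")


@dataclass
class ArchaeologyConfig:
    n_sites: int = 1229


@dataclass
class SimConfig:
    seed: int = 0
    tree: TreeConfig = field(default_factory=TreeConfig)
    cognates: CognateConfig = field(default_factory=CognateConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    pollen: PollenConfig = field(default_factory=PollenConfig)
    genotypes: GenotypeConfig = field(default_factory=GenotypeConfig)
    archaeology: ArchaeologyConfig = field(default_factory=ArchaeologyConfig)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STREAM[stream]])


# -- dated trees -------------------------------------------------------------


def simulate_dated_tree(cfg: SimConfig) -> DatedTree:
    """Forward birth-death tree conditioned on the configured extant tip count.

    The present is the moment the lineage count first reaches n plus an
    exponential stopping hold; one extinct tip is grafted at the configured
    age onto a uniformly chosen coeval branch.
    """
    tc = cfg.tree
    rng = _rng(cfg, "tree")
    for _ in range(tc.retry_cap):
        tree = _simulate_bd(tc, rng)
        if tree is None:
            continue
        if tc.extinct_tip_age is None:
            return tree
        if tree.root.age > tc.extinct_tip_age:
            _graft_extinct_tip(tree, tc.extinct_tip_age, rng)
            return tree
    raise RuntimeError(
        "could not simulate a tree older than the extinct tip within the retry cap"
    )


def _simulate_bd(tc: TreeConfig, rng) -> DatedTree | None:
    lam, mu, n = tc.birth_rate, tc.death_rate, tc.n_extant_tips
    root = TreeNode()
    t_fwd = {root: 0.0}
    alive = []
    for _ in range(2):
        child = TreeNode()
        root.add_child(child)
        alive.append(child)
    dead = []
    t = 0.0
    while len(alive) < n:
        if not alive:
            return None
        total = len(alive) * (lam + mu)
        t += rng.exponential(1.0 / total)
        node = alive.pop(rng.integers(len(alive)))
        t_fwd[node] = t
        if rng.random() < lam / (lam + mu):
            for _ in range(2):
                child = TreeNode()
                node.add_child(child)
                alive.append(child)
        else:
            dead.append(node)
    present = t + rng.exponential(1.0 / (n * (lam + mu)))
    for leaf in alive:
        t_fwd[leaf] = present
    # ages, pruning of extinct lineages, unifurcation suppression
    for node, tf in t_fwd.items():
        node.age = present - tf

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_tip():
            return node if node.age == 0.0 or node in _alive_set else None
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    _alive_set = set(alive)
    root = prune(root)
    root.parent = None
    i = 0
    for node in _iter(root):  # deterministic traversal order
        if node.is_tip():
            i += 1
            node.name = f"L{i}"
            node.age = 0.0
    return DatedTree(root)


def _iter(root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _graft_extinct_tip(tree: DatedTree, age: float, rng) -> None:
    attach_time = rng.uniform(age, tree.root.age)
    candidates = [(p, c) for p, c in tree.branches()
                  if p.age > attach_time > c.age]
    if not candidates:
        raise RuntimeError("no branch spans the attachment time")
    parent, child = candidates[rng.integers(len(candidates))]
    mid = TreeNode(age=attach_time)
    extinct = TreeNode(name="Lx", age=age)
    parent.children[parent.children.index(child)] = mid
    mid.parent = parent
    mid.add_child(child)
    mid.add_child(extinct)
    tree._validate()


def kartvelian_reference_tree() -> DatedTree:
    """The study's mean chronology as a fixed dated tree.

    Topology (Svan,(Georgian+OldGeorgian,(Megrelian,Laz))): root (Svan vs
    Karto-Zan) at 7641 BP, Georgian-Zan split at 2617 BP, Megrelian-Laz
    (Zan) split at 1200 BP, Old Georgian an extinct tip at 900 BP attached
    to the Georgian lineage at 1100 BP.
    """
    svan = TreeNode("Svan", 0.0)
    georgian = TreeNode("Georgian", 0.0)
    old_georgian = TreeNode("OldGeorgian", 900.0)
    megrelian = TreeNode("Megrelian", 0.0)
    laz = TreeNode("Laz", 0.0)
    geo_node = TreeNode(age=1100.0)
    geo_node.add_child(georgian)
    geo_node.add_child(old_georgian)
    zan = TreeNode(age=1200.0)
    zan.add_child(megrelian)
    zan.add_child(laz)
    karto_zan = TreeNode(age=2617.0)
    karto_zan.add_child(geo_node)
    karto_zan.add_child(zan)
    root = TreeNode(age=7641.0)
    root.add_child(svan)
    root.add_child(karto_zan)
    return DatedTree(root)


# -- cognate matrices --------------------------------------------------------


def simulate_cognate_matrix(tree: DatedTree, cfg: SimConfig) -> CognateMatrix:
    """Simulate binary cognate columns on a dated tree.

    Columns are resimulated until at least one tip shows presence, mirroring
    the fact that only attested cognate sets are ever compiled; '?' cells
    are inserted missing-at-random at the configured fraction.
    """
    from .phylo.substitution import SubstitutionModel, covarion_generator, ctmc_rate_matrix

    cc = cfg.cognates
    rng = _rng(cfg, "cognates")
    if cc.model == "ctmc":
        q = ctmc_rate_matrix(cc.freq_present)
        freqs = np.array([1 - cc.freq_present, cc.freq_present])
        visible = np.array([0, 1])
    elif cc.model == "covarion":
        model = SubstitutionModel(kind="covarion", freq_present=cc.freq_present,
                                  covarion_switch=cc.covarion_switch,
                                  covarion_alpha=cc.covarion_alpha)
        q = covarion_generator(model)
        pi1 = cc.freq_present
        freqs = np.array([(1 - pi1) / 2, pi1 / 2, (1 - pi1) / 2, pi1 / 2])
        visible = np.array([0, 1, 0, 1])
    else:
        raise ValueError(f"unknown simulation model {cc.model!r}")

    # parents must be visited before children when simulating states downward
    branches = [(n, c) for n in tree.preorder() for c in n.children]
    p_branch = {}
    concept_rates = (
        np.exp(rng.normal(0.0, cc.concept_rate_sigma, size=cc.n_concepts))
        if cc.concept_rate_sigma > 0 else np.ones(cc.n_concepts)
    )
    concept_rates = concept_rates / concept_rates.mean()
    branch_rates = {}
    for _, child in branches:
        r = np.exp(rng.normal(0.0, cc.branch_rate_sigma)) if cc.branch_rate_sigma > 0 else 1.0
        branch_rates[id(child)] = r
    mean_br = np.mean(list(branch_rates.values()))
    branch_rates = {k: v / mean_br for k, v in branch_rates.items()}

    set_counts = np.array([1 + rng.poisson(max(cc.mean_sets_per_concept - 1.0, 0.0))
                           for _ in range(cc.n_concepts)])
    if cc.exact_total:
        # repair the shifted-Poisson draw to exactly n_concepts * mean
        # columns (736 at study scale), keeping >= 1 set per concept
        target = int(round(cc.n_concepts * cc.mean_sets_per_concept))
        while set_counts.sum() > target:
            j = rng.integers(cc.n_concepts)
            if set_counts[j] > 1:
                set_counts[j] -= 1
        while set_counts.sum() < target:
            set_counts[rng.integers(cc.n_concepts)] += 1

    tips = tree.tips()
    names = [t.name for t in tips]
    columns, concepts_col, ids = [], [], []
    for ci in range(cc.n_concepts):
        concept = f"c{ci + 1:03d}"
        n_sets = int(set_counts[ci])
        for si in range(n_sets):
            for _ in range(10000):
                states = {tree.root: rng.choice(len(freqs), p=freqs)}
                for parent, child in branches:
                    key = (id(parent), id(child), ci)
                    if key not in p_branch:
                        dt = ((parent.age - child.age) * cc.clock_rate
                              * concept_rates[ci] * branch_rates[id(child)])
                        p_branch[key] = expm(q * dt)
                    probs = p_branch[key][states[parent]]
                    states[child] = rng.choice(len(freqs), p=probs)
                obs = np.array([visible[states[t]] for t in tips])
                if obs.any():
                    break
            else:
                raise RuntimeError("observability filter failed to produce a column")
            col = np.where(obs == 1, PRESENT, ABSENT).astype(np.int8)
            if cc.missing_fraction > 0:
                mask = rng.random(len(col)) < cc.missing_fraction
                col[mask] = MISSING
            columns.append(col)
            concepts_col.append(concept)
            ids.append(f"{concept}_{si + 1}")
    return CognateMatrix(
        languages=names,
        tip_dates={t.name: t.age for t in tips},
        column_concepts=concepts_col,
        column_ids=ids,
        cells=np.array(columns, dtype=np.int8).T,
    )


# -- climate -----------------------------------------------------------------


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    """Unit-scale smooth Gaussian field (theoretical variance normalization).

    The white noise is convolved with a Gaussian kernel and divided by the
    kernel's theoretical standard-deviation reduction, so the correlation
    length grows with sigma while the amplitude stays order-one; as
    sigma -> infinity the layer tends to a spatial constant.
    """
    noise = rng.standard_normal(shape)
    smoothed = gaussian_filter(noise, sigma=sigma, mode="reflect")
    theoretical_sd = 1.0 / (2.0 * np.sqrt(np.pi) * max(sigma, 1e-9))
    return smoothed / theoretical_sd


def simulate_climate_series(cfg: SimConfig) -> list[ClimateGrid]:
    cl = cfg.climate
    rng = _rng(cfg, "climate")
    shape = (cl.grid_rows, cl.grid_cols)
    times = np.linspace(cl.time_span[0], cl.time_span[1], cl.n_time_slices)
    grids = []
    fields = {}
    for var in ("mat", "ap"):
        f = _smooth_field(rng, shape, cl.smoothness)
        series = [f]
        for _ in range(cl.n_time_slices - 1):
            g = _smooth_field(rng, shape, cl.smoothness)
            f = cl.ar_coeff * f + np.sqrt(1 - cl.ar_coeff**2) * g
            series.append(f)
        fields[var] = series
    for i, t in enumerate(times):
        lo_t, hi_t = cl.temp_range
        lo_p, hi_p = cl.precip_range
        mat = np.clip((lo_t + hi_t) / 2 + (hi_t - lo_t) / 2 * fields["mat"][i] / 2.5,
                      lo_t, hi_t)
        ap = np.clip((lo_p + hi_p) / 2 + (hi_p - lo_p) / 2 * fields["ap"][i] / 2.5,
                     lo_p, hi_p)
        grids.append(ClimateGrid(mat=mat, ap=ap, time_bp=float(t)))
    return grids


# -- species occurrences -----------------------------------------------------


def true_suitability(grid: ClimateGrid, resp: SpeciesResponse) -> np.ndarray:
    s = (np.exp(-0.5 * ((grid.mat - resp.mat_optimum) / resp.mat_width) ** 2)
         * np.exp(-0.5 * ((grid.ap - resp.ap_optimum) / resp.ap_width) ** 2))
    return np.where(grid.mask, 0.0, s)


def simulate_taxon_occurrences(grid: ClimateGrid, cfg: SimConfig,
                               taxon: str | None = None) -> OccurrenceSet:
    """Presence points sampled with probability proportional to true suitability.

    Points may repeat cells (they are pre-thinning); `thin_one_per_pixel`
    produces the canonical one-per-cell set.
    """
    sp = cfg.species
    rng = _rng(cfg, "species")
    if taxon is None:
        taxon = next(iter(sp.responses))
    resp = sp.responses[taxon]
    s = true_suitability(grid, resp).ravel()
    if s.sum() <= 0:
        raise ValueError("true suitability surface is everywhere zero")
    idx = rng.choice(s.size, size=sp.n_presences, replace=True, p=s / s.sum())
    cells = np.column_stack(np.unravel_index(idx, grid.shape))
    return OccurrenceSet(taxon=taxon, cells=cells, source_count=sp.n_presences)


# -- pollen sites ------------------------------------------------------------

_AP_BINS = {"AP_5_25": (5.0, 25.0), "AP_25_50": (25.0, 50.0),
            "AP_50_75": (50.0, 75.0), "AP_GT75": (75.0, 100.0)}


def simulate_pollen_sites(grids: list[ClimateGrid], cfg: SimConfig) -> list[PollenSite]:
    pc = cfg.pollen
    rng = _rng(cfg, "pollen")
    all_mat = np.concatenate([g.mat.ravel() for g in grids])
    all_ap = np.concatenate([g.ap.ravel() for g in grids])
    means = np.array([all_mat.mean(), all_ap.mean()])
    stds = np.array([all_mat.std(), all_ap.std()])
    stds = np.where(stds > 0, stds, 1.0)
    times = np.array([g.time_bp for g in grids])
    half_gap = (np.abs(np.diff(times)).mean() / 2.0) if len(times) > 1 else 0.0

    sites = []
    for _ in range(pc.n_sites):
        gi = rng.integers(len(grids))
        grid = grids[gi]
        valid = grid.valid_cells()
        row, col = valid[rng.integers(len(valid))]
        mat, ap_mm = grid.mat[row, col], grid.ap[row, col]
        z = (np.array([mat, ap_mm]) - means) / stds
        eta = pc.true_coefficients[:, 0] + pc.true_coefficients[:, 1:] @ z
        p = np.exp(eta - eta.max())
        p /= p.sum()
        biome = BIOMES[rng.choice(len(BIOMES), p=p)]
        if biome in _AP_BINS:
            lo, hi = _AP_BINS[biome]
            # draw strictly inside the bin (the binning convention at the
            # edges is the classifier's concern, not the generator's)
            ap_pct = float(rng.uniform(lo, min(hi, 99.99)))
            if biome == "AP_50_75":
                ap_pct = min(ap_pct, 75.0)
            elif biome == "AP_GT75":
                ap_pct = float(rng.uniform(75.01, 100.0))
            label = None
        else:
            ap_pct = float(rng.uniform(0.0, 4.99))
            label = biome
        date = float(np.clip(times[gi] + rng.uniform(-half_gap, half_gap),
                             min(times), max(times)))
        sites.append(PollenSite(row=int(row), col=int(col), date_bp=date,
                                ap_percent=ap_pct, biome=biome, mat=float(mat),
                                ap_mm=float(ap_mm), low_ap_label=label))
    return sites


def bayes_accuracy(grids: list[ClimateGrid], cfg: SimConfig, n: int = 20000,
                   seed: int = 12345) -> float:
    """Accuracy of the true model classifying its own draws (the Bayes rate)."""
    pc = cfg.pollen
    rng = np.random.default_rng(seed)
    all_mat = np.concatenate([g.mat.ravel() for g in grids])
    all_ap = np.concatenate([g.ap.ravel() for g in grids])
    means = np.array([all_mat.mean(), all_ap.mean()])
    stds = np.where(np.array([all_mat.std(), all_ap.std()]) > 0,
                    np.array([all_mat.std(), all_ap.std()]), 1.0)
    idx = rng.integers(len(all_mat), size=n)
    z = (np.column_stack([all_mat[idx], all_ap[idx]]) - means) / stds
    eta = pc.true_coefficients[:, 0] + z @ pc.true_coefficients[:, 1:].T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    labels = np.array([rng.choice(len(BIOMES), p=pi) for pi in p])
    return float((p.argmax(axis=1) == labels).mean())


# -- archaeological culture sites -------------------------------------------


def simulate_culture_sites(table: SocietyBiomeTable,
                           biome_rasters: dict[float, np.ndarray],
                           classes: list[str], cfg: SimConfig) -> list[CultureSiteRecord]:
    """Dated culture sites placed on cells whose biome matches the table."""
    rng = _rng(cfg, "cultures")
    slice_times = sorted(biome_rasters)
    sites: list[CultureSiteRecord] = []
    attempts = 0
    while len(sites) < cfg.archaeology.n_sites:
        attempts += 1
        if attempts > 100 * cfg.archaeology.n_sites:
            raise RuntimeError("could not place culture sites on matching biomes")
        t = slice_times[rng.integers(len(slice_times))]
        try:
            widx = table.window_of(t)
        except ValueError:
            continue
        cultures = [cu for cu in CULTURES if table.associations[(widx, cu)]]
        if not cultures:
            continue
        culture = cultures[rng.integers(len(cultures))]
        wanted = table.associations[(widx, culture)]
        raster = biome_rasters[t]
        ok = np.isin(raster, [classes.index(b) for b in wanted if b in classes])
        cells = np.argwhere(ok)
        if not len(cells):
            continue
        row, col = cells[rng.integers(len(cells))]
        older, younger = table.windows[widx]
        # date near the slice whose biome map placed the site, inside the window
        gaps = np.diff(sorted(slice_times))
        half = float(gaps.min() / 2.0) if len(gaps) else 0.0
        lo = max(younger, t - half)
        hi = min(older, t + half)
        date = float(rng.uniform(lo, hi)) if hi > lo else float(t)
        sites.append(CultureSiteRecord(row=int(row), col=int(col),
                                       date_bp=date, culture=culture))
    return sites


# -- genotypes ---------------------------------------------------------------


def simulate_genotype_data(cfg: SimConfig) -> GenotypeMatrix:
    """Balding-Nichols population frequencies, diploid calls, ancient missingness."""
    gc = cfg.genotypes
    rng = _rng(cfg, "genotypes")
    anc = rng.uniform(0.05, 0.95, size=gc.n_snps)
    if gc.fst > 0:
        a = anc * (1 - gc.fst) / gc.fst
        b = (1 - anc) * (1 - gc.fst) / gc.fst
        pop_freqs = np.stack([rng.beta(a, b) for _ in range(gc.n_pops)])
    else:
        pop_freqs = np.tile(anc, (gc.n_pops, 1))

    ids, pops, roles, calls = [], [], [], []
    for k in range(gc.n_pops):
        for i in range(gc.n_modern_per_pop):
            ids.append(f"mod_p{k}_{i}")
            pops.append(f"pop{k}")
            roles.append("modern-reference")
            calls.append(rng.binomial(2, pop_freqs[k]))
    n_admixed = int(round(gc.admixed_fraction * gc.n_ancient))
    for j in range(gc.n_ancient):
        if j < n_admixed:
            k1, k2 = rng.choice(gc.n_pops, size=2, replace=False)
            freq = 0.5 * pop_freqs[k1] + 0.5 * pop_freqs[k2]
            pop = f"pop{k1}+pop{k2}"
        else:
            k = int(rng.integers(gc.n_pops))
            freq = pop_freqs[k]
            pop = f"pop{k}"
        g = rng.binomial(2, freq).astype(np.int8)
        if gc.ancient_missing_rate > 0:
            g[rng.random(gc.n_snps) < gc.ancient_missing_rate] = 9
        ids.append(f"anc_{j}")
        pops.append(pop)
        roles.append("projected")
        calls.append(g)
    gm = GenotypeMatrix(individual_ids=ids, populations=pops, roles=roles,
                        snp_ids=[f"snp{j}" for j in range(gc.n_snps)],
                        calls=np.array(calls, dtype=np.int8))
    gm.true_pop_freqs = pop_freqs  # generator truth, handy for oracles
    return gm
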