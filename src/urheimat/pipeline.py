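"""Pipeline orchestration: validated YAML configs, staged runs, manifests.

Stages (simulate, phylo, compare, niche, biome, pca) execute in dependency
order on synthetic or user-supplied inputs; a JSON manifest records input
checksums, seeds and outputs so any stage can be rerun from it alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biome as biome_mod
from . import niche as niche_mod
from . import popgen, simulate
from .cognates import add_ascertainment_columns, matrix_summary, write_cognate_csv, \
    write_cognate_nexus
from .model_selection import build_comparison_table, nested_sampling
from .phylo import ClockModel, MCMCConfig, SubstitutionModel, mcc_tree, run_mcmc, \
    trace_ess
from .phylo.priors import kartvelian_calibrations

KNOWN_STAGES = ("simulate", "phylo", "compare", "niche", "biome", "pca")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate"])
    # per-stage parameter blocks with defaults filled by validate_config
    simulate: dict = field(default_factory=dict)
    phylo: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)
    niche: dict = field(default_factory=dict)
    biome: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)


_STAGE_DEFAULTS = {
    "simulate": {},
    "phylo": {"model": "covarion", "clock": "ucln", "gamma": 1,
              "generations": 50_000, "thin": 50, "burnin": 0.10,
              "zan_sigma": 10.0},
    "compare": {"particles": 20, "subchain": 100, "models": [
        ["covarion", "ucln", 1], ["covarion", "strict", 1], ["ctmc", "ucln", 1]]},
    "niche": {"n_background": 1000, "n_presences": 300, "taxa": 3},
    "biome": {"n_sites": 1134},
    "pca": {"k": 10},
}


def validate_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML; fills stage defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []
    known_top = {"out_dir", "seed", "stages"} | set(KNOWN_STAGES)
    for key in raw:
        if key not in known_top:
            errors.append(f"unknown key: {key}")
    if "out_dir" not in raw:
        errors.append("missing required key: out_dir")
    stages = raw.get("stages", ["simulate"])
    for s in stages:
        if s not in KNOWN_STAGES:
            errors.append(f"unknown stage name: {s}")
    if not isinstance(raw.get("seed", 0), int):
        errors.append("seed must be an integer")
    blocks = {}
    for stage in KNOWN_STAGES:
        block = dict(_STAGE_DEFAULTS[stage])
        user = raw.get(stage, {}) or {}
        if not isinstance(user, dict):
            errors.append(f"stage block {stage} must be a mapping")
            user = {}
        for k, v in user.items():
            if stage != "simulate" and k not in block:
                errors.append(f"unknown key {stage}.{k}")
            block[k] = v
        blocks[stage] = block
    for key, lo in (("generations", 1), ("thin", 1)):
        if blocks["phylo"][key] < lo:
            errors.append(f"phylo.{key} must be >= {lo}")
    if not 0 <= blocks["phylo"]["burnin"] < 1:
        errors.append("phylo.burnin must lie in [0,1)")
    if blocks["compare"]["particles"] < 2:
        errors.append("compare.particles must be >= 2")
    if errors:
        raise ConfigError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return PipelineConfig(out_dir=raw["out_dir"], seed=raw.get("seed", 0),
                          stages=list(stages), **blocks)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": [], "outputs": {},
                "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    ctx: dict = {}
    order = [s for s in KNOWN_STAGES if s in cfg.stages]
    for stage in order:
        outputs = _STAGE_RUNNERS[stage](cfg, ctx, out)
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {
            name: {"path": str(p), "sha256": _checksum(Path(p))}
            for name, p in outputs.items()
        }
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# -- stage runners -----------------------------------------------------------


def _sim_config(cfg: PipelineConfig) -> simulate.SimConfig:
    sc = simulate.SimConfig(seed=cfg.seed)
    for section, value in (cfg.simulate or {}).items():
        target = getattr(sc, section, None)
        if target is None:
            raise ConfigError(f"unknown simulate section {section}")
        for k, v in (value or {}).items():
            if not hasattr(target, k):
                raise ConfigError(f"unknown simulate key {section}.{k}")
            setattr(target, k, v)
    return sc


def _run_simulate(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    sc = _sim_config(cfg)
    tree = simulate.kartvelian_reference_tree()
    matrix = simulate.simulate_cognate_matrix(tree, sc)
    grids = simulate.simulate_climate_series(sc)
    ctx.update(sim=sc, tree=tree, matrix=matrix, grids=grids)
    csv_path = out / "cognates.csv"
    write_cognate_csv(matrix, csv_path)
    write_cognate_nexus(matrix, out / "cognates.nex")
    (out / "true_tree.nwk").write_text(tree.newick() + "\n")
    niche_mod.write_ascii_grid(grids[0].mat, out / "climate_mat_t0.asc")
    niche_mod.write_ascii_grid(grids[0].ap, out / "climate_ap_t0.asc")
    (out / "cognate_summary.json").write_text(
        json.dumps(matrix_summary(matrix), indent=2))
    return {"cognates_csv": csv_path, "cognates_nexus": out / "cognates.nex",
            "true_tree": out / "true_tree.nwk",
            "summary": out / "cognate_summary.json"}


def _phylo_inputs(cfg, ctx):
    if "matrix" not in ctx:
        _run_simulate(cfg, ctx, Path(cfg.out_dir))
    return add_ascertainment_columns(ctx["matrix"])


def _run_phylo(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    p = cfg.phylo
    m = _phylo_inputs(cfg, ctx)
    model = SubstitutionModel(kind=p["model"], gamma_categories=p["gamma"])
    clock = ClockModel(kind=p["clock"])
    cal = kartvelian_calibrations(p["zan_sigma"])
    mcfg = MCMCConfig(n_generations=int(p["generations"]), thin=int(p["thin"]),
                      burnin_fraction=float(p["burnin"]), seed=cfg.seed)
    sample = run_mcmc(m, model, clock, cal, mcfg)
    ctx["posterior"] = sample
    trace_path = out / "trace.tsv"
    sample.trace.to_csv(trace_path, sep="\t", index=False)
    mcc = mcc_tree(sample.trees)
    (out / "mcc.nwk").write_text(mcc.tree.newick() + "\n")
    summary = {
        "n_trees": len(sample.trees),
        "root_age_mean": float(sample.trace.tree_height.mean()),
        "ess_tree_height": float(trace_ess(sample.trace.tree_height.values)),
        "clade_support": {" ".join(sorted(c)): v
                          for c, v in mcc.clade_support.items()},
        "node_ages": {" ".join(sorted(c)): v for c, v in
                      ((c, {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in d.items()})
                       for c, d in mcc.node_ages.items())},
    }
    (out / "phylo_summary.json").write_text(json.dumps(summary, indent=2))
    return {"trace": trace_path, "mcc": out / "mcc.nwk",
            "summary": out / "phylo_summary.json"}


def _run_compare(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    p = cfg.compare
    m = _phylo_inputs(cfg, ctx)
    cal = kartvelian_calibrations(cfg.phylo["zan_sigma"])
    results = []
    for kind, clock_kind, gamma in p["models"]:
        label = f"{kind}+{clock_kind}+g{gamma}"
        res = nested_sampling(
            m, SubstitutionModel(kind=kind, gamma_categories=gamma),
            ClockModel(kind=clock_kind), cal,
            n_particles=int(p["particles"]), subchain_length=int(p["subchain"]),
            seed=cfg.seed, label=label)
        results.append(res)
    table = build_comparison_table(results)
    path = out / "model_comparison.csv"
    table.to_csv(path, index=False)
    ctx["comparison"] = table
    return {"comparison": path}


def _run_niche(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    p = cfg.niche
    if "grids" not in ctx:
        _run_simulate(cfg, ctx, out)
    sc, grids = ctx["sim"], ctx["grids"]
    sc.species.n_presences = int(p["n_presences"])
    taxa = list(sc.species.responses)[: int(p["taxa"])]
    grid = grids[0]
    binary_maps = []
    for taxon in taxa:
        occ = simulate.simulate_taxon_occurrences(grid, sc, taxon)
        thinned = niche_mod.thin_one_per_pixel(occ.cells, grid, taxon)
        bg = niche_mod.sample_background(grid, min(int(p["n_background"]),
                                                  len(grid.valid_cells())), cfg.seed)
        model = niche_mod.fit_maxent(thinned, bg, grid)
        smap = niche_mod.project_suitability(model, grid)
        thr = niche_mod.maxsss_threshold(
            niche_mod.suitability_of(model, grid.climate_at(thinned.cells)),
            niche_mod.suitability_of(model, grid.climate_at(bg.cells)))
        binary_maps.append(niche_mod.binarize(smap, thr))
    co = niche_mod.cooccurrence(binary_maps)
    path = out / "cooccurrence.asc"
    niche_mod.write_ascii_grid(co.values.astype(float), path)
    ctx["cooccurrence"] = co
    return {"cooccurrence": path}


def _run_biome(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    if "grids" not in ctx:
        _run_simulate(cfg, ctx, out)
    sc, grids = ctx["sim"], ctx["grids"]
    sc.pollen.n_sites = int(cfg.biome["n_sites"])
    sites = simulate.simulate_pollen_sites(grids, sc)
    model = biome_mod.fit_multinomial(sites)
    metrics = biome_mod.classification_metrics(model, sites)
    table = biome_mod.load_society_biome_table()
    rasters = {g.time_bp: biome_mod.project_biome_map(model, g) for g in grids}
    ctx.update(biome_model=model, biome_metrics=metrics, pollen_sites=sites,
               biome_rasters=rasters, society_table=table)
    payload = {"accuracy": metrics["accuracy"], "cohen_kappa": metrics["cohen_kappa"],
               "per_class_accuracy": metrics["per_class_accuracy"],
               "n_sites": len(sites)}
    path = out / "biome_metrics.json"
    path.write_text(json.dumps(payload, indent=2))
    return {"metrics": path}


def _run_pca(cfg: PipelineConfig, ctx: dict, out: Path) -> dict:
    sc = ctx.get("sim") or _sim_config(cfg)
    ctx["sim"] = sc
    g = simulate.simulate_genotype_data(sc)
    model = popgen.fit_pca(g, k=int(cfg.pca["k"]))
    report = popgen.pca_report(model, g)
    path = out / "pca_report.csv"
    report.to_csv(path, index=False)
    ctx["pca_report"] = report
    return {"report": path}


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "phylo": _run_phylo,
    "compare": _run_compare,
    "niche": _run_niche,
    "biome": _run_biome,
    "pca": _run_pca,
}
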