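"""Metropolis-Hastings sampling for tip-dated cognate phylogenies.

The state is a dated tree (with per-branch rates under the relaxed clock),
the substitution and clock parameters, optional per-concept rate
multipliers, and the FBD hyperparameters (diversification, turnover,
sampling proportion; extant sampling fixed at 1).  Moves: internal-node age
slides, root-age scaling, narrow exchange on the topology, multiplicative
scales on positive scalars, reflected windows on unit-interval scalars,
per-branch rate scales, and a mean-preserving delta exchange on concept
rates.  One root seed drives every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..cognates import CognateMatrix
from ..trees import DatedTree, TreeNode
from .likelihood import LikelihoodWorkspace, dataset_loglikelihood
from .priors import (CalibrationSet, ClockModel, FBDParams,
                     fbd_log_density, sample_ucln_rates)
from .substitution import SubstitutionModel, covarion_frequencies, \
    covarion_generator, ctmc_rate_matrix, spectral

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class LogNormalPrior:
    def __init__(self, s: float, scale: float):
        self.s, self.mu = s, np.log(scale)

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -np.inf
        z = (np.log(x) - self.mu) / self.s
        return -np.log(x * self.s) - _LOG_SQRT_2PI - 0.5 * z * z

    def rvs(self, rng) -> float:
        return float(np.exp(self.mu + self.s * rng.standard_normal()))


class ExponPrior:
    def __init__(self, scale: float):
        self.scale = scale

    def logpdf(self, x: float) -> float:
        return -np.inf if x < 0 else -x / self.scale - np.log(self.scale)

    def rvs(self, rng) -> float:
        return float(rng.exponential(self.scale))


class UnitUniformPrior:
    @staticmethod
    def logpdf(x: float) -> float:
        return 0.0 if 0.0 < x < 1.0 else -np.inf

    @staticmethod
    def rvs(rng) -> float:
        return float(rng.random())


# hyperpriors (configurable defaults; centers chosen for basic-vocabulary
# replacement scales, diversification per the canonical FBD parameterization)
PRIORS = {
    "clock_rate": LogNormalPrior(1.5, 2.0e-4),
    "clock_mean": LogNormalPrior(1.5, 2.0e-4),
    "ucln_sigma": ExponPrior(1.0 / 3.0),
    "freq_present": UnitUniformPrior(),
    "cov_switch": LogNormalPrior(1.0, 0.5),
    "cov_alpha": UnitUniformPrior(),
    "gamma_shape": LogNormalPrior(1.0, 1.0),
    "dollo_death": LogNormalPrior(1.0, 1.0),
    # centered on ln(n_tips)/root-age for a handful of languages over ~10 kyr;
    # a per-150-years diversification scale would imply thousands of languages
    "fbd_d": LogNormalPrior(1.5, 2.0e-4),
    "fbd_r": UnitUniformPrior(),
    "fbd_s": UnitUniformPrior(),
}
_UNIT_PARAMS = {"freq_present", "cov_alpha", "fbd_r", "fbd_s"}


def _ucln_logpdf(rates: np.ndarray, mean: float, s: float) -> float:
    if s <= 0:
        return 0.0
    mu = np.log(mean) - s * s / 2.0
    z = (np.log(rates) - mu) / s
    return float(-(np.log(rates * s) + _LOG_SQRT_2PI + 0.5 * z * z).sum())


def _normal_logpdf(x: float, mean: float, sigma: float) -> float:
    z = (x - mean) / sigma
    return -np.log(sigma) - _LOG_SQRT_2PI - 0.5 * z * z


@dataclass
class MCMCConfig:
    n_generations: int = 100_000
    thin: int = 100
    burnin_fraction: float = 0.10
    seed: int = 0
    likelihood_on: bool = True
    sample_topology: bool = True
    sample_concept_rates: bool = False
    root_age_max: float = 50_000.0
    store_trees: bool = True

    def __post_init__(self):
        if self.thin <= 0 or self.n_generations < self.thin:
            raise ValueError("need n_generations >= thin > 0")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must lie in [0,1)")


def retained_sample_count(n_generations: int, thin: int,
                          burnin_fraction: float) -> int:
    """Posterior samples kept after thinning and burn-in removal."""
    n = n_generations // thin
    return n - int(round(burnin_fraction * n))


@dataclass
class PosteriorSample:
    trees: list[DatedTree]
    trace: pd.DataFrame
    n_burnin: int
    acceptance_rates: dict[str, float]
    config: MCMCConfig


@dataclass
class State:
    tree: DatedTree
    params: dict[str, float]
    concept_rates: np.ndarray
    log_prior: float = -np.inf
    log_lik: float = 0.0

    def copy(self) -> "State":
        return State(tree=self.tree.copy(), params=dict(self.params),
                     concept_rates=self.concept_rates.copy(),
                     log_prior=self.log_prior, log_lik=self.log_lik)

    def posterior(self) -> float:
        return self.log_prior + self.log_lik


class Sampler:
    """Shared move/prior/likelihood machinery for MCMC and nested sampling."""

    def __init__(self, m: CognateMatrix, model: SubstitutionModel,
                 clock: ClockModel, cal: CalibrationSet, cfg: MCMCConfig,
                 fbd_fixed: FBDParams | None = None):
        self.m = m
        self.model = model
        self.clock = clock
        self.cal = cal
        self.cfg = cfg
        self.fbd_fixed = fbd_fixed
        self.n_concepts = m.n_concepts
        self._workspace = (None if model.kind == "sdollo"
                           else LikelihoodWorkspace(m, 2 if model.kind == "ctmc" else 4))
        self._decomp_cache: dict[tuple, tuple] = {}
        self.param_names = self._param_names()
        self.moves = self._build_moves()
        for name, age in cal.tip_calibrations.items():
            if name in m.languages and abs(m.tip_dates[name] - age) > 1e-9:
                raise ValueError(f"tip calibration conflicts with matrix date: {name}")
        for node_cal in cal.node_calibrations:
            missing = node_cal.clade - set(m.languages)
            if missing:
                raise ValueError(
                    f"calibrated clade tips absent from the data: {sorted(missing)}")

    # -- parameters ----------------------------------------------------------

    def _param_names(self) -> list[str]:
        names = []
        if self.clock.kind == "strict":
            names.append("clock_rate")
        else:
            names += ["clock_mean", "ucln_sigma"]
        if self.model.kind in ("ctmc", "covarion"):
            names.append("freq_present")
        if self.model.kind == "covarion":
            names += ["cov_switch", "cov_alpha"]
        if self.model.kind == "sdollo":
            names.append("dollo_death")
        if self.model.gamma_categories > 1:
            names.append("gamma_shape")
        if self.fbd_fixed is None:
            names += ["fbd_d", "fbd_r", "fbd_s"]
        return names

    def _affects_likelihood(self, name: str) -> bool:
        return name in {"clock_rate", "freq_present", "cov_switch", "cov_alpha",
                        "dollo_death", "gamma_shape"}

    def _fbd(self, params: dict) -> FBDParams:
        if self.fbd_fixed is not None:
            return self.fbd_fixed
        return FBDParams.from_canonical(params["fbd_d"], params["fbd_r"],
                                        params["fbd_s"], rho=1.0)

    # -- state construction --------------------------------------------------

    def initial_state(self, rng: np.random.Generator) -> State:
        params = {}
        for name in self.param_names:
            v = float(PRIORS[name].rvs(rng))
            if name == "fbd_r":
                v = min(max(v, 0.05), 0.95)  # keep psi usable with a dated tip
            params[name] = v
        tree = self._initial_tree(rng)
        if self.clock.kind == "ucln":
            clock = ClockModel(kind="ucln", mean=params["clock_mean"],
                               stdev_log=params["ucln_sigma"])
            rates = sample_ucln_rates(clock, 2 * tree.n_tips - 2, rng)
            for i, (_, child) in enumerate(tree.branches()):
                child.rate = float(rates[i])
        concept_rates = np.ones(self.n_concepts)
        state = State(tree=tree, params=params, concept_rates=concept_rates)
        state.log_prior = self.log_prior(state)
        state.log_lik = self.log_likelihood(state) if self.cfg.likelihood_on else 0.0
        return state

    def _initial_tree(self, rng) -> DatedTree:
        langs = list(self.m.languages)
        rng.shuffle(langs)
        nodes = [TreeNode(name, self.m.tip_dates[name]) for name in langs]
        # seed node ages near the calibrations so sharp priors start in range
        cal_ages = {frozenset(c.clade): c.mean for c in self.cal.node_calibrations}
        while len(nodes) > 1:
            a = nodes.pop(rng.integers(len(nodes)))
            b = nodes.pop(rng.integers(len(nodes)))
            parent = TreeNode()
            parent.add_child(a)
            parent.add_child(b)
            base = max(a.age, b.age)
            parent.age = base + float(rng.uniform(200.0, 1500.0))
            nodes.append(parent)
        tree = DatedTree(nodes[0])
        for clade, age in cal_ages.items():
            node = tree.mrca(sorted(clade))
            if tree.clade_tips(node) == clade:
                lo = max(c.age for c in node.children)
                if age > lo:
                    self._shift_above(node, age)
        return tree

    @staticmethod
    def _shift_above(node: TreeNode, age: float) -> None:
        delta = age - node.age
        node.age = age
        current = node
        while current.parent is not None:
            if current.parent.age <= current.age:
                current.parent.age = current.age + abs(delta) * 0.5 + 1.0
            current = current.parent

    # -- densities -----------------------------------------------------------

    def log_prior(self, state: State) -> float:
        tree = state.tree
        if tree.root.age > self.cfg.root_age_max:
            return -np.inf
        for parent, child in tree.branches():
            if parent.age <= child.age:
                return -np.inf
        logp = 0.0
        for name in self.param_names:
            lp = PRIORS[name].logpdf(state.params[name])
            if not np.isfinite(lp):
                return -np.inf
            logp += float(lp)
        try:
            fbd = self._fbd(state.params)
            logp += fbd_log_density(tree, fbd)
        except ValueError:
            return -np.inf
        if not np.isfinite(logp):
            return -np.inf
        for calnode in self.cal.node_calibrations:
            age = tree.mrca(sorted(calnode.clade)).age
            logp += _normal_logpdf(age, calnode.mean, calnode.sigma)
        if self.clock.kind == "ucln":
            rates = np.array([c.rate for _, c in tree.branches()])
            if (rates <= 0).any():
                return -np.inf
            logp += _ucln_logpdf(rates, state.params["clock_mean"],
                                 state.params["ucln_sigma"])
        if self.cfg.sample_concept_rates:
            logp += _ucln_logpdf(state.concept_rates, np.exp(0.125), 0.5)
        return float(logp)

    def log_likelihood(self, state: State) -> float:
        if not self.cfg.likelihood_on:
            return 0.0
        model = self._model_for(state.params)
        clock = self._clock_for(state.params)
        decomp = self._decomposition(model)
        try:
            return dataset_loglikelihood(state.tree, self.m, model, clock,
                                         concept_rates=state.concept_rates,
                                         decomposition=decomp,
                                         workspace=self._workspace, check=False)
        except ValueError:
            return -np.inf

    def _model_for(self, params: dict) -> SubstitutionModel:
        kw = {"kind": self.model.kind,
              "gamma_categories": self.model.gamma_categories,
              "gamma_shape": params.get("gamma_shape", self.model.gamma_shape)}
        if self.model.kind in ("ctmc", "covarion"):
            kw["freq_present"] = params["freq_present"]
        if self.model.kind == "covarion":
            kw["covarion_switch"] = params["cov_switch"]
            kw["covarion_alpha"] = params["cov_alpha"]
        if self.model.kind == "sdollo":
            kw["dollo_death"] = params["dollo_death"]
        return SubstitutionModel(**kw)

    def _clock_for(self, params: dict) -> ClockModel:
        if self.clock.kind == "strict":
            return ClockModel(kind="strict", rate=params["clock_rate"])
        return ClockModel(kind="ucln", mean=params["clock_mean"],
                          stdev_log=max(params["ucln_sigma"], 1e-12))

    def _decomposition(self, model: SubstitutionModel):
        if model.kind == "sdollo":
            return None
        if model.kind == "ctmc":
            key = ("ctmc", round(model.freq_present, 12))
            q = ctmc_rate_matrix(model.freq_present)
            freqs = np.array([1 - model.freq_present, model.freq_present])
        else:
            key = ("cov", round(model.freq_present, 12),
                   round(model.covarion_switch, 12), round(model.covarion_alpha, 12))
            q = None
        if key not in self._decomp_cache:
            if len(self._decomp_cache) > 512:
                self._decomp_cache.clear()
            if model.kind == "covarion":
                q = covarion_generator(model)
                freqs = covarion_frequencies(model.freq_present)
            self._decomp_cache[key] = spectral(q, freqs)
        return self._decomp_cache[key]

    # -- moves ---------------------------------------------------------------

    def _build_moves(self) -> list[tuple[str, float]]:
        moves = [("age_slide", 5.0), ("root_scale", 2.0), ("root_uniform", 2.0),
                 ("tree_scale", 1.0), ("rate_updown", 2.0)]
        if self.cal.node_calibrations:
            # scale every node above the oldest calibrated age jointly,
            # leaving the sharply calibrated nodes untouched; the up-down
            # variant divides the rates, following the height-rate ridge
            moves.append(("pivot_scale", 3.0))
            moves.append(("pivot_updown", 3.0))
        if self.cfg.sample_topology:
            moves.append(("narrow_exchange", 2.0))
        for name in self.param_names:
            moves.append((f"param:{name}", 1.0))
        if self.clock.kind == "ucln":
            moves.append(("branch_rate", 3.0))
        if self.cfg.sample_concept_rates:
            moves.append(("concept_delta", 3.0))
        w = np.array([wt for _, wt in moves])
        self._move_probs = w / w.sum()
        return moves

    def propose(self, state: State, rng) -> tuple[State, float, bool, str]:
        """Returns (proposal, log-Hastings, affects_likelihood, move name)."""
        name = self.moves[rng.choice(len(self.moves), p=self._move_probs)][0]
        new = state.copy()
        hastings = 0.0
        if name == "age_slide":
            internals = [n for n in new.tree.internals() if n.parent is not None]
            if not internals:
                name = "root_scale"
            else:
                node = internals[rng.integers(len(internals))]
                lo = max(c.age for c in node.children)
                hi = node.parent.age
                node.age = float(rng.uniform(lo, hi))
        if name == "root_scale":
            f = float(np.exp(1.2 * (rng.random() - 0.5)))
            root = new.tree.root
            lo = max(c.age for c in root.children)
            root.age = root.age * f
            hastings = np.log(f)
            if root.age <= lo:
                new.log_prior = -np.inf
                return new, hastings, False, name
        elif name in ("pivot_scale", "pivot_updown"):
            pivot = max(c.mean for c in self.cal.node_calibrations)
            f = float(np.exp(0.8 * (rng.random() - 0.5)))
            n_scaled = 0
            for node in new.tree.internals():
                if node.age > pivot:
                    node.age = pivot + f * (node.age - pivot)
                    n_scaled += 1
            hastings = n_scaled * np.log(f)
            if name == "pivot_updown":
                n_down = 0
                for key in ("clock_rate", "clock_mean"):
                    if key in new.params:
                        new.params[key] /= f
                        n_down += 1
                if self.clock.kind == "ucln":
                    for _, child in new.tree.branches():
                        child.rate /= f
                        n_down += 1
                hastings -= n_down * np.log(f)
        elif name == "root_uniform":
            # independence draw over the admissible root range: decorrelates
            # the weakly identified tree height
            root = new.tree.root
            lo = max(c.age for c in root.children)
            root.age = float(rng.uniform(lo, self.cfg.root_age_max))
        elif name in ("tree_scale", "rate_updown"):
            width = 0.15 if name == "tree_scale" else 0.15
            f = float(np.exp(width * (rng.random() - 0.5)))
            internals = new.tree.internals()
            for node in internals:
                node.age *= f
            hastings = len(internals) * np.log(f)
            if name == "rate_updown":
                n_down = 0
                for key in ("clock_rate", "clock_mean"):
                    if key in new.params:
                        new.params[key] /= f
                        n_down += 1
                if self.clock.kind == "ucln":
                    for _, child in new.tree.branches():
                        child.rate /= f
                        n_down += 1
                hastings -= n_down * np.log(f)
            # tips keep their dates; reject age inversions via the prior
        elif name == "narrow_exchange":
            ok = self._narrow_exchange(new.tree, rng)
            if not ok:
                new.log_prior = -np.inf
                return new, 0.0, False, name
        elif name.startswith("param:"):
            pname = name.split(":", 1)[1]
            v = new.params[pname]
            if pname in _UNIT_PARAMS:
                v = v + float(rng.uniform(-0.1, 0.1))
                # reflect into (0,1)
                while not 0.0 < v < 1.0:
                    if v <= 0.0:
                        v = -v
                    if v >= 1.0:
                        v = 2.0 - v
                    if v == 0.0:
                        v = 1e-9
            else:
                f = float(np.exp(0.8 * (rng.random() - 0.5)))
                v *= f
                hastings = np.log(f)
            new.params[pname] = v
        elif name == "branch_rate":
            branches = new.tree.branches()
            _, child = branches[rng.integers(len(branches))]
            f = float(np.exp(0.4 * (rng.random() - 0.5)))
            child.rate *= f
            hastings = np.log(f)
        elif name == "concept_delta":
            i, j = rng.choice(self.n_concepts, size=2, replace=False)
            d = float(rng.uniform(0, 0.2))
            if new.concept_rates[i] + d <= 0 or new.concept_rates[j] - d <= 0:
                new.log_prior = -np.inf
                return new, 0.0, False, name
            new.concept_rates[i] += d
            new.concept_rates[j] -= d
        if name.startswith("param:"):
            affects = self._affects_likelihood(name.split(":", 1)[1])
        else:
            affects = True  # tree, branch-rate and concept-rate moves
        return new, hastings, affects, name

    @staticmethod
    def _narrow_exchange(tree: DatedTree, rng) -> bool:
        candidates = []
        for gp in tree.internals():
            kids = gp.children
            if len(kids) != 2:
                continue
            for p, u in ((kids[0], kids[1]), (kids[1], kids[0])):
                if p.is_tip():
                    continue
                for c in p.children:
                    if p.age > u.age:  # swap keeps parent older than new child
                        candidates.append((gp, p, u, c))
        if not candidates:
            return False
        gp, p, u, c = candidates[rng.integers(len(candidates))]
        gp.children[gp.children.index(u)] = c
        p.children[p.children.index(c)] = u
        c.parent, u.parent = gp, p
        return True

    # -- steps ---------------------------------------------------------------

    def posterior_step(self, state: State, rng) -> tuple[State, bool, str]:
        new, hastings, affects, name = self.propose(state, rng)
        new.log_prior = self.log_prior(new)
        if not np.isfinite(new.log_prior):
            return state, False, name
        if self.cfg.likelihood_on:
            new.log_lik = self.log_likelihood(new) if affects else state.log_lik
            if not np.isfinite(new.log_lik):
                return state, False, name
        else:
            new.log_lik = 0.0
        delta = new.posterior() - state.posterior() + hastings
        if np.log(rng.random()) < delta:
            return new, True, name
        return state, False, name

    def prior_step(self, state: State, rng,
                   loglik_floor: float | None = None) -> tuple[State, bool]:
        """Prior-target MH step, optionally constrained to likelihood > floor."""
        new, hastings, affects, _ = self.propose(state, rng)
        new.log_prior = self.log_prior(new)
        if not np.isfinite(new.log_prior):
            return state, False
        if np.log(rng.random()) >= new.log_prior - state.log_prior + hastings:
            return state, False
        if loglik_floor is not None:
            new.log_lik = self.log_likelihood(new) if affects else state.log_lik
            if not (new.log_lik > loglik_floor):
                return state, False
        return new, True


def run_mcmc(m: CognateMatrix, model: SubstitutionModel, clock: ClockModel,
             cal: CalibrationSet | None = None, cfg: MCMCConfig | None = None,
             fbd: FBDParams | None = None) -> PosteriorSample:
    """Sample the posterior over dated trees and model parameters.

    ``fbd`` fixes the tree-prior parameters; by default the canonical FBD
    hyperparameters are sampled under their hyperpriors.  The retained tree
    count is floor(n_generations / thin) * (1 - burnin_fraction).
    """
    cal = cal or CalibrationSet()
    cfg = cfg or MCMCConfig()
    rng = np.random.default_rng(cfg.seed)
    sampler = Sampler(m, model, clock, cal, cfg, fbd_fixed=fbd)
    state = sampler.initial_state(rng)
    # make sure the chain starts somewhere with finite prior
    tries = 0
    while not np.isfinite(state.log_prior):
        state = sampler.initial_state(rng)
        tries += 1
        if tries > 200:
            raise RuntimeError("could not initialize a finite-prior state")

    n_samples = cfg.n_generations // cfg.thin
    trees: list[DatedTree] = []
    rows = []
    accepted: dict[str, int] = {}
    proposed: dict[str, int] = {}
    for gen in range(1, cfg.n_generations + 1):
        state, ok, name = sampler.posterior_step(state, rng)
        proposed[name] = proposed.get(name, 0) + 1
        if ok:
            accepted[name] = accepted.get(name, 0) + 1
        if gen % cfg.thin == 0:
            row = {"state": gen, "posterior": state.posterior(),
                   "likelihood": state.log_lik, "prior": state.log_prior,
                   "tree_height": state.tree.root.age}
            row.update(state.params)
            for calnode in cal.node_calibrations:
                row[f"mrca_{'_'.join(sorted(calnode.clade))}"] = \
                    state.tree.mrca(sorted(calnode.clade)).age
            rows.append(row)
            if cfg.store_trees:
                trees.append(state.tree.copy())
    n_burn = n_samples - retained_sample_count(cfg.n_generations, cfg.thin,
                                               cfg.burnin_fraction)
    trace = pd.DataFrame(rows[n_burn:])
    rates = {k: accepted.get(k, 0) / v for k, v in proposed.items()}
    return PosteriorSample(trees=trees[n_burn:] if cfg.store_trees else [],
                           trace=trace, n_burnin=n_burn,
                           acceptance_rates=rates, config=cfg)
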