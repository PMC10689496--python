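"""Nested-sampling marginal likelihoods and Bayes-factor model ranking.

Nested sampling maintains a set of "particles" drawn from the prior and
iteratively replaces the lowest-likelihood one with a prior draw constrained
to exceed the current likelihood floor; the evidence integral Z accumulates
over the deterministic prior-mass shrinkage ladder X_i = exp(-i/N).  The
standard deviation follows the information-theoretic estimate sqrt(H/N).
A log Bayes factor of at least 5 counts as very strong support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cognates import CognateMatrix
from .phylo.mcmc import MCMCConfig, Sampler
from .phylo.priors import CalibrationSet, ClockModel, FBDParams
from .phylo.substitution import SubstitutionModel

VERY_STRONG_LOG_BF = 5.0


@dataclass
class NestedSamplingResult:
    log_marginal_likelihood: float
    sd: float
    n_particles: int
    ladder: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iterations: int = 0
    label: str = ""


def _logsumexp(values):
    values = np.asarray(values, dtype=float)
    m = np.max(values)
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.exp(values - m).sum()))


def nested_sample_core(init_particles, loglik_fn, replace_fn, *,
                       n_particles: int, max_iterations: int = 100_000,
                       termination: float = 1e-6, rng=None) -> NestedSamplingResult:
    """Generic nested-sampling loop.

    init_particles: list of opaque particle states drawn from the prior.
    loglik_fn(p): log-likelihood of a particle.
    replace_fn(template, floor, rng): a new prior particle with logL > floor,
    typically a constrained-MCMC clone of ``template``.
    """
    particles = list(init_particles)
    if len(particles) != n_particles or n_particles < 2:
        raise ValueError("need at least 2 initialized particles")
    loglik = np.array([loglik_fn(p) for p in particles], dtype=float)
    rng = rng or np.random.default_rng()

    ladder = []
    log_w_terms = []  # log(w_i) + logL_i
    log_x_prev = 0.0
    log_z = -np.inf
    i = 0
    while i < max_iterations:
        i += 1
        worst = int(np.argmin(loglik))
        floor = float(loglik[worst])
        ladder.append(floor)
        log_x = -i / n_particles
        # w_i = X_{i-1} - X_i
        log_w = log_x_prev + np.log1p(-np.exp(log_x - log_x_prev))
        log_w_terms.append(log_w + floor)
        log_z = _logsumexp([log_z, log_w + floor])
        log_x_prev = log_x

        # termination: remaining prior mass at the best live likelihood
        remaining = log_x + float(np.max(loglik))
        if np.isfinite(log_z) and remaining < log_z + np.log(termination):
            break

        idx = int(rng.integers(n_particles - 1))
        if idx >= worst:
            idx += 1
        new_p, new_l = replace_fn(particles[idx], floor, rng)
        particles[worst] = new_p
        loglik[worst] = new_l

    # fill in the live points over the remaining prior mass
    log_x_live = log_x_prev - np.log(n_particles)
    for l in np.sort(loglik):
        log_w_terms.append(log_x_live + l)
        log_z = _logsumexp([log_z, log_x_live + l])

    # information H = E_post[log L] - log Z
    terms = np.asarray(log_w_terms)
    post = np.exp(terms - log_z)
    all_l = np.concatenate([np.asarray(ladder, dtype=float), np.sort(loglik)])
    h = float(np.sum(post * all_l) - log_z)
    sd = float(np.sqrt(max(h, 0.0) / n_particles))
    return NestedSamplingResult(log_marginal_likelihood=float(log_z),
                                sd=max(sd, 1e-12), n_particles=n_particles,
                                ladder=np.asarray(ladder), n_iterations=i)


def nested_sampling(m: CognateMatrix, model: SubstitutionModel, clock: ClockModel,
                    cal: CalibrationSet | None = None, n_particles: int = 20,
                    subchain_length: int = 100, seed: int = 0,
                    prior_burnin: int = 500, max_iterations: int = 100_000,
                    termination: float = 1e-6, fbd: FBDParams | None = None,
                    sample_concept_rates: bool = False,
                    label: str = "") -> NestedSamplingResult:
    """Marginal likelihood of a cognate model by nested sampling.

    Particles are joint-prior draws (equilibrated by prior-only MCMC);
    constrained replacement reuses the posterior sampler's move set with
    likelihood-threshold rejection.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    cal = cal or CalibrationSet()
    cfg = MCMCConfig(n_generations=max(subchain_length, 1), thin=1, seed=seed,
                     likelihood_on=True, sample_concept_rates=sample_concept_rates)
    sampler = Sampler(m, model, clock, cal, cfg, fbd_fixed=fbd)
    rng = np.random.default_rng(seed)

    particles = []
    for _ in range(n_particles):
        s = sampler.initial_state(rng)
        tries = 0
        while not np.isfinite(s.log_prior):
            s = sampler.initial_state(rng)
            tries += 1
            if tries > 200:
                raise ValueError("prior sampling impossible under this configuration")
        for _ in range(prior_burnin):
            s, _ = sampler.prior_step(s, rng)
        s.log_lik = sampler.log_likelihood(s)
        particles.append(s)

    def replace(template, floor, rng_):
        s = template.copy()
        for _ in range(subchain_length):
            s, _ = sampler.prior_step(s, rng_, loglik_floor=floor)
        return s, s.log_lik

    result = nested_sample_core(particles, lambda p: p.log_lik, replace,
                                n_particles=n_particles,
                                max_iterations=max_iterations,
                                termination=termination, rng=rng)
    result.label = label
    return result


def bayes_factor(logml_a: float, logml_b: float) -> dict:
    """BF of model a over model b; log BF >= 5 is very strong support."""
    if not (np.isfinite(logml_a) and np.isfinite(logml_b)):
        raise ValueError("marginal likelihoods must be finite")
    log_bf = logml_a - logml_b
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    return {"bf": bf, "log_bf": float(log_bf),
            "verdict": "very strong" if log_bf >= VERY_STRONG_LOG_BF else "weak"}


def build_comparison_table(results: list[NestedSamplingResult]) -> pd.DataFrame:
    """Model comparison sorted by log marginal likelihood (best first)."""
    if len(results) < 2:
        raise ValueError("need at least 2 results to compare")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate model labels")
    ordered = sorted(results, key=lambda r: r.log_marginal_likelihood, reverse=True)
    best = ordered[0].log_marginal_likelihood
    rows = []
    for r in ordered:
        fac = bayes_factor(best, r.log_marginal_likelihood)
        rows.append({"model": r.label,
                     "log_marginal_likelihood": r.log_marginal_likelihood,
                     "sd": r.sd, "bayes_factor": fac["bf"],
                     "log_bf": fac["log_bf"]})
    return pd.DataFrame(rows)
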