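"""Phylogenetic likelihoods for cognate matrices on dated trees.

Felsenstein pruning over columns for the binary CTMC and covarion models
(uncertain '?' cells sum over both states, discrete-gamma categories are
averaged per column, per-concept rate multipliers scale branch lengths),
with a per-concept ascertainment correction conditioning on at least one
language attesting each cognate set:

    logL_c = sum_cols log P(col) - n_cols(c) * log(1 - P_c(all-absent))

where P_c(all-absent) is the likelihood of the concept's flagged all-zero
column under the same concept rate.  The stochastic Dollo integrates a
single birth uniformly over the tree (plus a root stem) with independent
loss at rate mu_D thereafter, conditioned the same way.
"""

from __future__ import annotations

import numpy as np

from ..cognates import ABSENT, MISSING, PRESENT, CognateMatrix
from ..trees import DatedTree
from .substitution import (SubstitutionModel, covarion_frequencies,
                           covarion_generator, ctmc_rate_matrix, spectral,
                           transition_stack)


def _branch_rates(tree: DatedTree, clock) -> dict:
    """Per-branch absolute rate (substitutions per year) keyed by child id."""
    rates = {}
    for parent, child in tree.branches():
        if clock is None:
            rates[id(child)] = 1.0
        elif clock.kind == "strict":
            rates[id(child)] = clock.rate
        else:  # ucln: absolute rates live on the nodes
            rates[id(child)] = child.rate
    return rates


def _tip_partial(cells_row: np.ndarray, k: int) -> np.ndarray:
    """(n_cols, k) tip partial likelihoods; '?' leaves every state possible."""
    n = len(cells_row)
    out = np.zeros((n, k))
    if k == 2:
        out[cells_row == ABSENT, 0] = 1.0
        out[cells_row == PRESENT, 1] = 1.0
    else:  # covarion states (0s, 1s, 0f, 1f)
        out[cells_row == ABSENT, 0] = out[cells_row == ABSENT, 2] = 1.0
        out[cells_row == PRESENT, 1] = out[cells_row == PRESENT, 3] = 1.0
    out[cells_row == MISSING] = 1.0
    return out


class LikelihoodWorkspace:
    """Per-matrix precomputation shared across likelihood evaluations."""

    def __init__(self, m: CognateMatrix, k: int):
        self.k = k
        self.concept_idx = m.concept_index()
        self.n_concepts = m.n_concepts
        self.tip_partials = {
            lang: _tip_partial(m.cells[i], k) for i, lang in enumerate(m.languages)
        }
        self.data_counts = np.bincount(
            self.concept_idx[~m.is_ascertainment], minlength=m.n_concepts
        )
        self.asc_cols = np.flatnonzero(m.is_ascertainment)
        self.data_cols = np.flatnonzero(~m.is_ascertainment)


def column_likelihoods(tree: DatedTree, m: CognateMatrix, model: SubstitutionModel,
                       clock=None, concept_rates: np.ndarray | None = None,
                       decomposition=None,
                       workspace: LikelihoodWorkspace | None = None,
                       check: bool = True) -> np.ndarray:
    """Per-column likelihoods (gamma categories averaged), before ascertainment."""
    if check:
        if sorted(m.languages) != sorted(tree.tip_names()):
            raise ValueError("matrix languages and tree tips do not match")
        for lang, date in m.tip_dates.items():
            if abs(tree.find_tip(lang).age - date) > 1e-6:
                raise ValueError(f"tip date mismatch for {lang}")

    if model.kind == "ctmc":
        k = 2
        freqs = np.array([1 - model.freq_present, model.freq_present])
    elif model.kind == "covarion":
        k = 4
        freqs = covarion_frequencies(model.freq_present)
    else:
        raise ValueError("use sdollo_loglikelihood for the stochastic Dollo")
    if decomposition is None:
        q = ctmc_rate_matrix(model.freq_present) if k == 2 else covarion_generator(model)
        decomposition = spectral(q, freqs)
    u, lam, u_inv = decomposition
    ws = workspace or LikelihoodWorkspace(m, k)

    concept_idx = ws.concept_idx
    uniform_rates = concept_rates is None or np.ptp(concept_rates) == 0.0
    if concept_rates is None:
        concept_rates = np.ones(ws.n_concepts)
    rates = _branch_rates(tree, clock)
    gamma_rates = model.gamma_rates()

    site_lik = 0.0
    order = list(tree.postorder())
    for g in gamma_rates:
        partial: dict[int, np.ndarray] = {}
        for node in order:
            if node.is_tip():
                partial[id(node)] = ws.tip_partials[node.name]
            else:
                acc = None
                for child in node.children:
                    dur = (node.age - child.age) * rates[id(child)] * g
                    if uniform_rates:
                        p = transition_stack(u, lam, u_inv,
                                             dur * concept_rates[0])  # (k,k)
                        msg = partial[id(child)] @ p.T
                    else:
                        p = transition_stack(u, lam, u_inv, dur * concept_rates)
                        msg = np.einsum("cij,cj->ci", p[concept_idx],
                                        partial[id(child)])
                    acc = msg if acc is None else acc * msg
                partial[id(node)] = acc
        site_lik = site_lik + partial[id(tree.root)] @ freqs
    return site_lik / len(gamma_rates)


def _ascertainment_correct(m: CognateMatrix, site_lik: np.ndarray,
                           workspace: "LikelihoodWorkspace | None" = None) -> float:
    if workspace is not None:
        data_cols, asc_cols = workspace.data_cols, workspace.asc_cols
        concept_idx, data_counts = workspace.concept_idx, workspace.data_counts
    else:
        asc = m.is_ascertainment
        data_cols, asc_cols = np.flatnonzero(~asc), np.flatnonzero(asc)
        concept_idx = m.concept_index()
        data_counts = np.bincount(concept_idx[data_cols], minlength=m.n_concepts)
    lik = site_lik[data_cols]
    if (lik <= 0).any():
        raise ValueError("zero-probability column configuration")
    logl = float(np.log(lik).sum())
    if len(asc_cols):
        p_abs = site_lik[asc_cols]
        if (p_abs >= 1.0).any():
            raise ValueError("ascertainment correction undefined: P(all-absent)=1")
        logl -= float((data_counts[concept_idx[asc_cols]] * np.log1p(-p_abs)).sum())
    return logl


def dataset_loglikelihood(tree: DatedTree, m: CognateMatrix,
                          model: SubstitutionModel, clock=None,
                          concept_rates: np.ndarray | None = None,
                          decomposition=None,
                          workspace: LikelihoodWorkspace | None = None,
                          check: bool = True) -> float:
    """Ascertainment-corrected log-likelihood of a cognate matrix."""
    if model.kind == "sdollo":
        return sdollo_loglikelihood(tree, m, model, clock, concept_rates)
    site_lik = column_likelihoods(tree, m, model, clock, concept_rates,
                                  decomposition, workspace, check)
    return _ascertainment_correct(m, site_lik, workspace)


# -- stochastic Dollo --------------------------------------------------------


def sdollo_column_likelihoods(tree: DatedTree, m: CognateMatrix,
                              model: SubstitutionModel, clock=None,
                              concept_rates: np.ndarray | None = None,
                              stem_duration: float | None = None) -> np.ndarray:
    """Single-birth, multiple-death column likelihoods.

    Birth is uniform (per unit effective branch length) over the tree plus a
    root stem; the per-column probability is the birth-position integral of
    the death-process pattern probability, normalized by the total effective
    length, so the birth intensity cancels.
    """
    if model.kind != "sdollo":
        raise ValueError("model kind must be sdollo")
    if sorted(m.languages) != sorted(tree.tip_names()):
        raise ValueError("matrix languages and tree tips do not match")
    mu = model.dollo_death
    concept_idx = m.concept_index()
    if concept_rates is None:
        concept_rates = np.ones(m.n_concepts)
    rates = _branch_rates(tree, clock)
    gamma_rates = model.gamma_rates()
    lang_row = {lang: i for i, lang in enumerate(m.languages)}
    if stem_duration is None:
        stem_duration = tree.root.age if tree.root.age > 0 else 1.0
    if rates:
        mean_rate = float(np.mean(list(rates.values())))
    elif clock is not None:
        mean_rate = clock.rate if clock.kind == "strict" else clock.mean
    else:
        mean_rate = 1.0

    n_cols = m.cells.shape[1]
    out = np.zeros(n_cols)
    order = list(tree.postorder())
    branches = tree.branches()
    for g in gamma_rates:
        # effective lengths per branch per concept
        eff = {id(c): (p.age - c.age) * rates[id(c)] * g * concept_rates
               for p, c in branches}
        eff_stem = stem_duration * mean_rate * g * concept_rates
        total_len = sum(v for v in eff.values()) + eff_stem  # (n_concepts,)

        # D[node]: P(pattern below node | alive at node), per column
        # A[node]: 1 if no observed presence below node
        d_val: dict[int, np.ndarray] = {}
        a_val: dict[int, np.ndarray] = {}
        for node in order:
            if node.is_tip():
                row = m.cells[lang_row[node.name]]
                d_val[id(node)] = np.where(row == ABSENT, 0.0, 1.0)
                a_val[id(node)] = (row != PRESENT).astype(float)
            else:
                d = np.ones(n_cols)
                a = np.ones(n_cols)
                for child in node.children:
                    ell = eff[id(child)][concept_idx]
                    surv = np.exp(-mu * ell)
                    d *= surv * d_val[id(child)] + (1 - surv) * a_val[id(child)]
                    a *= a_val[id(child)]
                d_val[id(node)] = d
                a_val[id(node)] = a

        measure = np.zeros(n_cols)
        for parent, child in branches:
            ell = eff[id(child)][concept_idx]
            integ_surv = (1 - np.exp(-mu * ell)) / mu
            contrib = d_val[id(child)] * integ_surv + a_val[id(child)] * (ell - integ_surv)
            # births on this branch can only explain presences inside it
            measure += contrib * a_outside(tree, child, a_val, n_cols)
        ell = eff_stem[concept_idx]
        integ_surv = (1 - np.exp(-mu * ell)) / mu
        measure += d_val[id(tree.root)] * integ_surv + a_val[id(tree.root)] * (ell - integ_surv)
        out += measure / total_len[concept_idx]
    return out / len(gamma_rates)


def a_outside(tree: DatedTree, node, a_val: dict, n_cols: int) -> np.ndarray:
    """Indicator per column that all observed presences lie inside `node`'s subtree."""
    ind = np.ones(n_cols)
    current = node
    while current.parent is not None:
        for sib in current.parent.children:
            if sib is not current:
                ind = ind * a_val[id(sib)]
        current = current.parent
    return ind


def sdollo_loglikelihood(tree: DatedTree, m: CognateMatrix,
                         model: SubstitutionModel, clock=None,
                         concept_rates: np.ndarray | None = None,
                         stem_duration: float | None = None) -> float:
    site_lik = sdollo_column_likelihoods(tree, m, model, clock, concept_rates,
                                         stem_duration)
    return _ascertainment_correct(m, site_lik)
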