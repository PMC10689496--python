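"""Posterior summaries: effective sample size, HPD intervals, MCC trees."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from ..trees import DatedTree


def trace_ess(trace: np.ndarray) -> float:
    """Effective sample size, n / (1 + 2 * sum of autocorrelations).

    The autocorrelation sum is truncated by the initial positive-pair rule:
    consecutive pairs (rho_1+rho_2), (rho_3+rho_4), ... are added while
    positive.  A zero-variance trace is degenerate and returns n with a
    warning.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("trace too short for an ESS estimate")
    var = x.var()
    if var == 0:
        warnings.warn("zero-variance trace: ESS undefined, returning n", RuntimeWarning)
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (var * n)
    total = 0.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair <= 0:
            break
        total += pair
        k += 2
    return float(n / (1.0 + 2.0 * total))


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(mass*n) points.

    Ties break to the leftmost (lowest) window.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0,1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples")
    w = ceil(mass * n)
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(x[i]), float(x[i + w - 1])


@dataclass
class MCCSummary:
    tree: DatedTree
    clade_support: dict[frozenset, float]
    node_ages: dict[frozenset, dict] = field(default_factory=dict)
    log_clade_credibility: float = 0.0
    height_rule: str = "mean-age"  # node heights are clade-wise mean MRCA ages


def mcc_tree(trees: list[DatedTree], hpd_mass: float = 0.95) -> MCCSummary:
    """Maximum clade credibility tree over a posterior sample.

    The sampled topology maximizing the product of its clades' posterior
    frequencies is selected; each internal node's age is the mean MRCA age
    of its clade across the trees containing that clade, with an HPD
    interval attached when enough samples exist.
    """
    if not trees:
        raise ValueError("empty posterior sample")
    n = len(trees)
    clade_ages: dict[frozenset, list[float]] = {}
    tree_clades: list[set[frozenset]] = []
    for t in trees:
        clades = set()
        for node in t.internals():
            clade = t.clade_tips(node)
            clades.add(clade)
            clade_ages.setdefault(clade, []).append(node.age)
        tree_clades.append(clades)
    support = {c: len(ages) / n for c, ages in clade_ages.items()}

    scores = [sum(np.log(support[c]) for c in clades) for clades in tree_clades]
    best = int(np.argmax(scores))
    mcc = trees[best].copy()

    node_ages = {}
    for node in mcc.internals():
        clade = mcc.clade_tips(node)
        ages = np.asarray(clade_ages[clade])
        node.age = float(ages.mean())
        entry = {"mean": float(ages.mean()), "support": support[clade]}
        if len(ages) >= 20:
            lo, hi = hpd_interval(ages, hpd_mass)
            entry["hpd"] = (lo, hi)
        node_ages[clade] = entry
    # mean ages may break parent>child order in pathological samples; nudge
    for node in mcc.internals():
        for child in node.children:
            if not child.is_tip() and child.age >= node.age:
                node.age = child.age + 1e-9
    return MCCSummary(tree=mcc, clade_support=support, node_ages=node_ages,
                      log_clade_credibility=float(scores[best]))
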