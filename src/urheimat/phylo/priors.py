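"""Tree and clock priors: fossilized birth-death, UCLN clock, calibrations.

The FBD density is evaluated for a labeled dated tree conditioned on its
root age and on both root lineages leaving sampled descendants, with
extant-sampling fraction rho and through-time sampling rate psi for
non-contemporaneous tips.  With mu = psi = 0 and rho = 1 it reduces to the
Yule density conditioned on the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy.stats import lognorm, norm

from ..trees import DatedTree


@dataclass
class FBDParams:
    birth: float          # lambda, per lineage-year
    death: float = 0.0    # mu
    psi: float = 0.0      # fossil/ancient-language sampling rate
    rho: float = 1.0      # extant sampling fraction

    def __post_init__(self):
        if self.birth <= 0:
            raise ValueError("birth rate must be positive")
        if self.death < 0 or self.psi < 0:
            raise ValueError("death and psi must be non-negative")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0,1]")

    @classmethod
    def from_canonical(cls, diversification: float, turnover: float,
                       sampling_proportion: float, rho: float = 1.0) -> "FBDParams":
        """(d, r, s) -> (lambda, mu, psi): lam=d/(1-r), mu=lam*r, psi=mu*s/(1-s)."""
        if not 0 <= turnover < 1:
            raise ValueError("turnover must lie in [0,1)")
        if not 0 <= sampling_proportion < 1:
            raise ValueError("sampling proportion must lie in [0,1)")
        lam = diversification / (1.0 - turnover)
        mu = lam * turnover
        psi = mu * sampling_proportion / (1.0 - sampling_proportion)
        return cls(birth=lam, death=mu, psi=psi, rho=rho)


def _c1_c2(p: FBDParams):
    c1 = abs(np.sqrt((p.birth - p.death - p.psi) ** 2 + 4 * p.birth * p.psi))
    c2 = -(p.birth - p.death - 2 * p.birth * p.rho - p.psi) / c1
    return c1, c2


def _log_q(t: float, p: FBDParams) -> float:
    c1, c2 = _c1_c2(p)
    # log of 4 e^{-c1 t} / ((1-c2) e^{-c1 t} + (1+c2))^2, kept stable for large t
    return np.log(4.0) - c1 * t - 2.0 * np.log((1 - c2) * np.exp(-c1 * t) + (1 + c2))

def _p0(t: float, p: FBDParams) -> float:
    c1, c2 = _c1_c2(p)
    e = np.exp(-c1 * t)
    frac = ((1 - c2) * e - (1 + c2)) / ((1 - c2) * e + (1 + c2))
    return 1.0 + (-(p.birth - p.death - p.psi) + c1 * frac) / (2.0 * p.birth)


def fbd_log_density(tree: DatedTree, p: FBDParams) -> float:
    """Log density of a labeled dated tree under the FBD prior.

    Conditioned on the root age and on both root children having sampled
    descendants.  Exactly one non-extant tip is allowed per the study design
    (an arbitrary number is supported); psi must be positive if any tip is
    non-extant.
    """
    tips = tree.tips()
    extant = [t for t in tips if t.age == 0.0]
    fossils = [t for t in tips if t.age > 0.0]
    if fossils and p.psi <= 0:
        raise ValueError("non-extant tips require psi > 0")
    n_tips = len(tips)
    n_int = n_tips - 1

    logf = 0.0
    for parent, child in tree.branches():
        logf += _log_q(parent.age, p) - _log_q(child.age, p)
    logf += (n_int - 1) * np.log(p.birth)
    logf += len(extant) * np.log(p.rho)
    for f in fossils:
        p0 = _p0(f.age, p)
        if p0 <= 0:
            return -np.inf
        logf += np.log(p.psi) + np.log(p0)
    logf += n_int * np.log(2.0) - lgamma(n_tips + 1)
    p0_root = _p0(tree.root.age, p)
    if p0_root >= 1.0:
        return -np.inf
    logf -= 2.0 * np.log1p(-p0_root)
    return float(logf)


def yule_log_density(tree: DatedTree, birth: float) -> float:
    """Closed-form Yule density conditioned on the root age (oracle form)."""
    n = tree.n_tips
    total = tree.total_branch_time()
    return (-birth * total + (n - 2) * np.log(birth)
            + (n - 1) * np.log(2.0) - lgamma(n + 1))


# -- clock models ------------------------------------------------------------


@dataclass
class ClockModel:
    kind: str = "strict"      # strict | ucln
    rate: float = 1.0e-4      # strict rate (substitutions per year)
    mean: float = 1.0e-4      # ucln real-space mean M
    stdev_log: float = 0.5    # ucln log-space sd S

    def __post_init__(self):
        if self.kind not in ("strict", "ucln"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.kind == "strict" and self.rate <= 0:
            raise ValueError("strict clock rate must be positive")
        if self.kind == "ucln":
            if self.mean <= 0:
                raise ValueError("ucln mean must be positive")
            if self.stdev_log < 0:
                raise ValueError("ucln stdev_log must be non-negative")


def clock_prior_logdensity(rates: np.ndarray, clock: ClockModel) -> float:
    """UCLN: iid lognormal with real-space mean M, log-space sd S.

    Under the strict clock branch rates are forced equal; unequal vectors
    are rejected by validation and the density is a point mass (0 returned).
    """
    rates = np.asarray(rates, dtype=float)
    if (rates <= 0).any():
        raise ValueError("branch rates must be positive")
    if clock.kind == "strict":
        if not np.allclose(rates, clock.rate, rtol=1e-12):
            raise ValueError("strict clock requires all branch rates equal to it")
        return 0.0
    s = clock.stdev_log
    if s == 0:
        return 0.0 if np.allclose(rates, clock.mean) else -np.inf
    mu = np.log(clock.mean) - s**2 / 2.0
    return float(lognorm.logpdf(rates, s=s, scale=np.exp(mu)).sum())


def sample_ucln_rates(clock: ClockModel, n: int, rng) -> np.ndarray:
    mu = np.log(clock.mean) - clock.stdev_log**2 / 2.0
    return np.exp(rng.normal(mu, clock.stdev_log, size=n))


# -- calibrations ------------------------------------------------------------


@dataclass
class NodeCalibration:
    clade: frozenset[str]
    mean: float
    sigma: float

    def __post_init__(self):
        self.clade = frozenset(self.clade)
        if self.sigma <= 0:
            raise ValueError("calibration sigma must be positive")


@dataclass
class CalibrationSet:
    tip_calibrations: dict[str, float] = field(default_factory=dict)
    node_calibrations: list[NodeCalibration] = field(default_factory=list)

    def log_density(self, tree: DatedTree) -> float:
        logp = 0.0
        for cal in self.node_calibrations:
            missing = cal.clade - set(tree.tip_names())
            if missing:
                raise ValueError(f"calibrated clade tips absent: {sorted(missing)}")
            age = tree.mrca(sorted(cal.clade)).age
            logp += float(norm.logpdf(age, loc=cal.mean, scale=cal.sigma))
        return logp


def kartvelian_calibrations(zan_sigma: float = 10.0) -> CalibrationSet:
    """The study's calibrations: Old Georgian tip fixed at 900 BP and a
    Normal(1200, sigma) prior on the Megrelian-Laz (Zan) split."""
    return CalibrationSet(
        tip_calibrations={"OldGeorgian": 900.0},
        node_calibrations=[NodeCalibration(frozenset({"Megrelian", "Laz"}),
                                           1200.0, zan_sigma)],
    )
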