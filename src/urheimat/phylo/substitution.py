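"""Binary substitution models for cognate gain and loss.

All rate matrices are normalized so the expected number of visible (0<->1)
substitutions per unit branch length is one at equilibrium; the clock model
carries the absolute per-year scaling.  The covarion adds a hidden slow/fast
regime that a cognate switches between without changing its visible state:
states are ordered (0-slow, 1-slow, 0-fast, 1-fast), the slow regime runs at
fraction ``alpha`` of the fast rate, and hidden categories have equal
equilibrium weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist


@dataclass
class SubstitutionModel:
    kind: str = "ctmc"                  # ctmc | covarion | sdollo
    freq_present: float = 0.5           # pi_1 of the visible chain
    covarion_switch: float = 0.5        # hidden slow<->fast switch rate s
    covarion_alpha: float = 0.5         # slow-rate fraction in (0, 1]
    dollo_death: float = 1.0            # loss rate mu_D (per unit branch length)
    dollo_birth: float = 1.0            # birth intensity lambda_D (cancels in the likelihood)
    gamma_categories: int = 1           # 1 or 4
    gamma_shape: float = 1.0

    def __post_init__(self):
        if not 0 < self.freq_present < 1:
            raise ValueError("freq_present must lie in (0,1)")
        if self.kind == "covarion":
            if self.covarion_switch <= 0:
                raise ValueError("covarion switch rate must be positive")
            if not 0 < self.covarion_alpha <= 1:
                raise ValueError("covarion alpha must lie in (0,1]")
        if self.kind == "sdollo" and self.dollo_death <= 0:
            raise ValueError("Dollo death rate must be positive")
        if self.gamma_categories not in (1, 4):
            raise ValueError("gamma_categories must be 1 or 4")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.gamma_categories)


def ctmc_rate_matrix(freq_present: float) -> np.ndarray:
    """Reversible 2-state rate matrix with unit expected substitution rate."""
    pi0, pi1 = 1.0 - freq_present, freq_present
    q = np.array([[-pi1, pi1], [pi0, -pi0]])
    return q / (2.0 * pi0 * pi1)


def ctmc_transition_matrix(rate: float, t: float, freqs: tuple[float, float]) -> np.ndarray:
    """Closed-form 2-state transition matrix P(rate * t)."""
    if t < 0:
        raise ValueError("negative time")
    if rate <= 0:
        raise ValueError("rate must be positive")
    pi0, pi1 = freqs
    beta = 1.0 / (2.0 * pi0 * pi1)
    e = np.exp(-beta * rate * t)
    return np.array([
        [pi0 + pi1 * e, pi1 * (1 - e)],
        [pi0 * (1 - e), pi1 + pi0 * e],
    ])


def covarion_frequencies(freq_present: float) -> np.ndarray:
    pi0, pi1 = 1.0 - freq_present, freq_present
    return np.array([pi0 / 2, pi1 / 2, pi0 / 2, pi1 / 2])


def covarion_generator(model: SubstitutionModel) -> np.ndarray:
    """4x4 covarion rate matrix, states (0s, 1s, 0f, 1f).

    Within-slow substitution runs at rate alpha, within-fast at rate 1 (both
    scaled by the visible equilibrium frequencies), switching preserves the
    visible state, and the whole matrix is rescaled so the expected visible
    substitution rate at equilibrium is 1.
    """
    if model.kind != "covarion":
        raise ValueError("model kind must be covarion")
    pi0, pi1 = 1.0 - model.freq_present, model.freq_present
    s, alpha = model.covarion_switch, model.covarion_alpha
    q = np.zeros((4, 4))
    q[0, 1] = alpha * pi1
    q[1, 0] = alpha * pi0
    q[2, 3] = pi1
    q[3, 2] = pi0
    q[0, 2] = q[2, 0] = q[1, 3] = q[3, 1] = s
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    w = covarion_frequencies(model.freq_present)
    visible_rate = (w[0] * q[0, 1] + w[1] * q[1, 0] + w[2] * q[2, 3] + w[3] * q[3, 2])
    return q / visible_rate


def spectral(q: np.ndarray, freqs: np.ndarray):
    """Eigendecomposition of a reversible rate matrix via symmetrization.

    Returns (u, lam, u_inv) with q = u @ diag(lam) @ u_inv; transition
    matrices for many branch lengths follow by exponentiating lam.
    """
    d = np.sqrt(freqs)
    sym = (q * d[:, None]) / d[None, :]
    lam, vec = np.linalg.eigh((sym + sym.T) / 2.0)
    u = vec / d[:, None]
    u_inv = vec.T * d[None, :]
    return u, lam, u_inv


def transition_stack(u, lam, u_inv, lengths: np.ndarray) -> np.ndarray:
    """P(lengths[i]) for a whole array of branch lengths at once."""
    lengths = np.asarray(lengths, dtype=float)
    e = np.exp(np.multiply.outer(lengths, lam))           # (..., k)
    p = np.einsum("ik,...k,kj->...ij", u, e, u_inv)
    return np.clip(p, 0.0, None)


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean-one discrete gamma category rates (equal-probability categories)."""
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1.0 / shape)
    # mean within each slab via the shape+1 identity
    cdf_up = gamma_dist.cdf(edges, a=shape + 1, scale=1.0 / shape)
    rates = (cdf_up[1:] - cdf_up[:-1]) * k
    return rates / rates.mean()
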