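"""PCA of modern genotypes with least-squares projection of ancient samples.

Follows the smartpca conventions: per-SNP frequencies estimated with the
(1 + sum)/(2 + 2n) shrinkage form, genotypes centered at 2p and scaled by
sqrt(p(1-p)), missing reference calls mean-imputed, no outlier-removal
iterations, and high-missingness individuals placed by solving a least
squares fit of their observed normalized calls against the loadings
restricted to their observed SNPs (lsqproject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 9


@dataclass
class GenotypeMatrix:
    """Diploid calls {0,1,2,9=missing}, individuals x SNPs."""

    individual_ids: list[str]
    populations: list[str]
    roles: list[str]  # "modern-reference" | "projected"
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if not (len(self.individual_ids) == len(self.populations) == len(self.roles) == n):
            raise ValueError("individual annotation length mismatch")
        if len(self.snp_ids) != m:
            raise ValueError("snp id length mismatch")
        if not set(np.unique(self.calls)) <= {0, 1, 2, MISSING}:
            raise ValueError("calls must be 0/1/2/9")
        if "modern-reference" not in self.roles:
            raise ValueError("need at least one modern-reference individual")

    def reference_index(self) -> np.ndarray:
        return np.array([r == "modern-reference" for r in self.roles])


@dataclass
class PCAModel:
    snp_ids: list[str]
    freqs: np.ndarray        # shrinkage allele frequency per retained SNP
    norms: np.ndarray        # sqrt(p(1-p)) per retained SNP
    loadings: np.ndarray     # (n_snps, K) orthonormal columns
    eigenvalues: np.ndarray  # length K, non-increasing
    n_dropped_monomorphic: int = 0


@dataclass
class ProjectionResult:
    individual_ids: list[str]
    coords: np.ndarray       # (n, K)
    snps_used: np.ndarray    # per individual
    populations: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)


def normalize_genotypes(g: GenotypeMatrix):
    """Normalize against the modern-reference panel.

    Returns (normalized reference matrix, kept SNP index, freqs, norms).
    SNPs monomorphic in the reference set are dropped.
    """
    ref = g.reference_index()
    if ref.sum() < 2:
        raise ValueError("need at least 2 modern-reference individuals")
    calls = g.calls[ref].astype(float)
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    total = np.where(obs, calls, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (1.0 + total) / (2.0 + 2.0 * n_obs)
    mean_call = np.where(n_obs > 0, total / np.maximum(n_obs, 1), 0.0)
    poly = (n_obs > 0) & (mean_call > 0) & (mean_call < 2)
    if not poly.any():
        raise ValueError("all SNPs dropped as monomorphic")
    keep = np.flatnonzero(poly)
    p = p[keep]
    norms = np.sqrt(p * (1.0 - p))
    sub = calls[:, keep]
    obs = sub != MISSING
    normalized = np.where(obs, (sub - 2.0 * p) / norms, 0.0)
    return normalized, keep, p, norms


def fit_pca(g: GenotypeMatrix, k: int = 10) -> PCAModel:
    """Top-k eigendecomposition of the reference covariance (no outlier passes)."""
    normalized, keep, p, norms = normalize_genotypes(g)
    n_ref = normalized.shape[0]
    if k > min(n_ref - 1, len(keep)):
        raise ValueError("k too large for the reference panel")
    # SVD of the (individuals x snps) normalized matrix
    u, s, vt = np.linalg.svd(normalized, full_matrices=False)
    loadings = vt[:k].T
    eigenvalues = (s[:k] ** 2) / max(n_ref - 1, 1)
    # fixed sign convention: largest-|weight| loading entry positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        snp_ids=[g.snp_ids[i] for i in keep],
        freqs=p, norms=norms, loadings=loadings, eigenvalues=eigenvalues,
        n_dropped_monomorphic=int(g.calls.shape[1] - len(keep)),
    )


def lsq_project(model: PCAModel, calls: np.ndarray) -> tuple[np.ndarray, int]:
    """Project one individual's calls (aligned to the model's SNP set).

    Least-squares fit of normalized observed calls on the loadings restricted
    to observed SNPs; with no missingness this equals the plain dot products.
    """
    calls = np.asarray(calls, dtype=float)
    obs = calls != MISSING
    n_used = int(obs.sum())
    if n_used == 0:
        raise ValueError("individual has no usable SNPs")
    y = (calls[obs] - 2.0 * model.freqs[obs]) / model.norms[obs]
    a = model.loadings[obs]
    coords, *_ = np.linalg.lstsq(a, y, rcond=None)
    return coords, n_used


def project_individuals(model: PCAModel, g: GenotypeMatrix,
                        snp_index: np.ndarray | None = None) -> ProjectionResult:
    """Project the `projected`-role individuals of a GenotypeMatrix."""
    if snp_index is None:
        pos = {s: i for i, s in enumerate(g.snp_ids)}
        snp_index = np.array([pos[s] for s in model.snp_ids])
    rows = [i for i, r in enumerate(g.roles) if r == "projected"]
    coords, used, ids, pops, roles = [], [], [], [], []
    for i in rows:
        c, n = lsq_project(model, g.calls[i, snp_index])
        coords.append(c)
        used.append(n)
        ids.append(g.individual_ids[i])
        pops.append(g.populations[i])
        roles.append(g.roles[i])
    k = model.loadings.shape[1]
    return ProjectionResult(
        individual_ids=ids,
        coords=np.array(coords).reshape(len(rows), k),
        snps_used=np.array(used, dtype=int),
        populations=pops, roles=roles,
    )


def pca_report(model: PCAModel, g: GenotypeMatrix,
               period_labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Coordinates of every individual: reference scores plus projections."""
    pos = {s: i for i, s in enumerate(g.snp_ids)}
    snp_index = np.array([pos[s] for s in model.snp_ids])
    records = []
    for i, (iid, pop, role) in enumerate(zip(g.individual_ids, g.populations, g.roles)):
        try:
            coords, n_used = lsq_project(model, g.calls[i, snp_index])
        except ValueError:
            continue
        rec = {"id": iid, "population": pop, "role": role,
               "period": (period_labels or {}).get(iid, ""),
               "snps_used": n_used}
        rec.update({f"PC{j + 1}": coords[j] for j in range(len(coords))})
        records.append(rec)
    return pd.DataFrame.from_records(records)


# -- EIGENSTRAT I/O ----------------------------------------------------------


def write_eigenstrat(g: GenotypeMatrix, prefix: str) -> None:
    with open(f"{prefix}.geno", "w") as fh:
        for j in range(len(g.snp_ids)):
            fh.write("".join(str(int(v)) for v in g.calls[:, j]) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for j, sid in enumerate(g.snp_ids):
            fh.write(f"{sid}\t1\t0.0\t{j + 1}\tA\tG\n")
    with open(f"{prefix}.ind", "w") as fh:
        for iid, pop, role in zip(g.individual_ids, g.populations, g.roles):
            tag = pop if role == "modern-reference" else f"{pop}_proj"
            fh.write(f"{iid}\tU\t{tag}\n")


def read_eigenstrat(prefix: str) -> GenotypeMatrix:
    with open(f"{prefix}.snp") as fh:
        snp_ids = [ln.split()[0] for ln in fh if ln.strip()]
    ids, pops, roles = [], [], []
    with open(f"{prefix}.ind") as fh:
        for ln in fh:
            if not ln.strip():
                continue
            iid, _, tag = ln.split()
            ids.append(iid)
            if tag.endswith("_proj"):
                pops.append(tag[: -len("_proj")])
                roles.append("projected")
            else:
                pops.append(tag)
                roles.append("modern-reference")
    rows = []
    with open(f"{prefix}.geno") as fh:
        for ln in fh:
            if ln.strip():
                rows.append([int(ch) for ch in ln.strip()])
    calls = np.array(rows, dtype=np.int8).T  # geno is snps x individuals
    return GenotypeMatrix(individual_ids=ids, populations=pops, roles=roles,
                          snp_ids=snp_ids, calls=calls)


def hudson_fst(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Hudson FST estimator between two diploid populations (ratio of averages)."""
    def freqs(c):
        obs = c != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, c, 0).sum(axis=0)
        return tot / (2.0 * np.maximum(n, 1)), n

    p1, n1 = freqs(np.asarray(calls_a, dtype=float))
    p2, n2 = freqs(np.asarray(calls_b, dtype=float))
    ok = (n1 > 1) & (n2 > 1)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
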