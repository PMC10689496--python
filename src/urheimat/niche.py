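"""Maximum-entropy habitat suitability modelling and range-overlap algebra.

A taxon's climatic niche is fitted by contrasting the climate at occurrence
cells with the climate of random background cells (a Gibbs distribution over
the landscape), using quadratic and hinge features with L1 regularization.
Fitted models are projected onto past climate grids, binarized at the
maximum-training-sensitivity-plus-specificity (maxSSS) threshold, and the
binary ranges of many taxa are multiplied to map their co-occurrence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize


# -- climate grids -----------------------------------------------------------


@dataclass
class ClimateGrid:
    """Two-layer raster: mean annual temperature (degC) and annual precip (mm)."""

    mat: np.ndarray
    ap: np.ndarray
    time_bp: float = 0.0
    origin: tuple[float, float] = (0.0, 0.0)  # x, y of the lower-left corner
    cellsize: float = 1.0
    mask: np.ndarray = field(default=None)  # True where nodata

    def __post_init__(self):
        self.mat = np.asarray(self.mat, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.mat.shape != self.ap.shape:
            raise ValueError("layers must share shape")
        if self.mask is None:
            self.mask = np.zeros(self.mat.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.mat.shape:
            raise ValueError("mask must share the layer shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mat.shape

    def valid_cells(self) -> np.ndarray:
        """(n, 2) array of (row, col) indices of unmasked cells."""
        return np.argwhere(~self.mask)

    def climate_at(self, cells: np.ndarray) -> np.ndarray:
        """(n, 2) array of (mat, ap) for (row, col) cell indices."""
        cells = np.atleast_2d(cells)
        return np.column_stack([self.mat[cells[:, 0], cells[:, 1]],
                                self.ap[cells[:, 0], cells[:, 1]]])

    def cell_of_point(self, x: float, y: float) -> tuple[int, int]:
        col = int((x - self.origin[0]) // self.cellsize)
        row = int((y - self.origin[1]) // self.cellsize)
        return row, col

    def contains_cell(self, row: int, col: int) -> bool:
        r, c = self.shape
        return 0 <= row < r and 0 <= col < c and not self.mask[row, col]


def write_ascii_grid(layer: np.ndarray, path, origin=(0.0, 0.0), cellsize=1.0,
                     mask: np.ndarray | None = None, nodata=-9999.0) -> None:
    """ESRI ASCII grid writer (text raster; row 0 of the array is the top row)."""
    rows, cols = layer.shape
    data = layer.copy().astype(float)
    if mask is not None:
        data[mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write(f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n")
        fh.write(f"cellsize {cellsize}\nNODATA_value {nodata}\n")
        for row in data:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Returns (array, origin, cellsize, mask)."""
    header = {}
    values = []
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                values.append([float(v) for v in parts])
    arr = np.array(values)
    nodata = header.get("nodata_value", -9999.0)
    mask = arr == nodata
    return arr, (header["xllcorner"], header["yllcorner"]), header["cellsize"], mask


# -- occurrences -------------------------------------------------------------


@dataclass
class OccurrenceSet:
    taxon: str
    cells: np.ndarray          # (n, 2) int (row, col), one per cell after thinning
    source_count: int = 0      # points before thinning

    def __post_init__(self):
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=int))


def thin_one_per_pixel(points: np.ndarray, grid: ClimateGrid,
                       taxon: str = "taxon") -> OccurrenceSet:
    """Keep at most one occurrence per grid cell (first in sorted order)."""
    points = np.atleast_2d(np.asarray(points, dtype=int))
    keep = [tuple(p) for p in points if grid.contains_cell(p[0], p[1])]
    if not keep:
        raise ValueError("all points fall outside the grid")
    unique = sorted(set(keep))
    return OccurrenceSet(taxon=taxon, cells=np.array(unique), source_count=len(points))


def sample_background(grid: ClimateGrid, n: int, seed: int) -> OccurrenceSet:
    """n distinct cells drawn uniformly without replacement from unmasked cells."""
    valid = grid.valid_cells()
    if n > len(valid):
        raise ValueError(f"requested {n} background cells but only {len(valid)} valid")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(valid), size=n, replace=False)
    return OccurrenceSet(taxon="background", cells=valid[idx], source_count=n)


# -- MaxEnt ------------------------------------------------------------------

N_HINGE_KNOTS = 30


@dataclass
class MaxEntModel:
    feature_means: np.ndarray      # standardization over background, raw (mat, ap)
    feature_stds: np.ndarray
    hinge_knots: np.ndarray        # (2, N_HINGE_KNOTS) knots per variable (raw scale)
    var_ranges: np.ndarray         # (2, 2) background (min, max) per variable
    weights: np.ndarray
    reg_betas: np.ndarray
    log_z: float                   # log partition over training background
    entropy: float                 # entropy of the raw distribution over background
    n_background: int = 0
    output: str = "cloglog"        # or "logistic"

    def to_json(self) -> str:
        from dataclasses import fields
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        for k in ("feature_means", "feature_stds", "hinge_knots", "var_ranges",
                  "weights", "reg_betas"):
            d[k] = np.asarray(d[k])
        return cls(**d)


def _features(climate: np.ndarray, means, stds, knots, var_ranges) -> np.ndarray:
    """Quadratic + forward/reverse hinge design matrix for (n, 2) raw climate."""
    clipped = np.clip(climate, var_ranges[:, 0], var_ranges[:, 1])
    z = (clipped - means) / stds
    cols = [z, z**2]
    for v in range(2):
        x = clipped[:, v]
        lo, hi = var_ranges[v]
        k = knots[v]
        fwd = np.clip((x[:, None] - k[None, :]) / np.maximum(hi - k, 1e-12), 0, 1)
        rev = np.clip((k[None, :] - x[:, None]) / np.maximum(k - lo, 1e-12), 0, 1)
        cols.extend([fwd, rev])
    return np.column_stack(cols)


def fit_maxent(presences: OccurrenceSet, background: OccurrenceSet,
               grid: ClimateGrid, max_iter: int = 2500,
               reg_multiplier: float = 1.0, output: str = "cloglog") -> MaxEntModel:
    """L1-regularized maximum-entropy fit of presences against background.

    The model is a Gibbs distribution q_w(x) ~ exp(w . f(x)) over background
    cells; the penalized negative log-likelihood of the presence sample is
    minimized with per-feature penalties beta_j (quadratic-class multiplier
    interpolated by presence count, hinge-class 0.5), each scaled by
    s_j / sqrt(m) for m presences.
    """
    if len(presences.cells) < 5:
        raise ValueError("need at least 5 presences after thinning")
    bg_clim = grid.climate_at(background.cells)
    if np.ptp(bg_clim, axis=0).min() <= 0:
        raise ValueError("degenerate (constant) predictor layer")
    pr_clim = grid.climate_at(presences.cells)

    means = bg_clim.mean(axis=0)
    stds = bg_clim.std(axis=0)
    var_ranges = np.column_stack([bg_clim.min(axis=0), bg_clim.max(axis=0)])
    knots = np.stack([np.linspace(var_ranges[v, 0], var_ranges[v, 1],
                                  N_HINGE_KNOTS + 2)[1:-1] for v in range(2)])

    f_bg = _features(bg_clim, means, stds, knots, var_ranges)
    f_pr = _features(pr_clim, means, stds, knots, var_ranges)
    m, n_feat = len(f_pr), f_bg.shape[1]

    # regularization: first 4 features are the quadratic class, rest hinge
    quad_mult = np.interp(np.log10(max(m, 1)),
                          [1.0, 2.0], [1.0, 0.25])  # 10 presences -> 1.0, 100 -> 0.25
    betas = np.empty(n_feat)
    betas[:4] = quad_mult
    betas[4:] = 0.5
    s_j = np.maximum(f_bg.std(axis=0), 1e-6)
    # hinge bases active on few background points have tiny empirical spread;
    # floor their penalty scale at half the [0,1] feature range so boundary
    # knots cannot soak up sampling noise
    s_j[4:] = np.maximum(s_j[4:], 0.5)
    betas = reg_multiplier * betas * s_j / np.sqrt(m)

    mean_pr = f_pr.mean(axis=0)
    objective_trace: list[float] = []

    def negloglik(w):
        eta = f_bg @ w
        lz = _logsumexp(eta) - np.log(len(f_bg))
        return -(mean_pr @ w) + lz

    def obj(wsplit):
        w = wsplit[:n_feat] - wsplit[n_feat:]
        return negloglik(w) + betas @ (wsplit[:n_feat] + wsplit[n_feat:])

    def grad(wsplit):
        w = wsplit[:n_feat] - wsplit[n_feat:]
        eta = f_bg @ w
        p = np.exp(eta - _logsumexp(eta))
        g = -mean_pr + p @ f_bg
        return np.concatenate([g + betas, -g + betas])

    w0 = np.zeros(2 * n_feat)
    res = minimize(obj, w0, jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * n_feat),
                   callback=lambda x: objective_trace.append(obj(x)),
                   options={"maxiter": max_iter, "ftol": 1e-10})
    w = res.x[:n_feat] - res.x[n_feat:]

    eta_bg = f_bg @ w
    log_z = _logsumexp(eta_bg) - np.log(len(f_bg))
    raw = np.exp(eta_bg - _logsumexp(eta_bg))
    entropy = float(-(raw * np.log(np.maximum(raw, 1e-300))).sum())

    model = MaxEntModel(feature_means=means, feature_stds=stds, hinge_knots=knots,
                        var_ranges=var_ranges, weights=w, reg_betas=betas,
                        log_z=float(log_z), entropy=entropy,
                        n_background=len(f_bg), output=output)
    model.objective_trace = objective_trace  # optimizer contract, inspectable
    return model


def _logsumexp(x):
    m = np.max(x)
    return m + np.log(np.exp(x - m).sum())


@dataclass
class SuitabilityMap:
    values: np.ndarray
    mask: np.ndarray
    time_bp: float = 0.0


@dataclass
class BinaryMap:
    values: np.ndarray  # {0,1}; masked cells 0 with mask True
    mask: np.ndarray
    time_bp: float = 0.0


def suitability_of(model: MaxEntModel, climate: np.ndarray) -> np.ndarray:
    """Per-point suitability via the complementary log-log transform."""
    f = _features(np.atleast_2d(climate), model.feature_means, model.feature_stds,
                  model.hinge_knots, model.var_ranges)
    eta = f @ model.weights
    # raw_rel = N_bg * raw(x) where raw() is the Gibbs density over the
    # background sample.  The output transforms rescale raw by exp(H) so a
    # featureless model maps to ~0.632 (cloglog) / 0.5 (logistic).
    raw_rel = np.exp(eta - model.log_z)
    r = raw_rel * np.exp(model.entropy) / max(model.n_background, 1)
    if model.output == "logistic":
        return np.clip(r / (1.0 + r), 0.0, 1.0)
    return np.clip(1.0 - np.exp(-r), 0.0, 1.0)


def project_suitability(model: MaxEntModel, grid: ClimateGrid) -> SuitabilityMap:
    clim = np.column_stack([grid.mat.ravel(), grid.ap.ravel()])
    s = suitability_of(model, clim).reshape(grid.shape)
    s = np.where(grid.mask, np.nan, s)
    return SuitabilityMap(values=s, mask=grid.mask.copy(), time_bp=grid.time_bp)


def maxsss_threshold(presence_suit: np.ndarray, background_suit: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity over presence candidates.

    Background points stand in for absences; ties break to the lowest
    threshold so binary ranges err inclusive.
    """
    presence_suit = np.asarray(presence_suit, dtype=float)
    background_suit = np.asarray(background_suit, dtype=float)
    if presence_suit.size == 0 or background_suit.size == 0:
        raise ValueError("empty suitability series")
    best_thr, best_score = None, -np.inf
    for thr in np.unique(presence_suit):
        sens = float((presence_suit >= thr).mean())
        spec = float((background_suit < thr).mean())
        score = sens + spec
        if score > best_score + 1e-12:
            best_score, best_thr = score, float(thr)
    return best_thr


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    vals = np.where(np.isnan(smap.values), 0, (smap.values >= threshold).astype(int))
    return BinaryMap(values=vals, mask=smap.mask.copy(), time_bp=smap.time_bp)


def cooccurrence(maps: list[BinaryMap]) -> BinaryMap:
    """Per-cell product of binary presence maps (range intersection)."""
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("geometry mismatch")
    vals = np.ones(shape, dtype=int)
    mask = np.zeros(shape, dtype=bool)
    for m in maps:
        vals *= m.values.astype(int)
        mask |= m.mask
    vals[mask] = 0
    return BinaryMap(values=vals, mask=mask, time_bp=maps[0].time_bp)


def combine_period(slices: list[BinaryMap], rule: str = "union",
                   frequency: float = 0.5) -> BinaryMap:
    """Combine per-slice maps into one per-period map (default union)."""
    if not slices:
        raise ValueError("empty slice list")
    shape = slices[0].values.shape
    for m in slices:
        if m.values.shape != shape:
            raise ValueError("geometry mismatch")
    stack = np.stack([m.values for m in slices])
    mask = np.logical_and.reduce([m.mask for m in slices])
    if rule == "union":
        vals = stack.max(axis=0)
    elif rule == "intersection":
        vals = stack.min(axis=0)
    elif rule == "frequency":
        vals = (stack.mean(axis=0) >= frequency).astype(int)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    vals = np.where(mask, 0, vals)
    return BinaryMap(values=vals, mask=mask, time_bp=slices[0].time_bp)
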