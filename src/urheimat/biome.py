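"""Biome binning of pollen sites, the multinomial biome-climate model, and
society-biome association mapping.

Dated fossil-pollen/land-cover sites are binned into 8 biomes by arboreal
pollen (AP) percentage: four forest classes (5-25, 25-50, 50-75, >75 % AP)
and, below 5 % AP, the open/barren classes Desert, Steppe, Tundra and
Glacier taken from the site's land-cover label.  A multinomial logistic
regression links biome to mean annual temperature and annual precipitation;
projecting it over climate grids yields per-slice biome maps, which combine
with a culture x period x biome association table to map where each past
society could live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from sklearn.linear_model import LogisticRegression

BIOMES = ["Desert", "Steppe", "Tundra", "Glacier",
          "AP_5_25", "AP_25_50", "AP_50_75", "AP_GT75"]
LOW_AP_LABELS = {"Desert", "Steppe", "Tundra", "Glacier"}
CULTURES = ["HG", "N", "CA", "BA", "IA"]


def assign_biome(ap_percent: float, low_ap_label: str | None = None) -> str:
    """AP-percentage binning: [5,25) [25,50) [50,75] (75,100]; <5 uses the label.

    Boundaries are lower-inclusive at 5/25/50; 75 belongs to the 50-75 class
    and strictly greater than 75 to the top class.
    """
    if not 0.0 <= ap_percent <= 100.0:
        raise ValueError(f"ap_percent out of range: {ap_percent}")
    if ap_percent < 5.0:
        if low_ap_label is None:
            raise ValueError("ap_percent < 5 requires a low-AP land-cover label")
        if low_ap_label not in LOW_AP_LABELS:
            raise ValueError(f"unknown low-AP label {low_ap_label!r}")
        return low_ap_label
    if ap_percent < 25.0:
        return "AP_5_25"
    if ap_percent < 50.0:
        return "AP_25_50"
    if ap_percent <= 75.0:
        return "AP_50_75"
    return "AP_GT75"


@dataclass
class PollenSite:
    row: int
    col: int
    date_bp: float
    ap_percent: float
    biome: str
    mat: float
    ap_mm: float
    low_ap_label: str | None = None

    def __post_init__(self):
        expect = assign_biome(self.ap_percent, self.low_ap_label)
        if expect != self.biome:
            raise ValueError(
                f"biome {self.biome!r} inconsistent with ap_percent {self.ap_percent}"
            )


@dataclass
class BiomeModel:
    classes: list[str]
    coef: np.ndarray          # (n_classes, 3): intercept, mat, ap (raw scale)
    reference_class: str
    means: np.ndarray
    stds: np.ndarray

    def predict_proba(self, climate: np.ndarray) -> np.ndarray:
        climate = np.atleast_2d(np.asarray(climate, dtype=float))
        eta = self.coef[:, 0] + climate @ self.coef[:, 1:].T
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, climate: np.ndarray) -> list[str]:
        proba = self.predict_proba(climate)
        return [self.classes[i] for i in proba.argmax(axis=1)]


def fit_multinomial(sites: list[PollenSite], max_coef: float = 30.0) -> BiomeModel:
    """Maximum-likelihood softmax fit of biome on (MAT, AP) climate.

    Predictors are standardized internally; coefficients are returned on the
    raw scale and re-based so the reference (first observed) class is zero.
    Complete separation is flagged and coefficients capped at |coef| <= 30
    on the standardized scale.
    """
    if not sites:
        raise ValueError("no sites")
    labels = [s.biome for s in sites]
    classes = sorted(set(labels), key=BIOMES.index)
    if len(classes) < 2:
        raise ValueError("need at least 2 biome classes to fit")
    x = np.array([[s.mat, s.ap_mm] for s in sites], dtype=float)
    means, stds = x.mean(axis=0), x.std(axis=0)
    stds = np.where(stds > 0, stds, 1.0)
    z = (x - means) / stds
    y = np.array([classes.index(b) for b in labels])

    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000, tol=1e-8)
    clf.fit(z, y)

    coef_z = np.zeros((len(classes), 3))
    if len(classes) == 2:
        coef_z[1, 0] = clf.intercept_[0]
        coef_z[1, 1:] = clf.coef_[0]
    else:
        coef_z[:, 0] = clf.intercept_
        coef_z[:, 1:] = clf.coef_
    if np.abs(coef_z).max() > max_coef:
        warnings.warn("separation suspected; coefficients capped", RuntimeWarning)
        coef_z = np.clip(coef_z, -max_coef, max_coef)

    # un-standardize: eta = b0 + b.z = (b0 - b.mu/sd) + (b/sd).x
    coef = np.zeros_like(coef_z)
    coef[:, 1:] = coef_z[:, 1:] / stds
    coef[:, 0] = coef_z[:, 0] - (coef_z[:, 1:] / stds) @ means
    coef -= coef[0]  # zero reference class
    return BiomeModel(classes=classes, coef=coef, reference_class=classes[0],
                      means=means, stds=stds)


def classification_metrics(model: BiomeModel, sites: list[PollenSite]) -> dict:
    """Accuracy, Cohen's kappa, per-class accuracy and the confusion matrix."""
    if not sites:
        raise ValueError("no sites")
    x = np.array([[s.mat, s.ap_mm] for s in sites])
    truth = [s.biome for s in sites]
    pred = model.predict(x)
    classes = model.classes
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        cm[classes.index(t), classes.index(p)] += 1
    return confusion_metrics(cm, classes)


def confusion_metrics(cm: np.ndarray, classes: list[str] | None = None) -> dict:
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    row_tot = cm.sum(axis=1)
    per_class = np.divide(np.diag(cm), row_tot, out=np.zeros(len(cm)),
                          where=row_tot > 0)
    return {
        "accuracy": float(p_o),
        "cohen_kappa": float(kappa),
        "per_class_accuracy": {
            (classes[i] if classes else i): float(per_class[i]) for i in range(len(cm))
        },
        "confusion_matrix": cm.astype(int),
    }


def project_biome_map(model: BiomeModel, grid) -> np.ndarray:
    """Per-cell argmax biome class index (into model.classes); masked -> -1."""
    clim = np.column_stack([grid.mat.ravel(), grid.ap.ravel()])
    proba = model.predict_proba(clim)
    out = proba.argmax(axis=1).reshape(grid.shape)
    return np.where(grid.mask, -1, out)


# -- society-biome table -----------------------------------------------------


@dataclass
class SocietyBiomeTable:
    windows: list[tuple[float, float]]          # (older, younger) BP, ordered
    associations: dict[tuple[int, str], frozenset[str]]

    def window_of(self, time_bp: float) -> int:
        for i, (older, younger) in enumerate(self.windows):
            if younger <= time_bp <= older:
                return i
        raise ValueError(f"time {time_bp} BP outside all windows")

    def biomes_for(self, time_bp: float, culture: str) -> frozenset[str]:
        if culture not in CULTURES:
            raise ValueError(f"unknown culture {culture!r}")
        return self.associations[(self.window_of(time_bp), culture)]


def load_society_biome_table(path=None, extend_final_to_1500: bool = False) -> SocietyBiomeTable:
    """Load the packaged association table (or a YAML with the same layout)."""
    if path is None:
        text = (resources.files("urheimat") / "data"
                / "society_biome_table.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    windows, assoc = [], {}
    for i, block in enumerate(raw["windows"]):
        older, younger = float(block["span"][0]), float(block["span"][1])
        windows.append((older, younger))
        for culture in CULTURES:
            assoc[(i, culture)] = frozenset(block.get(culture) or [])
    if extend_final_to_1500:
        older, _ = windows[-1]
        windows[-1] = (older, 1500.0)
    return SocietyBiomeTable(windows=windows, associations=assoc)


def society_map(biome_raster: np.ndarray, classes: list[str], time_bp: float,
                culture: str, table: SocietyBiomeTable):
    """Binary suitability: 1 where the cell's biome is associated with the culture."""
    from .niche import BinaryMap  # local import to avoid a cycle

    wanted = table.biomes_for(time_bp, culture)
    idx = {i for i, c in enumerate(classes) if c in wanted}
    vals = np.isin(biome_raster, list(idx)).astype(int) if idx else np.zeros_like(biome_raster)
    mask = biome_raster < 0
    vals = np.where(mask, 0, vals)
    return BinaryMap(values=vals, mask=mask, time_bp=time_bp)


def aggregate_mode(rasters: list[np.ndarray]) -> np.ndarray:
    """Per-cell modal value across slices; ties resolve to the earliest slice."""
    if not rasters:
        raise ValueError("empty raster list")
    stack = np.stack(rasters)
    out = np.empty(stack.shape[1:], dtype=stack.dtype)
    flat = stack.reshape(len(rasters), -1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        values, counts = np.unique(col, return_counts=True)
        best = counts.max()
        winners = set(values[counts == best])
        for v in col:  # earliest slice wins ties
            if v in winners:
                out.flat[j] = v
                break
    return out


@dataclass
class CultureSiteRecord:
    row: int
    col: int
    date_bp: float
    culture: str


def culture_biome_crosstab(sites: list[CultureSiteRecord],
                           biome_rasters: dict[float, np.ndarray],
                           classes: list[str],
                           windows: list[tuple[float, float]],
                           cutoff: float = 0.05):
    """Count each culture's sites per biome per window; derive associations.

    ``biome_rasters`` maps slice time (BP) to class-index rasters; each site
    uses the nearest slice.  Off-grid sites are skipped and reported.
    Associations with site fraction >= cutoff form a derived table.
    """
    slice_times = np.array(sorted(biome_rasters))
    counts: dict[tuple[int, str, str], int] = {}
    totals: dict[tuple[int, str], int] = {}
    skipped = 0
    for s in sites:
        widx = None
        for i, (older, younger) in enumerate(windows):
            if younger <= s.date_bp <= older:
                widx = i
                break
        if widx is None:
            skipped += 1
            continue
        t = slice_times[np.argmin(np.abs(slice_times - s.date_bp))]
        raster = biome_rasters[float(t)]
        r, c = raster.shape
        if not (0 <= s.row < r and 0 <= s.col < c) or raster[s.row, s.col] < 0:
            skipped += 1
            continue
        biome = classes[raster[s.row, s.col]]
        counts[(widx, s.culture, biome)] = counts.get((widx, s.culture, biome), 0) + 1
        totals[(widx, s.culture)] = totals.get((widx, s.culture), 0) + 1

    fractions = {
        key: counts[key] / totals[(key[0], key[1])] for key in counts
    }
    associations = {
        (w, cu): frozenset(
            b for b in classes if fractions.get((w, cu, b), 0.0) >= cutoff
        )
        for w in range(len(windows))
        for cu in CULTURES
    }
    derived = SocietyBiomeTable(windows=list(windows), associations=associations)
    return {"counts": counts, "fractions": fractions, "skipped": skipped,
            "total_used": sum(totals.values()), "derived_table": derived}
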