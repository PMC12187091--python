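"""Reliability filtering, batch harmonization and feature selection.

Stages, in pipeline order: segmentation agreement (Dice / Hausdorff) and ICC
reliability filtering against a re-segmentation, parametric empirical-Bayes
ComBat harmonization across sites, mean normalization (train-learned), greedy
Pearson redundancy pruning at |r| > 0.99, and one-way ANOVA F ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.feature_selection import f_classif


# ---------------------------------------------------------------------------
# Segmentation agreement
# ---------------------------------------------------------------------------

def segmentation_agreement(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, float]:
    """Dice coefficient and classical (max-min) Hausdorff distance in mm.

    Surfaces are the mask voxels with at least one 6-neighbor outside; the
    Hausdorff distance is the symmetric maximum over both directed
    surface-to-surface distances, measured between voxel centers in world
    units.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    if not a.any() and not b.any():
        raise ValueError("both masks empty: agreement undefined")
    inter = np.count_nonzero(a & b)
    dice = 2.0 * inter / (np.count_nonzero(a) + np.count_nonzero(b))
    if not a.any() or not b.any():
        return dice, float("inf")

    def surface(m: np.ndarray) -> np.ndarray:
        eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(3, 1))
        pts = np.argwhere(m & ~eroded)
        if pts.size == 0:  # single-voxel or thin mask
            pts = np.argwhere(m)
        return pts * np.asarray(spacing)

    pa, pb = surface(a), surface(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(dice), float(max(d_ab, d_ba))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc(measurements: np.ndarray, form: str = "icc2") -> float:
    """Single-measure two-way ICC from the ANOVA mean-squares decomposition.

    ``measurements`` is cases x raters.  ``form="icc2"`` is the two-way
    random-effects absolute-agreement ICC(2,1) (inter-reader); ``"icc3"`` the
    two-way mixed-effects consistency ICC(3,1) (intra-reader).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        warnings.warn("zero between-case variance: ICC set to 0")
        return 0.0
    if form == "icc3":
        denom = msr + (k - 1) * mse
    elif form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError("form must be 'icc2' or 'icc3'")
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


@dataclass
class ReliabilityReport:
    """Per-feature ICCs plus per-case segmentation agreement."""

    intra_icc: pd.Series
    inter_icc: pd.Series
    dice: pd.Series
    hausdorff_mm: pd.Series

    def reliable_features(self, threshold: float = 0.75) -> list[str]:
        keep = (self.intra_icc >= threshold) & (self.inter_icc >= threshold)
        return list(self.intra_icc.index[keep])


def reliability_filter(
    reader1: pd.DataFrame,
    reader1_repeat: pd.DataFrame,
    reader2: pd.DataFrame,
    threshold: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """Features with intra-reader ICC(3,1) and inter-reader ICC(2,1) >= threshold."""
    cols = reader1.columns
    intra = {}
    inter = {}
    for c in cols:
        intra[c] = icc(np.column_stack([reader1[c], reader1_repeat[c]]), "icc3")
        inter[c] = icc(np.column_stack([reader1[c], reader2[c]]), "icc2")
    report = pd.DataFrame({"intra_icc": pd.Series(intra), "inter_icc": pd.Series(inter)})
    keep = [c for c in cols if intra[c] >= threshold and inter[c] >= threshold]
    return keep, report


# ---------------------------------------------------------------------------
# ComBat harmonization
# ---------------------------------------------------------------------------

def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m ** 2) / s2 if s2 > 0 else 2.0


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m ** 3) / s2 if s2 > 0 else m


def combat(
    features: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    *,
    location_shrinkage: bool = False,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch harmonization.

    The ComBat model: per feature, data are standardized by the grand mean
    and pooled variance; per-batch additive (gamma) and multiplicative
    (delta^2) effects are estimated and removed, with the variance effects
    shrunk toward a parametric inverse-gamma prior by the iterative EB solve.

    By default the additive effects are removed exactly (``gamma_hat``), so
    post-harmonization batch means equalize to the preserved feature grand
    mean up to float round-off; ``location_shrinkage=True`` additionally
    shrinks the additive effects toward their normal prior (the textbook EB
    location update), which trades exact mean equalization for lower-variance
    estimates in small batches.  Every batch needs >= 2 samples.  Constant
    features are passed through unchanged.
    """
    x = features.to_numpy(dtype=float).T  # features x samples
    batch = np.asarray(batch)
    if batch.shape[0] != features.shape[0]:
        raise ValueError("batch labels must match sample count")
    levels, counts = np.unique(batch, return_counts=True)
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"batch(es) {list(bad)} have fewer than 2 samples")
    g, n = x.shape
    n_batch = len(levels)
    onehot = np.stack([batch == b for b in levels]).astype(float)  # B x n

    batch_means = (onehot @ x.T) / counts[:, None]  # B x g
    grand = (counts / n) @ batch_means  # g
    resid = x - batch_means.T @ onehot
    var_pooled = (resid ** 2).sum(axis=1) / n  # g
    keep = var_pooled > 0
    z = np.zeros_like(x)
    sd = np.sqrt(var_pooled[keep])
    z[keep] = (x[keep] - grand[keep, None]) / sd[:, None]

    out = x.copy()
    if keep.sum() > 0:
        zk = z[keep]
        gamma_hat = (onehot @ zk.T) / counts[:, None]  # B x g'
        # population variance: consistent with the pooled-variance
        # standardization, so a single batch round-trips exactly
        delta_hat = np.stack(
            [zk[:, batch == b].var(axis=1, ddof=0) for b in levels]
        )  # B x g'
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for bi in range(n_batch):
            g_hat = gamma_hat[bi]
            d_hat = np.maximum(delta_hat[bi], 1e-12)
            if g_hat.size < 2:
                gamma_star[bi], delta_star[bi] = g_hat, d_hat
                continue
            g_bar, t2 = g_hat.mean(), g_hat.var()
            a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)
            nb = counts[bi]
            g_new, d_new = g_hat.copy(), d_hat.copy()
            zb = zk[:, batch == levels[bi]]
            for _ in range(100):
                if t2 > 0:
                    g_upd = (nb * t2 * g_hat + d_new * g_bar) / (nb * t2 + d_new)
                else:
                    g_upd = np.full_like(g_hat, g_bar)
                ss = ((zb - g_upd[:, None]) ** 2).sum(axis=1)
                d_upd = (0.5 * ss + b_pr) / (nb / 2.0 + a_pr - 1.0)
                change = max(
                    np.abs(g_upd - g_new).max(initial=0),
                    np.abs(d_upd - d_new).max(initial=0),
                )
                g_new, d_new = g_upd, d_upd
                if change < 1e-8:
                    break
            gamma_star[bi], delta_star[bi] = g_new, np.maximum(d_new, 1e-12)
        if not location_shrinkage:
            gamma_star = gamma_hat
        adj = zk.copy()
        for bi, b in enumerate(levels):
            sel = batch == b
            adj[:, sel] = (zk[:, sel] - gamma_star[bi][:, None]) / np.sqrt(
                delta_star[bi]
            )[:, None]
        out[keep] = adj * sd[:, None] + grand[keep, None]
    return pd.DataFrame(out.T, index=features.index, columns=features.columns)


# ---------------------------------------------------------------------------
# Normalization / pruning / ranking
# ---------------------------------------------------------------------------

class MeanNormalizer:
    """(x - mean) / (max - min), parameters learned on training rows."""

    def fit(self, X: pd.DataFrame) -> "MeanNormalizer":
        self.mean_ = X.mean(axis=0)
        self.range_ = X.max(axis=0) - X.min(axis=0)
        constant = self.range_ == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature(s) mapped to 0 by mean normalization"
            )
        self.range_ = self.range_.replace(0, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.mean_) / self.range_

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def mean_normalize(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    norm = MeanNormalizer().fit(train)
    if test is None:
        return norm.transform(train)
    return norm.transform(train), norm.transform(test)


def pearson_prune(features: pd.DataFrame, threshold: float = 0.99) -> list[str]:
    """Greedy redundancy pruning in catalog (column) order.

    Walk columns left to right; drop a candidate when |Pearson r| with any
    already-kept column exceeds ``threshold``.  Deterministic.
    """
    if features.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    x = features.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    kept: list[int] = []
    for j in range(features.shape[1]):
        if kept and np.any(np.abs(corr[j, kept]) > threshold):
            continue
        kept.append(j)
    return [features.columns[j] for j in kept]


def anova_rank(
    features: pd.DataFrame, labels: np.ndarray | pd.Series, k: int
) -> list[str]:
    """Top-k features by one-way ANOVA F statistic (ties broken by column order)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or (counts < 2).any():
        raise ValueError("need two classes with >= 2 samples each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, _ = f_classif(features.to_numpy(dtype=float), y)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    order = np.argsort(-f_stat, kind="stable")
    return [features.columns[j] for j in order[:k]]
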