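"""Gray-level texture features on a discretized ROI.

Implements the co-occurrence (GLCM), run-length (GLRLM) and dependence (GLDM)
matrix families plus first-order statistics, following the standard IBSI-style
formulations:

* GLCM: symmetric matrices at Chebyshev distance 1 over the 13 unique 3-D
  directions, each normalized; features computed per direction and averaged.
  Logarithms are base 2 with the 0*log(0) = 0 convention.
* GLRLM: run matrices per direction (runs = maximal same-level segments along
  the direction restricted to the ROI), features averaged over directions.
* GLDM: dependence size of a voxel = 1 + number of its 26-neighbors inside the
  ROI with exactly the same level (similarity tolerance 0; self-inclusive, so
  an isolated voxel has dependence 1 and the center of a constant 3x3x3 ROI
  has dependence 27).
* First-order: computed on raw (non-discretized) ROI intensities; Entropy and
  Uniformity use a fixed-bin-count histogram (default 25 bins) of those
  intensities.  Kurtosis is the raw fourth standardized moment (3 for a
  normal distribution), Skewness the third; both are reported as 0 for a
  constant ROI.
"""

from __future__ import annotations

import numpy as np

from .types import DiscretizedROI, ImageVolume

#: 13 unique 3-D directions (half of the 26-neighborhood).
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx == 0 and ((dy, dz) > (0, 0)))
)
# The comprehension above keeps exactly one of each +/- offset pair.
assert len(DIRECTIONS_13) == 13

#: All 26 neighbor offsets.
OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_FEATURES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLDM_FEATURES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
FIRSTORDER_FEATURES = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
)


def _shifted_views(shape, off):
    """Slices selecting (center, neighbor) so neighbor = center + off."""
    sl_c, sl_n = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            sl_c.append(slice(0, n - o))
            sl_n.append(slice(o, n))
        else:
            sl_c.append(slice(-o, n))
            sl_n.append(slice(0, n + o))
    return tuple(sl_c), tuple(sl_n)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(d: DiscretizedROI) -> list[np.ndarray]:
    """Normalized symmetric co-occurrence matrix per direction (skips empty)."""
    ng = d.n_bins
    mats = []
    for off in DIRECTIONS_13:
        sl_c, sl_n = _shifted_views(d.levels.shape, off)
        valid = d.mask[sl_c] & d.mask[sl_n]
        if not valid.any():
            continue
        i = d.levels[sl_c][valid] - 1
        j = d.levels[sl_n][valid] - 1
        m = np.zeros((ng, ng))
        np.add.at(m, (i, j), 1.0)
        np.add.at(m, (j, i), 1.0)
        mats.append(m / m.sum())
    return mats


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    lv = np.arange(1, ng + 1, dtype=float)
    ii = lv[:, None]
    jj = lv[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(np.sum(lv * px))
    uy = float(np.sum(lv * py))
    sigx = float(np.sqrt(np.sum((lv - ux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((lv - uy) ** 2 * py)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(ng)
    idx_i, idx_j = np.nonzero(p)
    np.add.at(p_sum, idx_i + idx_j, p[idx_i, idx_j])
    np.add.at(p_diff, np.abs(idx_i - idx_j), p[idx_i, idx_j])

    hxy = float(-_xlog2x(p).sum())
    pxpy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(pxpy[nz])))
    hxy2 = float(-_xlog2x(pxpy).sum())
    hx = float(-_xlog2x(px).sum())
    hy = float(-_xlog2x(py).sum())

    diff_avg = float(np.sum(k_diff * p_diff))
    feats = {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum((ii + jj - ux - uy) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - ux - uy) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - ux - uy) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": 1.0 if sigx * sigy == 0
        else float((np.sum(ii * jj * p) - ux * uy) / (sigx * sigy)),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-_xlog2x(p_diff).sum()),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p_diff / (1.0 + k_diff))),
        "Idm": float(np.sum(p_diff / (1.0 + k_diff ** 2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (k_diff / ng) ** 2))),
        "Idn": float(np.sum(p_diff / (1.0 + k_diff / ng))),
        "Imc1": 0.0 if max(hx, hy) == 0 else float((hxy - hxy1) / max(hx, hy)),
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "InverseVariance": float(np.sum(p_diff[1:] / k_diff[1:] ** 2)) if ng > 1 else 0.0,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-_xlog2x(p_sum).sum()),
        "SumSquares": float(np.sum((ii - ux) ** 2 * p)),
    }
    # Maximal correlation coefficient: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k p(i,k) p(j,k) / (px_i py_k), on the support of px.
    present = px > 0
    if present.sum() <= 1:
        feats["MCC"] = 1.0
    else:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        pys = py[present]
        q = (ps / pxs[:, None]) @ (ps / pys[None, :]).T
        eig = np.linalg.eigvals(q)
        eig = np.sort(np.abs(eig))[::-1]
        feats["MCC"] = float(np.sqrt(max(0.0, eig[1].real))) if eig.size > 1 else 1.0
    return feats


def glcm_features(d: DiscretizedROI) -> dict[str, float]:
    """Direction-averaged GLCM features (feature-then-average aggregation)."""
    mats = glcm_matrices(d)
    if not mats:
        raise ValueError("no voxel pairs in ROI: GLCM undefined")
    per_dir = [_glcm_single(p) for p in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrices(d: DiscretizedROI) -> list[np.ndarray]:
    """Run-length matrix P(level, run length) per direction."""
    levels, mask = d.levels, d.mask
    ng = d.n_bins
    shape = np.asarray(levels.shape)
    mats = []
    for off in DIRECTIONS_13:
        offa = np.asarray(off)
        # A run starts at voxels whose backward neighbor is absent or differs.
        sl_c, sl_n = _shifted_views(levels.shape, off)
        cont = np.zeros(levels.shape, dtype=bool)
        # cont[neighbor] = True when neighbor continues a run from center
        cont[sl_n] = mask[sl_c] & mask[sl_n] & (levels[sl_c] == levels[sl_n])
        starts = np.argwhere(mask & ~cont)
        run_levels = levels[tuple(starts.T)]
        pos = starts
        lengths = np.ones(len(starts), dtype=np.int64)
        active = np.ones(len(starts), dtype=bool)
        counts: dict[tuple[int, int], int] = {}
        while active.any():
            nxt = pos[active] + offa
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            ok = np.zeros(inb.shape, dtype=bool)
            if inb.any():
                t = tuple(nxt[inb].T)
                ok[inb] = mask[t] & (levels[t] == run_levels[active][inb])
            act_idx = np.flatnonzero(active)
            done = act_idx[~ok]
            for idx in done:
                key = (int(run_levels[idx]), int(lengths[idx]))
                counts[key] = counts.get(key, 0) + 1
            cont_idx = act_idx[ok]
            pos[cont_idx] += offa
            lengths[cont_idx] += 1
            active[done] = False
        if not counts:
            continue
        lmax = max(k[1] for k in counts)
        m = np.zeros((ng, lmax))
        for (g, l), c in counts.items():
            m[g - 1, l - 1] = c
        mats.append(m)
    return mats


def _glrlm_single(m: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = m.sum()
    p = m / nr
    ng, lmax = m.shape
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    jv = np.arange(1, lmax + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pr = p.sum(axis=0)
    mu_i = float(np.sum(iv[:, 0] * pg))
    mu_j = float(np.sum(jv[0, :] * pr))
    return {
        "ShortRunEmphasis": float(np.sum(p / jv ** 2)),
        "LongRunEmphasis": float(np.sum(p * jv ** 2)),
        "GrayLevelNonUniformity": float(np.sum(m.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg ** 2)),
        "RunLengthNonUniformity": float(np.sum(m.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(pr ** 2)),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (iv - mu_i) ** 2)),
        "RunVariance": float(np.sum(p * (jv - mu_j) ** 2)),
        "RunEntropy": float(-_xlog2x(p).sum()),
        "LowGrayLevelRunEmphasis": float(np.sum(p / iv ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(p * iv ** 2)),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(p / (iv ** 2 * jv ** 2))),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(p * iv ** 2 / jv ** 2)),
        "LongRunLowGrayLevelEmphasis": float(np.sum(p * jv ** 2 / iv ** 2)),
        "LongRunHighGrayLevelEmphasis": float(np.sum(p * iv ** 2 * jv ** 2)),
    }


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    """Direction-averaged run-length features."""
    if not d.mask.any():
        raise ValueError("empty ROI")
    n_vox = int(d.mask.sum())
    mats = glrlm_matrices(d)
    per_dir = [_glrlm_single(m, n_vox) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Dependence matrix P(level, dependence size), sizes 1..27."""
    levels, mask = d.levels, d.mask
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        sl_c, sl_n = _shifted_views(levels.shape, off)
        eq = mask[sl_c] & mask[sl_n] & (levels[sl_c] == levels[sl_n])
        dep[sl_c] += eq
    dep = dep + 1  # self-inclusive convention
    g = levels[mask]
    s = dep[mask]
    m = np.zeros((d.n_bins, 27))
    np.add.at(m, (g - 1, s - 1), 1.0)
    return m[:, : s.max()]


def gldm_features(d: DiscretizedROI) -> dict[str, float]:
    if not d.mask.any():
        raise ValueError("empty ROI")
    m = gldm_matrix(d)
    nz = m.sum()
    p = m / nz
    ng, dmax = m.shape
    iv = np.arange(1, ng + 1, dtype=float)[:, None]
    jv = np.arange(1, dmax + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mu_i = float(np.sum(iv[:, 0] * pg))
    mu_j = float(np.sum(jv[0, :] * pd_))
    return {
        "SmallDependenceEmphasis": float(np.sum(p / jv ** 2)),
        "LargeDependenceEmphasis": float(np.sum(p * jv ** 2)),
        "GrayLevelNonUniformity": float(np.sum(m.sum(axis=1) ** 2) / nz),
        "DependenceNonUniformity": float(np.sum(m.sum(axis=0) ** 2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd_ ** 2)),
        "GrayLevelVariance": float(np.sum(p * (iv - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(p * (jv - mu_j) ** 2)),
        "DependenceEntropy": float(-_xlog2x(p).sum()),
        "LowGrayLevelEmphasis": float(np.sum(p / iv ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(p * iv ** 2)),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(p / (iv ** 2 * jv ** 2))),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(p * iv ** 2 / jv ** 2)),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(p * jv ** 2 / iv ** 2)),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(p * iv ** 2 * jv ** 2)),
    }


# ---------------------------------------------------------------------------
# First order
# ---------------------------------------------------------------------------

def firstorder_features(
    vol: ImageVolume | np.ndarray,
    mask: np.ndarray,
    n_bins: int = 25,
) -> dict[str, float]:
    """First-order statistics on raw ROI intensities."""
    values = vol.values if isinstance(vol, ImageVolume) else np.asarray(vol, dtype=float)
    voxvol = vol.voxel_volume if isinstance(vol, ImageVolume) else 1.0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI")
    x = values[mask].astype(float)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd ** 3)
        kurt = float(np.mean((x - mean) ** 4) / sd ** 4)
    else:
        skew = kurt = 0.0
    # Entropy / Uniformity on a fixed-bin-count histogram of the raw values.
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    else:
        hist = np.array([n])
    ph = hist / n
    energy = float(np.sum(x ** 2))
    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": float(-_xlog2x(ph).sum()),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "TotalEnergy": energy * voxvol,
        "Uniformity": float(np.sum(ph ** 2)),
        "Variance": var,
    }
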