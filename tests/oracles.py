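"""Independent brute-force oracles used by the tests.

Everything here is written as plain, slow enumeration over voxels/pairs/runs,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _in(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def glcm_matrix_brute(levels, mask, n_bins, direction):
    """Symmetric normalized co-occurrence matrix for one direction."""
    m = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for p in itertools.product(*(range(s) for s in shape)):
        if not mask[p]:
            continue
        q = tuple(c + d for c, d in zip(p, direction))
        if _in(shape, q) and mask[q]:
            i, j = levels[p] - 1, levels[q] - 1
            m[i, j] += 1
            m[j, i] += 1
    s = m.sum()
    return m / s if s else m


def glrlm_matrix_brute(levels, mask, n_bins, direction):
    """Run-length counts {(level, length): count} for one direction."""
    shape = levels.shape
    runs = {}
    for p in itertools.product(*(range(s) for s in shape)):
        if not mask[p]:
            continue
        prev = tuple(c - d for c, d in zip(p, direction))
        if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        cur = p
        while True:
            nxt = tuple(c + d for c, d in zip(cur, direction))
            if _in(shape, nxt) and mask[nxt] and levels[nxt] == levels[p]:
                length += 1
                cur = nxt
            else:
                break
        key = (int(levels[p]), length)
        runs[key] = runs.get(key, 0) + 1
    if not runs:
        return np.zeros((n_bins, 1))
    lmax = max(k[1] for k in runs)
    m = np.zeros((n_bins, lmax))
    for (g, l), c in runs.items():
        m[g - 1, l - 1] = c
    return m


def gldm_matrix_brute(levels, mask, n_bins):
    """Dependence counts P(level, 1 + #equal 26-neighbors)."""
    shape = levels.shape
    entries = {}
    offsets = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    for p in itertools.product(*(range(s) for s in shape)):
        if not mask[p]:
            continue
        dep = 1
        for o in offsets:
            q = tuple(c + d for c, d in zip(p, o))
            if _in(shape, q) and mask[q] and levels[q] == levels[p]:
                dep += 1
        key = (int(levels[p]), dep)
        entries[key] = entries.get(key, 0) + 1
    dmax = max(k[1] for k in entries)
    m = np.zeros((n_bins, dmax))
    for (g, d), c in entries.items():
        m[g - 1, d - 1] = c
    return m


# ---------------------------------------------------------------------------
# Feature formulas from a matrix (independent re-derivation)
# ---------------------------------------------------------------------------

def _x2(v):
    return 0.0 if v <= 0 else v * math.log2(v)


def glcm_features_brute(p):
    ng = p.shape[0]
    feats = {}
    idx = [(i, j) for i in range(ng) for j in range(ng)]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    ux = sum((i + 1) * px[i] for i in range(ng))
    uy = sum((j + 1) * py[j] for j in range(ng))
    sx = math.sqrt(sum((i + 1 - ux) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - uy) ** 2 * py[j] for j in range(ng)))
    psum = {}
    pdiff = {}
    for i, j in idx:
        psum[i + j + 2] = psum.get(i + j + 2, 0) + p[i, j]
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0) + p[i, j]
    feats["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i, j in idx)
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3), ("ClusterProminence", 4)):
        feats[name] = sum((i + 1 + j + 1 - ux - uy) ** power * p[i, j] for i, j in idx)
    feats["Contrast"] = sum((i - j) ** 2 * p[i, j] for i, j in idx)
    feats["Correlation"] = 1.0 if sx * sy == 0 else (
        (feats["Autocorrelation"] - ux * uy) / (sx * sy))
    da = sum(k * v for k, v in pdiff.items())
    feats["DifferenceAverage"] = da
    feats["DifferenceEntropy"] = -sum(_x2(v) for v in pdiff.values())
    feats["DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    feats["Id"] = sum(v / (1 + k) for k, v in pdiff.items())
    feats["Idm"] = sum(v / (1 + k ** 2) for k, v in pdiff.items())
    feats["Idmn"] = sum(v / (1 + (k / ng) ** 2) for k, v in pdiff.items())
    feats["Idn"] = sum(v / (1 + k / ng) for k, v in pdiff.items())
    hxy = -sum(_x2(p[i, j]) for i, j in idx)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i, j in idx if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(_x2(px[i] * py[j]) for i, j in idx)
    hx = -sum(_x2(v) for v in px)
    hy = -sum(_x2(v) for v in py)
    feats["Imc1"] = 0.0 if max(hx, hy) == 0 else (hxy - hxy1) / max(hx, hy)
    feats["Imc2"] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    feats["InverseVariance"] = sum(v / k ** 2 for k, v in pdiff.items() if k > 0)
    feats["JointAverage"] = ux
    feats["JointEnergy"] = sum(p[i, j] ** 2 for i, j in idx)
    feats["JointEntropy"] = hxy
    feats["MaximumProbability"] = max(p[i, j] for i, j in idx)
    feats["SumAverage"] = sum(k * v for k, v in psum.items())
    feats["SumEntropy"] = -sum(_x2(v) for v in psum.values())
    feats["SumSquares"] = sum((i + 1 - ux) ** 2 * p[i, j] for i, j in idx)
    present = [i for i in range(ng) if px[i] > 0]
    if len(present) <= 1:
        feats["MCC"] = 1.0
    else:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k])
                    for k in range(ng) if py[k] > 0
                )
        eig = sorted(np.abs(np.linalg.eigvals(q)), reverse=True)
        feats["MCC"] = math.sqrt(max(0.0, eig[1].real))
    return feats


def glrlm_features_brute(m, n_voxels):
    nr = m.sum()
    ng, lmax = m.shape
    p = m / nr
    cells = [(i, j) for i in range(ng) for j in range(lmax)]
    mu_i = sum((i + 1) * p[i, j] for i, j in cells)
    mu_j = sum((j + 1) * p[i, j] for i, j in cells)
    return {
        "ShortRunEmphasis": sum(p[i, j] / (j + 1) ** 2 for i, j in cells),
        "LongRunEmphasis": sum(p[i, j] * (j + 1) ** 2 for i, j in cells),
        "GrayLevelNonUniformity": sum(m[i, :].sum() ** 2 for i in range(ng)) / nr,
        "GrayLevelNonUniformityNormalized": sum(p[i, :].sum() ** 2 for i in range(ng)),
        "RunLengthNonUniformity": sum(m[:, j].sum() ** 2 for j in range(lmax)) / nr,
        "RunLengthNonUniformityNormalized": sum(p[:, j].sum() ** 2 for j in range(lmax)),
        "RunPercentage": nr / n_voxels,
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * p[i, j] for i, j in cells),
        "RunVariance": sum((j + 1 - mu_j) ** 2 * p[i, j] for i, j in cells),
        "RunEntropy": -sum(_x2(p[i, j]) for i, j in cells),
        "LowGrayLevelRunEmphasis": sum(p[i, j] / (i + 1) ** 2 for i, j in cells),
        "HighGrayLevelRunEmphasis": sum(p[i, j] * (i + 1) ** 2 for i, j in cells),
        "ShortRunLowGrayLevelEmphasis": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i, j in cells),
        "ShortRunHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i, j in cells),
        "LongRunLowGrayLevelEmphasis": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i, j in cells),
        "LongRunHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i, j in cells),
    }


def gldm_features_brute(m):
    nz = m.sum()
    ng, dmax = m.shape
    p = m / nz
    cells = [(i, j) for i in range(ng) for j in range(dmax)]
    mu_i = sum((i + 1) * p[i, j] for i, j in cells)
    mu_j = sum((j + 1) * p[i, j] for i, j in cells)
    return {
        "SmallDependenceEmphasis": sum(p[i, j] / (j + 1) ** 2 for i, j in cells),
        "LargeDependenceEmphasis": sum(p[i, j] * (j + 1) ** 2 for i, j in cells),
        "GrayLevelNonUniformity": sum(m[i, :].sum() ** 2 for i in range(ng)) / nz,
        "DependenceNonUniformity": sum(m[:, j].sum() ** 2 for j in range(dmax)) / nz,
        "DependenceNonUniformityNormalized": sum(
            p[:, j].sum() ** 2 for j in range(dmax)),
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * p[i, j] for i, j in cells),
        "DependenceVariance": sum((j + 1 - mu_j) ** 2 * p[i, j] for i, j in cells),
        "DependenceEntropy": -sum(_x2(p[i, j]) for i, j in cells),
        "LowGrayLevelEmphasis": sum(p[i, j] / (i + 1) ** 2 for i, j in cells),
        "HighGrayLevelEmphasis": sum(p[i, j] * (i + 1) ** 2 for i, j in cells),
        "SmallDependenceLowGrayLevelEmphasis": sum(
            p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i, j in cells),
        "SmallDependenceHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i, j in cells),
        "LargeDependenceLowGrayLevelEmphasis": sum(
            p[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i, j in cells),
        "LargeDependenceHighGrayLevelEmphasis": sum(
            p[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i, j in cells),
    }


# ---------------------------------------------------------------------------
# Statistical oracles
# ---------------------------------------------------------------------------

def delong_brute(scores_a, scores_b, y):
    """Placement values and covariance by O(n^2) pair enumeration."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)

    def psi(x, yv):
        return 1.0 if x > yv else (0.5 if x == yv else 0.0)

    out = {}
    for tag, s in (("a", np.asarray(scores_a, float)), ("b", np.asarray(scores_b, float))):
        v10 = np.array([np.mean([psi(s[i], s[j]) for j in neg]) for i in pos])
        v01 = np.array([np.mean([psi(s[i], s[j]) for i in pos]) for j in neg])
        out[tag] = (v10.mean(), v10, v01)
    (auc_a, v10a, v01a), (auc_b, v10b, v01b) = out["a"], out["b"]
    m, n = len(pos), len(neg)

    def cov(u, v):
        return np.sum((u - u.mean()) * (v - v.mean())) / (len(u) - 1)

    s10 = np.array([[cov(v10a, v10a), cov(v10a, v10b)], [cov(v10b, v10a), cov(v10b, v10b)]])
    s01 = np.array([[cov(v01a, v01a), cov(v01a, v01b)], [cov(v01b, v01a), cov(v01b, v01b)]])
    c = s10 / m + s01 / n
    var_diff = c[0, 0] + c[1, 1] - 2 * c[0, 1]
    z = (auc_a - auc_b) / math.sqrt(var_diff) if var_diff > 0 else 0.0
    return auc_a, auc_b, c, z


def harrell_c_brute(risk, time, event):
    risk, time, event = map(np.asarray, (risk, time, event))
    conc = comp = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = event[i] == 1 and (
                time[i] < time[j] or (time[i] == time[j] and event[j] == 0)
            )
            if not usable:
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                conc += 0.5
    return conc / comp


def calinski_harabasz_brute(points, labels):
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), len(points)
    grand = points.mean(axis=0)
    ssb = sum(
        (labels == u).sum() * np.sum((points[labels == u].mean(axis=0) - grand) ** 2)
        for u in uniq
    )
    ssw = sum(
        np.sum((points[labels == u] - points[labels == u].mean(axis=0)) ** 2)
        for u in uniq
    )
    return (ssb / (k - 1)) / (ssw / (n - k))


def ball_hall_brute(points, labels):
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    vals = []
    for u in np.unique(labels):
        mem = points[labels == u]
        vals.append(np.sum((mem - mem.mean(axis=0)) ** 2) / len(mem))
    return float(np.mean(vals))
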