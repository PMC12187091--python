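"""Tumor-microenvironment quantification from histology patches.

Per whole-slide image (or synthetic scene) the module produces 162 features:

* 150 nuclear morphological features (NMF): per nucleus, 10 measurements —
  area, major/minor axis length, aspect ratio, RGB channel means, and the
  mean/max/min distance to Delaunay-graph neighbors — each aggregated over
  the slide into a normalized 10-bin histogram plus mean, SD, skewness,
  kurtosis and Shannon entropy (10 x 15 = 150).
* 12 cell spatial distribution features (CSDF): cell count, density and
  proportion relative to the tissue area, plus 9 statistics of the Birch
  clustering of nucleus centroids (cluster count, size/dispersion/extent
  means and SDs, Ball-Hall and Calinski-Harabasz indices).

IHC patches are handled by optical-density color deconvolution: the stain
matrix is inverted in OD space, nuclei/areas positive for the second stain
are thresholded, and the same NMF/CSDF machinery runs on the positive areas.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.registration import phase_cross_correlation
from sklearn.cluster import Birch

__all__ = [
    "NMF_BASE_FEATURES",
    "tissue_mask",
    "patchify",
    "nucleus_morphometrics",
    "delaunay_distances",
    "aggregate_nmf",
    "csdf_basic",
    "birch_cluster",
    "csdf_cluster_features",
    "csdf_vector",
    "color_deconvolution",
    "register_translation",
]

#: the 10 per-nucleus measurements, in catalog order
NMF_BASE_FEATURES = (
    "area", "major_axis", "minor_axis", "aspect_ratio",
    "mean_r", "mean_g", "mean_b",
    "delaunay_mean", "delaunay_max", "delaunay_min",
)

BACKGROUND_RGB_THRESHOLD = 210.0


def tissue_mask(rgb: np.ndarray, threshold: float = BACKGROUND_RGB_THRESHOLD) -> np.ndarray:
    """Tissue = pixels whose mean RGB value does not exceed the threshold."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return rgb.astype(float).mean(axis=2) <= threshold


def patchify(
    image: np.ndarray,
    patch: int = 2048,
    min_tissue_fraction: float = 0.05,
    edge_policy: str = "drop",
) -> list[tuple[int, int, np.ndarray]]:
    """Non-overlapping patch grid over the non-background area.

    Returns ``(row0, col0, patch_array)`` triples for tiles whose tissue
    fraction meets ``min_tissue_fraction``.  ``edge_policy="drop"`` discards
    partial edge tiles (integer-division grid); ``"pad"`` zero-pads them.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if edge_policy == "drop":
        nr, nc = h // patch, w // patch
    elif edge_policy == "pad":
        nr, nc = -(-h // patch), -(-w // patch)
    else:
        raise ValueError("edge_policy must be 'drop' or 'pad'")
    tiles = []
    for r in range(nr):
        for c in range(nc):
            tile = img[r * patch:(r + 1) * patch, c * patch:(c + 1) * patch]
            if edge_policy == "pad" and tile.shape[:2] != (patch, patch):
                pads = [(0, patch - tile.shape[0]), (0, patch - tile.shape[1])]
                if tile.ndim == 3:
                    pads.append((0, 0))
                tile = np.pad(tile, pads, constant_values=255)
            frac = tissue_mask(tile).mean() if tile.ndim == 3 else 1.0
            if frac >= min_tissue_fraction:
                tiles.append((r * patch, c * patch, tile))
    return tiles


def nucleus_morphometrics(rgb: np.ndarray, label_mask: np.ndarray) -> pd.DataFrame:
    """Per-nucleus geometry and color (first 7 of the 10 measurements).

    Area is the pixel count; major/minor axis lengths come from the
    second-central-moment (area-equivalent) ellipse; RGB means are over the
    nucleus pixels.  The Delaunay columns are added separately by
    :func:`delaunay_distances`.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.max() == 0:
        raise ValueError("label mask contains no nuclei")
    if np.issubdtype(np.asarray(label_mask).dtype, np.signedinteger) and label_mask.min() < 0:
        raise ValueError("labels must be positive integers")
    props = regionprops_table(
        label_mask,
        intensity_image=np.asarray(rgb, dtype=float),
        properties=(
            "label", "area", "centroid", "axis_major_length",
            "axis_minor_length", "intensity_mean",
        ),
    )
    df = pd.DataFrame(props).set_index("label")
    df = df.rename(
        columns={
            "axis_major_length": "major_axis",
            "axis_minor_length": "minor_axis",
            "centroid-0": "centroid_y",
            "centroid-1": "centroid_x",
            "intensity_mean-0": "mean_r",
            "intensity_mean-1": "mean_g",
            "intensity_mean-2": "mean_b",
        }
    )
    df["area"] = df["area"].astype(float)
    minor = df["minor_axis"].replace(0, np.nan)
    df["aspect_ratio"] = (df["major_axis"] / minor).fillna(1.0)
    order = ["centroid_y", "centroid_x"] + [
        c for c in NMF_BASE_FEATURES if c in df.columns
    ]
    return df[order]


def delaunay_distances(centroids: np.ndarray) -> pd.DataFrame:
    """Mean/max/min Euclidean distance to Delaunay-graph neighbors.

    Fewer than 3 points (or collinear points) cannot be triangulated; the
    neighbor set then falls back to the k nearest points (k = min(2, n-1))
    with a warning.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n == 0:
        raise ValueError("no centroids")
    if n == 1:
        return pd.DataFrame(
            {"delaunay_mean": [0.0], "delaunay_max": [0.0], "delaunay_min": [0.0]}
        )
    neighbors: list[set[int]] = [set() for _ in range(n)]
    tri = None
    if n >= 3:
        try:
            tri = Delaunay(pts)
        except Exception:
            tri = None
    if tri is not None:
        indptr, idx = tri.vertex_neighbor_vertices
        for i in range(n):
            neighbors[i] = set(idx[indptr[i]:indptr[i + 1]])
    else:
        warnings.warn("degenerate centroid set: falling back to k-nearest neighbors")
        k = min(2, n - 1)
        d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=2)
        np.fill_diagonal(d2, np.inf)
        for i in range(n):
            neighbors[i] = set(np.argsort(d2[i])[:k])
    out = np.zeros((n, 3))
    for i in range(n):
        nb = sorted(neighbors[i])
        d = np.sqrt(np.sum((pts[nb] - pts[i]) ** 2, axis=1))
        out[i] = d.mean(), d.max(), d.min()
    return pd.DataFrame(out, columns=["delaunay_mean", "delaunay_max", "delaunay_min"])


# ---------------------------------------------------------------------------
# NMF aggregation
# ---------------------------------------------------------------------------


def aggregate_nmf(nuclei: pd.DataFrame, n_bins: int = 10) -> pd.Series:
    """Slide-level 150-vector: per measurement, a normalized 10-bin histogram
    over the slide's [min, max] plus mean, population SD, skewness, excess
    kurtosis, and Shannon entropy (bits) of the histogram.

    A single nucleus (or a constant measurement) yields SD = skewness =
    kurtosis = 0 and all histogram mass in the first bin.
    """
    if len(nuclei) == 0:
        raise ValueError("empty nucleus table")
    missing = [c for c in NMF_BASE_FEATURES if c not in nuclei.columns]
    if missing:
        raise ValueError(f"nucleus table lacks measurements: {missing}")
    values = {}
    for feat in NMF_BASE_FEATURES:
        x = nuclei[feat].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi > lo:
            hist, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
        else:
            hist = np.zeros(n_bins, dtype=int)
            hist[0] = len(x)
        p = hist / len(x)
        for b in range(n_bins):
            values[f"{feat}_hist{b + 1}"] = float(p[b])
        mean = float(x.mean())
        sd = float(x.std())
        if sd > 0 and len(x) > 1:
            skew = float(np.mean((x - mean) ** 3) / sd ** 3)
            kurt = float(np.mean((x - mean) ** 4) / sd ** 4 - 3.0)
        else:
            skew = kurt = 0.0
        nz = p[p > 0]
        values[f"{feat}_mean"] = mean
        values[f"{feat}_sd"] = sd
        values[f"{feat}_skewness"] = skew
        values[f"{feat}_kurtosis"] = kurt
        values[f"{feat}_entropy"] = float(-(nz * np.log2(nz)).sum())
    return pd.Series(values, dtype=float)


# ---------------------------------------------------------------------------
# CSDF
# ---------------------------------------------------------------------------


def csdf_basic(
    nuclei: pd.DataFrame, tissue: np.ndarray
) -> tuple[int, float, float]:
    """(cell count, density = count/tissue area, proportion = cell area/tissue area)."""
    area = float(np.count_nonzero(tissue))
    if area == 0:
        raise ValueError("zero tissue area")
    count = int(len(nuclei))
    total_cell_area = float(nuclei["area"].sum()) if count else 0.0
    return count, count / area, total_cell_area / area


def birch_cluster(
    centroids: np.ndarray,
    *,
    n_clusters: int | None = None,
    threshold: float | None = None,
    merge_factor: float = 5.0,
) -> np.ndarray:
    """Birch CF-tree clustering of nucleus centroids with automatic k.

    With ``n_clusters`` given, the standard Birch global step produces that
    many clusters.  Otherwise k emerges from the data: the CF tree is built
    at a fine threshold t0 (the mean nearest-neighbor distance unless
    ``threshold`` is passed), and subcluster centroids are merged by
    single-linkage cut at ``merge_factor * t0``.  Neighboring subclusters
    inside one density cluster sit ~1-2 t0 apart and chain together, while
    genuinely separated clusters stay apart; a scene without structure above
    that scale is one cluster.  Deterministic given the inputs.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n < 2:
        return np.zeros(n, dtype=int)
    if np.allclose(pts, pts[0]):
        return np.zeros(n, dtype=int)
    t0 = _fine_threshold(pts, threshold)
    if n_clusters is not None:
        model = Birch(n_clusters=int(n_clusters), threshold=t0)
        return model.fit_predict(pts)
    model = Birch(n_clusters=None, threshold=t0)
    sub = model.fit_predict(pts)
    centers = model.subcluster_centers_
    if len(centers) == 1:
        return np.zeros(n, dtype=int)
    from scipy.cluster.hierarchy import fcluster, linkage

    link = linkage(centers, method="single")
    merged = fcluster(link, t=merge_factor * t0, criterion="distance") - 1
    labels = merged[sub]
    # outlier absorption: clusters below 5% of the scene (or < 3 nuclei) are
    # tail points split off by the fine threshold, not genuine clusters
    uniq, counts = np.unique(labels, return_counts=True)
    min_size = max(3, int(np.ceil(0.05 * n)))
    big = uniq[counts >= min_size]
    small = uniq[counts < min_size]
    if len(big) > 0 and len(small) > 0:
        big_mask = np.isin(labels, big)
        big_idx = np.flatnonzero(big_mask)
        for lab in small:
            for i in np.flatnonzero(labels == lab):
                d2 = np.sum((pts[big_idx] - pts[i]) ** 2, axis=1)
                labels[i] = labels[big_idx[np.argmin(d2)]]
    # relabel to consecutive ids in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _fine_threshold(pts: np.ndarray, override: float | None) -> float:
    if override is not None:
        return float(override)
    d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.sqrt(d2.min(axis=1))
    nn = nn[np.isfinite(nn)]
    t = float(nn.mean()) if nn.size else 1.0
    return max(t, 1e-9)


def csdf_cluster_features(
    centroids: np.ndarray, labels: np.ndarray
) -> dict[str, float]:
    """Nine cluster statistics of a centroid partition.

    size = member count; dispersion = mean member distance to the cluster
    centroid; extent = cluster diameter (max pairwise member distance);
    Ball-Hall = mean over clusters of within-cluster-SS / size;
    Calinski-Harabasz = [SS_between/(k-1)] / [SS_within/(n-k)] (0, flagged,
    for k = 1).
    """
    pts = np.asarray(centroids, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    n = len(pts)
    if k < 1:
        raise ValueError("need at least one cluster")
    sizes, dispersions, extents, wss = [], [], [], []
    for lab in uniq:
        members = pts[labels == lab]
        c = members.mean(axis=0)
        d = np.sqrt(np.sum((members - c) ** 2, axis=1))
        sizes.append(len(members))
        dispersions.append(d.mean())
        extents.append(float(pdist(members).max()) if len(members) > 1 else 0.0)
        wss.append(float(np.sum(d ** 2)))
    sizes_a = np.asarray(sizes, float)
    grand = pts.mean(axis=0)
    ss_between = float(
        sum(
            s * np.sum((pts[labels == lab].mean(axis=0) - grand) ** 2)
            for s, lab in zip(sizes, uniq)
        )
    )
    ss_within = float(sum(wss))
    if k > 1 and n > k:
        ch = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else 0.0
    else:
        ch = 0.0
    return {
        "n_clusters": float(k),
        "cluster_size_mean": float(sizes_a.mean()),
        "cluster_size_sd": float(sizes_a.std()),
        "dispersion_mean": float(np.mean(dispersions)),
        "dispersion_sd": float(np.std(dispersions)),
        "extent_mean": float(np.mean(extents)),
        "extent_sd": float(np.std(extents)),
        "ball_hall": float(np.mean([w / s for w, s in zip(wss, sizes)])),
        "calinski_harabasz": float(ch),
    }


def csdf_vector(nuclei: pd.DataFrame, tissue: np.ndarray) -> pd.Series:
    """The 12-value CSDF vector for one slide."""
    count, density, proportion = csdf_basic(nuclei, tissue)
    pts = nuclei[["centroid_y", "centroid_x"]].to_numpy(dtype=float)
    if count >= 2:
        labels = birch_cluster(pts)
        cl = csdf_cluster_features(pts, labels)
    else:
        cl = {
            "n_clusters": float(min(count, 1)), "cluster_size_mean": float(count),
            "cluster_size_sd": 0.0, "dispersion_mean": 0.0, "dispersion_sd": 0.0,
            "extent_mean": 0.0, "extent_sd": 0.0, "ball_hall": 0.0,
            "calinski_harabasz": 0.0,
        }
    out = {"cell_count": float(count), "cell_density": density, "cell_proportion": proportion}
    out.update(cl)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# IHC: color deconvolution and registration
# ---------------------------------------------------------------------------


def optical_density(rgb: np.ndarray) -> np.ndarray:
    """OD = -log10((I + 1) / 256) per channel of an 8-bit image."""
    return -np.log10((np.asarray(rgb, dtype=float) + 1.0) / 256.0)


def _complete_stain_matrix(stains: np.ndarray) -> np.ndarray:
    m = np.array([s / np.linalg.norm(s) for s in np.asarray(stains, float)])
    if m.shape[0] == 2:
        residual = np.cross(m[0], m[1])
        nrm = np.linalg.norm(residual)
        if nrm < 1e-12:
            raise ValueError("stain vectors are collinear")
        m = np.vstack([m, residual / nrm])
    if m.shape != (3, 3):
        raise ValueError("need 2 or 3 stain vectors of length 3")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("singular stain matrix")
    return m


def color_deconvolution(
    rgb: np.ndarray,
    stain_vectors: np.ndarray,
    *,
    positive_stain: int = 1,
    positive_threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB patch into per-stain density images.

    ``stain_vectors`` holds 2 (or 3) rows of RGB absorption directions; a
    third orthogonal residual channel is completed automatically.  Densities
    are obtained by inverting the stain matrix in optical-density space.  The
    positive mask thresholds the ``positive_stain`` channel (Otsu by default).

    Returns ``(densities[H, W, n_stains], positive_mask)``.
    """
    m = _complete_stain_matrix(stain_vectors)
    od = optical_density(rgb)
    dens = od.reshape(-1, 3) @ np.linalg.inv(m)
    dens = dens.reshape(od.shape)
    channel = dens[..., positive_stain]
    if positive_threshold is None:
        spread = float(channel.max() - channel.min())
        if spread < 1e-6:
            positive = np.zeros(channel.shape, dtype=bool)
        else:
            positive = channel > threshold_otsu(channel)
    else:
        positive = channel > positive_threshold
    return dens, positive


def register_translation(
    fixed: np.ndarray, moving: np.ndarray
) -> tuple[tuple[float, float], bool]:
    """Translation-only rigid registration by phase cross-correlation.

    Returns ``((dy, dx), confident)`` where (dy, dx) is the estimated
    displacement of ``moving`` relative to ``fixed`` (apply the negative
    shift to ``moving`` to align it).  Mean levels are removed first so the
    estimate ignores global brightness offsets; flat images return a zero
    shift with ``confident=False``.
    """

    def gray(img):
        img = np.asarray(img, dtype=float)
        return img.mean(axis=2) if img.ndim == 3 else img

    f = gray(fixed)
    mv = gray(moving)
    if f.std() < 1e-9 or mv.std() < 1e-9:
        return (0.0, 0.0), False
    shift, _error, _ = phase_cross_correlation(f - f.mean(), mv - mv.mean())
    return (float(-shift[0]), float(-shift[1])), True


def nmf_csdf_features(
    rgb: np.ndarray, label_mask: np.ndarray
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Convenience: full 150 NMF + 12 CSDF for one patch/scene."""
    table = nucleus_morphometrics(rgb, label_mask)
    dd = delaunay_distances(table[["centroid_y", "centroid_x"]].to_numpy())
    table = table.assign(**{c: dd[c].to_numpy() for c in dd.columns})
    nmf = aggregate_nmf(table)
    csdf = csdf_vector(table, tissue_mask(rgb))
    return nmf, csdf, table
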