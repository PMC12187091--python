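"""Synthetic inputs with planted, recoverable ground truth.

Three generators cover everything the pipeline consumes:

* **MRI phantoms** — a spherical ROI inside a 3-D volume, filled with a
  Gaussian random field (smoothed white noise) whose mean, variance and
  spatial correlation length are class-conditional, so two phantom classes
  differ in texture in a way GLCM-family features can recover.
* **Cohorts** — per-patient clinical covariates (age, sex, N stage, WBC,
  hemoglobin), a binary immunotherapy-response label drawn from a logistic
  model on planted score features, overall-survival times from an exponential
  proportional-hazards model with uniform administrative censoring, and a
  site/batch label.
* **Nuclei scenes** — clustered nucleus centroids (uniform cluster centers,
  Gaussian within-cluster offsets), elliptical nuclei rendered into an RGB
  patch and a 16-bit label mask, for H&E-like and IHC-like histology patches.

Every generator is a pure function of its spec (which includes the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.draw import ellipse as draw_ellipse

from .radiomics.types import ImageVolume

# ---------------------------------------------------------------------------
# MRI phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureParams:
    """Gaussian-random-field parameters for one phantom class."""

    mean: float = 100.0
    variance: float = 400.0
    correlation_length: float = 1.0  # voxels; Gaussian smoothing kernel width

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_radius: float = 8.0
    class_label: int = 0
    texture_params: tuple[TextureParams, TextureParams] = (
        TextureParams(mean=100.0, variance=400.0, correlation_length=0.8),
        TextureParams(mean=130.0, variance=400.0, correlation_length=2.0),
    )
    background_mean: float = 40.0
    background_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        if any(self.roi_radius * 2 + 2 > s for s in self.shape):
            raise ValueError(
                f"ROI of radius {self.roi_radius} does not fit inside volume "
                f"of shape {self.shape}"
            )


def _gaussian_random_field(rng, shape, params: TextureParams) -> np.ndarray:
    if params.variance == 0:
        return np.full(shape, params.mean)
    noise = rng.standard_normal(shape)
    if params.correlation_length > 0:
        noise = ndimage.gaussian_filter(noise, params.correlation_length, mode="wrap")
    sd = noise.std()
    if sd == 0:
        return np.full(shape, params.mean)
    return params.mean + np.sqrt(params.variance) * (noise - noise.mean()) / sd


def sphere_mask(shape, radius, center=None) -> np.ndarray:
    if center is None:
        center = tuple((s - 1) / 2 for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius ** 2


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, np.ndarray]:
    """Phantom volume plus binary spherical ROI mask (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    mask = sphere_mask(spec.shape, spec.roi_radius)
    params = spec.texture_params[spec.class_label]
    roi_field = _gaussian_random_field(rng, spec.shape, params)
    background = spec.background_mean + spec.background_sd * rng.standard_normal(spec.shape)
    values = np.where(mask, roi_field, background)
    return ImageVolume(values, spec.spacing), mask


def perturb_mask(mask: np.ndarray, magnitude: float, seed: int = 0) -> np.ndarray:
    """Simulate a second reader: random local boundary displacement.

    The boundary of the perturbed mask is moved by at most ``magnitude``
    voxels: the signed Euclidean distance map of the mask is offset by a
    smooth random field clipped to [-magnitude, magnitude] and re-thresholded.
    ``magnitude = 0`` returns an identical mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if magnitude == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = inside - outside  # positive inside
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 2.0)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    displacement = np.clip(magnitude * noise, -magnitude, magnitude)
    out = (signed + displacement) > 0
    if not out.any():
        raise ValueError("perturbation magnitude emptied the mask")
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential baseline hazard with log-linear covariate effects."""

    baseline_hazard: float = 0.02  # events per month
    coefficients: tuple[tuple[str, float], ...] = (("risk_score", 0.8),)
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator settings.

    ``planted_effect`` is the per-feature log-odds of response attached to
    each of ``n_score_features`` standard-normal planted score columns
    (``score_0`` ...); ``responder_prevalence`` fixes the marginal response
    rate via the logistic intercept.
    """

    n_patients: int = 246
    responder_prevalence: float = 0.74
    planted_effect: float = 0.0
    n_score_features: int = 3
    n_noise_features: int = 10
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    n_batches: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.responder_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


def _uniform_censor_bound(rate: float, hazards: np.ndarray) -> float:
    """Upper bound b of Uniform(0, b) censoring achieving the target rate.

    For an exponential event time with hazard h and independent C~U(0, b),
    P(censored) = (1 - exp(-h b)) / (h b); solve the cohort-average for b.
    """

    def mean_censored(b: float) -> float:
        x = hazards * b
        return float(np.mean(np.where(x > 1e-12, (1 - np.exp(-x)) / np.maximum(x, 1e-12), 1.0)))

    lo, hi = 1e-6, 1e3 / hazards.mean()
    # mean_censored is decreasing in b from 1 to 0
    if mean_censored(hi) > rate:
        return hi
    return float(optimize.brentq(lambda b: mean_censored(b) - rate, lo, hi))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a clinical cohort table with planted response and survival.

    Columns: patient_id (index), age, sex, n_stage, wbc, hemoglobin, batch,
    score_* (planted response/risk features), noise_* (pure noise features),
    response, time_months, event, plus ``truth_response_lp`` and
    ``truth_risk_lp`` (the generating linear predictors).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    age = np.clip(rng.normal(50, 11, n), 18, 80).round(1)
    sex = rng.binomial(1, 0.75, n)  # 1 = male; NPC cohorts skew male
    n_stage = rng.choice([0, 1, 2, 3], size=n, p=[0.1, 0.3, 0.4, 0.2])
    wbc = np.clip(rng.normal(6.5, 1.8, n), 2.0, 15.0).round(2)
    hemoglobin = np.clip(rng.normal(135, 16, n), 80, 180).round(1)
    batch = rng.integers(0, spec.n_batches, n)

    scores = rng.standard_normal((n, spec.n_score_features))
    noise = rng.standard_normal((n, spec.n_noise_features))

    lp_resp = spec.planted_effect * scores.sum(axis=1)
    intercept = math.log(spec.responder_prevalence / (1 - spec.responder_prevalence))
    p_resp = 1.0 / (1.0 + np.exp(-(intercept + lp_resp)))
    response = rng.binomial(1, p_resp)

    sm = spec.survival_model
    cols = {"age": (age - age.mean()) / age.std(), "n_stage": n_stage, "response": response}
    for i in range(spec.n_score_features):
        cols[f"score_{i}"] = scores[:, i]
    risk_lp = np.zeros(n)
    for name, beta in sm.coefficients:
        if name == "risk_score":
            risk_lp = risk_lp + beta * scores.sum(axis=1) / math.sqrt(spec.n_score_features)
        elif name in cols:
            risk_lp = risk_lp + beta * np.asarray(cols[name], dtype=float)
        else:
            raise ValueError(f"unknown survival coefficient target {name!r}")
    hazards = sm.baseline_hazard * np.exp(risk_lp)
    event_time = rng.exponential(1.0 / hazards)
    if sm.censoring_rate == 0:
        time = event_time
        event = np.ones(n, dtype=int)
    else:
        b = _uniform_censor_bound(sm.censoring_rate, hazards)
        censor_time = rng.uniform(0, b, n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "n_stage": n_stage,
            "wbc": wbc,
            "hemoglobin": hemoglobin,
            "batch": batch,
            "response": response,
            "time_months": np.maximum(time, 1e-3).round(3),
            "event": event,
            "truth_response_lp": lp_resp,
            "truth_risk_lp": risk_lp,
        },
        index=pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id"),
    )
    for i in range(spec.n_score_features):
        df[f"score_{i}"] = scores[:, i]
    for i in range(spec.n_noise_features):
        df[f"noise_{i}"] = noise[:, i]
    return df


# ---------------------------------------------------------------------------
# Nuclei scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    canvas: tuple[int, int] = (512, 512)
    n_clusters: int = 4
    cells_per_cluster: float = 25.0
    cluster_spread: float = 25.0  # px, Gaussian sd of within-cluster offsets
    major_axis: tuple[float, float] = (12.0, 2.0)  # mean, sd in px
    minor_axis: tuple[float, float] = (8.0, 1.5)
    nucleus_color: tuple[int, int, int] = (80, 60, 140)  # hematoxylin-like
    positive_color: tuple[int, int, int] = (130, 110, 100)  # DAB/gray-like
    stroma_color: tuple[int, int, int] = (205, 170, 195)
    background_color: tuple[int, int, int] = (245, 245, 245)
    positive_fraction: float = 0.0  # fraction of IHC-positive nuclei
    color_noise_sd: float = 4.0
    max_overlap: float = 0.1
    poisson_counts: bool = True
    min_center_separation: float = 0.0  # px; rejection-sample cluster centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1:
            raise ValueError("need at least one cluster and one cell")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction in [0, 1]")
        if sum(self.background_color) / 3 <= 210:
            raise ValueError("background color must have mean RGB > 210")


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render (RGB uint8 patch, uint16 label mask, nucleus table).

    Nucleus centers follow a clustered point process: cluster centers uniform
    inside the canvas margin, member offsets Gaussian with ``cluster_spread``.
    Each nucleus is an ellipse with sampled axes and orientation; overlap with
    previously placed nuclei is allowed up to ``max_overlap`` of its area
    (later placements win in the label mask).  Placement failure after
    repeated attempts raises (infeasible density).

    The returned table holds, per label: the sampled ground-truth geometry
    (``truth_*`` columns), the cluster id, and the IHC-positive flag.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    margin = spec.major_axis[0] + 3 * spec.major_axis[1] + 1
    if 2 * margin >= min(h, w):
        raise ValueError("canvas too small for requested nucleus geometry")

    for _try in range(500):
        centers = np.column_stack(
            [rng.uniform(margin, h - margin, spec.n_clusters),
             rng.uniform(margin, w - margin, spec.n_clusters)]
        )
        if spec.n_clusters == 1 or spec.min_center_separation <= 0:
            break
        d = centers[:, None] - centers[None, :]
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= spec.min_center_separation:
            break
    else:
        raise ValueError(
            "could not place cluster centers at the requested separation"
        )
    label_mask = np.zeros((h, w), dtype=np.uint16)
    records = []
    label = 0
    for ci, (cy, cx) in enumerate(centers):
        if spec.poisson_counts:
            n_cells = max(1, int(rng.poisson(spec.cells_per_cluster)))
        else:
            n_cells = int(round(spec.cells_per_cluster))
        for _ in range(n_cells):
            placed = False
            for _attempt in range(150):
                yx = np.array([cy, cx]) + rng.normal(0, spec.cluster_spread, 2)
                major = max(2.0, rng.normal(*spec.major_axis))
                minor = max(1.5, rng.normal(*spec.minor_axis))
                if minor > major:
                    major, minor = minor, major
                theta = rng.uniform(0, np.pi)
                rr, cc = draw_ellipse(
                    yx[0], yx[1], major / 2, minor / 2,
                    shape=(h, w), rotation=theta,
                )
                if rr.size == 0:
                    continue
                # reject nuclei clipped by the canvas edge
                full_rr, full_cc = draw_ellipse(
                    yx[0], yx[1], major / 2, minor / 2, rotation=theta
                )
                if rr.size < full_rr.size:
                    continue
                overlap = np.count_nonzero(label_mask[rr, cc]) / rr.size
                if overlap > spec.max_overlap:
                    continue
                label += 1
                label_mask[rr, cc] = label
                positive = bool(rng.random() < spec.positive_fraction)
                records.append(
                    {
                        "label": label,
                        "cluster": ci,
                        "truth_y": float(yx[0]),
                        "truth_x": float(yx[1]),
                        "truth_major": float(major),
                        "truth_minor": float(minor),
                        "truth_theta": float(theta),
                        "positive": positive,
                    }
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    "could not place nucleus without excessive overlap: "
                    "requested density is infeasible"
                )

    table = pd.DataFrame.from_records(records).set_index("label")

    # Render RGB: background everywhere, stroma disks around clusters, nuclei.
    rgb = np.empty((h, w, 3), dtype=float)
    rgb[...] = np.asarray(spec.background_color, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    stroma_r = 3.0 * spec.cluster_spread + spec.major_axis[0]
    tissue = np.zeros((h, w), dtype=bool)
    for cy, cx in centers:
        tissue |= (yy - cy) ** 2 + (xx - cx) ** 2 <= stroma_r ** 2
    rgb[tissue] = np.asarray(spec.stroma_color, dtype=float)
    nuc = label_mask > 0
    if len(table):
        pos_labels = set(table.index[table["positive"]])
        pos_pix = np.isin(label_mask, list(pos_labels)) if pos_labels else np.zeros_like(nuc)
        rgb[nuc & ~pos_pix] = np.asarray(spec.nucleus_color, dtype=float)
        if pos_labels:
            rgb[pos_pix] = np.asarray(spec.positive_color, dtype=float)
    rgb += rng.normal(0, spec.color_noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb, label_mask, table


def scene_with_morphometrics(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Scene plus the measured per-nucleus morphometrics (generator's table).

    The measured columns (area, axes, aspect ratio, RGB means, Delaunay
    distances) are computed from the rendered mask/patch so they match the
    rendered labels one-to-one; ``truth_*`` columns keep the sampled
    parameters.
    """
    from .pathomics import delaunay_distances, nucleus_morphometrics

    rgb, label_mask, truth = generate_scene(spec)
    measured = nucleus_morphometrics(rgb, label_mask)
    dd = delaunay_distances(measured[["centroid_y", "centroid_x"]].to_numpy())
    measured[["delaunay_mean", "delaunay_max", "delaunay_min"]] = dd
    table = measured.join(truth)
    return rgb, label_mask, table
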