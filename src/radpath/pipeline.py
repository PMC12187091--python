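"""End-to-end study orchestration on synthetic cohorts.

Three study drivers mirror the analysis arms:

* :func:`run_response_study` — phantoms whose ROI texture depends on the
  response label -> radiomic extraction -> ComBat + normalization + pruning +
  ANOVA -> classifier comparison -> Radscore, clinical and combined logistic
  models -> ROC/DeLong/calibration/decision-curve evaluation on a held-out
  split.
* :func:`run_survival_study` — cohort feature tables with a planted
  prognostic score -> follow-up filter + SMOTE -> selection -> Cox radiomic /
  clinical / combined models -> Harrell + horizon C-indices -> maximally
  selected cutpoint -> Kaplan-Meier log-rank stratification.
* :func:`run_radpath_study` — patients with a shared latent factor driving
  both a radiomic table and rendered nuclei scenes -> NMF/CSDF extraction ->
  Spearman + BH-FDR correlation with per-marker summaries.

Every stage derives its randomness from ``config.seed``; a run with a fixed
config is bit-reproducible.  When ``out_dir`` is given, the resolved config,
seed registry and stage outputs are written there.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlation, pathomics, response, selection, survival
from .radiomics import enumerate_catalog, extract_features
from .synthetic import (
    CohortSpec,
    PhantomSpec,
    SceneSpec,
    SurvivalModel,
    TextureParams,
    generate_cohort,
    generate_phantom,
    scene_with_morphometrics,
)


@dataclass
class RunConfig:
    """Thresholds and sizes for the study drivers (defaults = study values)."""

    seed: int = 0
    # cohort
    n_patients: int = 180
    responder_prevalence: float = 0.74
    train_fraction: float = 0.6
    n_batches: int = 2
    # phantoms
    phantom_shape: tuple[int, int, int] = (20, 20, 20)
    roi_radius: float = 7.0
    texture_contrast: float = 1.0  # 0 = null effect, 1 = full planted contrast
    sequences: tuple[str, ...] = ("T2",)
    image_types: tuple[str, ...] = ("original",)
    # preprocessing / selection
    n_bins: int = 25
    icc_threshold: float = 0.75
    pcc_threshold: float = 0.99
    anova_k: int = 8
    # modeling / evaluation
    folds: int = 5
    algorithms: tuple[str, ...] = (
        "adaptive_boosting", "random_forest", "svm", "logistic_regression",
        "gaussian_process", "gradient_boosting", "categorical_boosting",
    )
    bootstrap: int = 1000
    background_threshold: float = 210.0
    patch_size: int = 2048
    fdr_threshold: float = 0.05
    horizons: tuple[float, ...] = (12.0, 24.0, 36.0)
    min_follow_up_months: float = 24.0
    # survival study
    planted_log_hr: float = 0.8
    censoring_rate: float = 0.3
    # rad-path study
    n_scene_patients: int = 60
    scene_markers: tuple[str, ...] = ("HE",)
    latent_coupling: float = 0.8

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls(**data)


def _write(out_dir, name, obj) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path)
    else:
        path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


# ---------------------------------------------------------------------------
# Response study
# ---------------------------------------------------------------------------

_BASE_TEXTURE = TextureParams(mean=100.0, variance=400.0, correlation_length=0.8)
_FULL_CONTRAST = TextureParams(mean=100.0, variance=400.0, correlation_length=2.2)


def _class_textures(contrast: float) -> tuple[TextureParams, TextureParams]:
    """Class-1 texture interpolates toward the full-contrast parameters.

    The two classes share mean and variance and differ only in spatial
    correlation length, so first-order statistics are matched and the planted
    signal is a genuine texture (co-occurrence) difference.
    """
    c1 = TextureParams(
        mean=_BASE_TEXTURE.mean
        + contrast * (_FULL_CONTRAST.mean - _BASE_TEXTURE.mean),
        variance=_BASE_TEXTURE.variance
        + contrast * (_FULL_CONTRAST.variance - _BASE_TEXTURE.variance),
        correlation_length=_BASE_TEXTURE.correlation_length
        + contrast * (_FULL_CONTRAST.correlation_length - _BASE_TEXTURE.correlation_length),
    )
    return _BASE_TEXTURE, c1


def simulate_response_features(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table plus extracted radiomic FeatureTable for every patient."""
    cohort = generate_cohort(
        CohortSpec(
            n_patients=config.n_patients,
            responder_prevalence=config.responder_prevalence,
            planted_effect=0.0,
            n_batches=config.n_batches,
            seed=config.seed,
        )
    )
    textures = _class_textures(config.texture_contrast)
    catalog = enumerate_catalog(config.sequences).subset(
        image_type=config.image_types
    )
    rows = {}
    rng = np.random.default_rng(config.seed + 1)
    for i, (pid, row) in enumerate(cohort.iterrows()):
        vols = {}
        for si, seq in enumerate(config.sequences):
            spec = PhantomSpec(
                shape=config.phantom_shape,
                roi_radius=config.roi_radius,
                class_label=int(row["response"]),
                texture_params=textures,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, mask = generate_phantom(spec)
            vols[seq] = vol
        rows[pid] = extract_features(
            vols, mask, catalog, n_bins=config.n_bins,
            image_types=config.image_types,
        )
    features = pd.DataFrame(rows).T.dropna(axis=1, how="all")
    features.index.name = "patient_id"
    return cohort, features


def _split(cohort: pd.DataFrame, frac: float, seed: int):
    rng = np.random.default_rng(seed + 2)
    idx = np.arange(len(cohort))
    rng.shuffle(idx)
    n_train = int(round(frac * len(cohort)))
    return cohort.index[np.sort(idx[:n_train])], cohort.index[np.sort(idx[n_train:])]


CLINICAL_VARS = ("age", "sex", "n_stage", "wbc", "hemoglobin")


def run_response_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate -> extract -> harmonize -> select -> train -> evaluate."""
    cohort, features = simulate_response_features(config)
    train_ids, test_ids = _split(cohort, config.train_fraction, config.seed)
    y_train = cohort.loc[train_ids, "response"].to_numpy()
    y_test = cohort.loc[test_ids, "response"].to_numpy()

    harmonized = selection.combat(features, cohort["batch"])
    norm = selection.MeanNormalizer().fit(harmonized.loc[train_ids])
    x_train = norm.transform(harmonized.loc[train_ids])
    x_test = norm.transform(harmonized.loc[test_ids])
    kept = selection.pearson_prune(x_train, config.pcc_threshold)
    picked = selection.anova_rank(x_train[kept], y_train, config.anova_k)
    x_train, x_test = x_train[picked], x_test[picked]

    leaderboard, model = response.compare_classifiers(
        x_train, y_train, config.algorithms, config.folds, config.seed
    )
    rad_train = response.radscore(model, x_train)
    rad_test = response.radscore(model, x_test)
    roc_train = response.roc_metrics(rad_train, y_train)
    roc_test = response.roc_metrics(rad_test, y_test, threshold=roc_train.threshold)

    clin = cohort[list(CLINICAL_VARS)].astype(float)
    clin = (clin - clin.loc[train_ids].mean()) / clin.loc[train_ids].std()
    clinical_model = response.stepwise_logistic(clin.loc[train_ids], y_train)
    combined_input = clin.copy()
    combined_input["radscore"] = np.nan
    combined_input.loc[train_ids, "radscore"] = rad_train
    combined_input.loc[test_ids, "radscore"] = rad_test
    combined_model = response.stepwise_logistic(combined_input.loc[train_ids], y_train)

    def safe_predict(m: response.LogisticModel, X: pd.DataFrame) -> np.ndarray:
        return m.predict(X) if m.terms else np.full(len(X), y_train.mean())

    clin_test = safe_predict(clinical_model, clin.loc[test_ids])
    comb_test = safe_predict(combined_model, combined_input.loc[test_ids])
    dl = response.delong(rad_test, clin_test, y_test)
    try:
        calib = response.calibration(
            np.clip(rad_test, 1e-6, 1 - 1e-6), y_test,
            bootstrap=config.bootstrap, seed=config.seed,
        )
    except ValueError:  # scores too discrete for decile grouping
        calib = None
    dca = response.decision_curve(rad_test, y_test)

    report = {
        "config": dataclasses.asdict(config),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "selected_features": picked,
        "leaderboard": leaderboard.to_dict(orient="records"),
        "train": dataclasses.asdict(roc_train),
        "test": dataclasses.asdict(roc_test),
        "clinical_terms": clinical_model.terms,
        "combined_terms": combined_model.terms,
        "delong_radiomic_vs_clinical": dataclasses.asdict(dl),
        "calibration_hl_p": None if calib is None else calib["hl_p"],
    }
    _write(out_dir, "response_report.json", report)
    _write(out_dir, "leaderboard.csv", leaderboard)
    _write(out_dir, "decision_curve.csv", dca)
    if calib is not None:
        _write(out_dir, "calibration_curve.csv", calib["curve"])
    if out_dir is not None:
        config.to_yaml(Path(out_dir) / "config.yaml")
    report["_models"] = {"radiomic": model, "clinical": clinical_model,
                         "combined": combined_model}
    report["_scores"] = {"rad_test": rad_test, "clin_test": clin_test,
                         "comb_test": comb_test, "y_test": y_test}
    return report


# ---------------------------------------------------------------------------
# Survival study
# ---------------------------------------------------------------------------


def run_survival_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """SMOTE -> select -> Cox models -> C-indices -> cutpoint -> KM."""
    cohort = generate_cohort(
        CohortSpec(
            n_patients=config.n_patients,
            responder_prevalence=config.responder_prevalence,
            survival_model=SurvivalModel(
                coefficients=(("risk_score", config.planted_log_hr),),
                censoring_rate=config.censoring_rate,
            ),
            n_batches=config.n_batches,
            seed=config.seed,
        )
    )
    cohort = survival.follow_up_filter(cohort, config.min_follow_up_months)
    feature_cols = [c for c in cohort.columns if c.startswith(("score_", "noise_"))]
    train_ids, test_ids = _split(cohort, config.train_fraction, config.seed)

    feats = cohort[feature_cols]
    norm = selection.MeanNormalizer().fit(feats.loc[train_ids])
    x_train = norm.transform(feats.loc[train_ids])
    x_test = norm.transform(feats.loc[test_ids])

    ev_train = cohort.loc[train_ids, "event"].to_numpy()
    aug = x_train.copy()
    aug["_time"] = cohort.loc[train_ids, "time_months"].to_numpy()
    aug_bal, ev_bal = survival.smote(aug, ev_train, seed=config.seed)
    t_bal = aug_bal.pop("_time").to_numpy()
    t_bal = np.maximum(t_bal, 1e-3)

    kept = selection.pearson_prune(aug_bal, config.pcc_threshold)
    picked = selection.anova_rank(aug_bal[kept], ev_bal, config.anova_k)

    rad_cox = survival.cox_fit(aug_bal[picked], t_bal, ev_bal, penalizer=0.01)
    lp = rad_cox.predict_log_partial_hazard

    def cindex(ids, score):
        t = cohort.loc[ids, "time_months"].to_numpy()
        e = cohort.loc[ids, "event"].to_numpy()
        return survival.harrell_c(score, t, e)

    rad_train_score = lp(x_train[picked]).to_numpy()
    rad_test_score = lp(x_test[picked]).to_numpy()

    clin = cohort[["age", "n_stage", "hemoglobin"]].astype(float)
    clin = (clin - clin.loc[train_ids].mean()) / clin.loc[train_ids].std()
    clin_cox = survival.cox_fit(
        clin.loc[train_ids],
        cohort.loc[train_ids, "time_months"],
        cohort.loc[train_ids, "event"],
        stepwise=True, penalizer=0.01,
    )
    comb = clin.copy()
    comb.loc[train_ids, "os_radscore"] = rad_train_score
    comb.loc[test_ids, "os_radscore"] = rad_test_score
    comb_cox = survival.cox_fit(
        comb.loc[train_ids],
        cohort.loc[train_ids, "time_months"],
        cohort.loc[train_ids, "event"],
        stepwise=True, penalizer=0.01,
    )

    def model_scores(cox, X):
        cols = list(cox.params_.index)
        return cox.predict_log_partial_hazard(X[cols]).to_numpy()

    scores = {
        "radiomic": (rad_train_score, rad_test_score),
        "clinical": (model_scores(clin_cox, clin.loc[train_ids]),
                     model_scores(clin_cox, clin.loc[test_ids])),
        "combined": (model_scores(comb_cox, comb.loc[train_ids]),
                     model_scores(comb_cox, comb.loc[test_ids])),
    }
    cindices = {
        name: {"train": cindex(train_ids, s_tr), "test": cindex(test_ids, s_te)}
        for name, (s_tr, s_te) in scores.items()
    }
    horizon_cs = {}
    t_test = cohort.loc[test_ids, "time_months"].to_numpy()
    e_test = cohort.loc[test_ids, "event"].to_numpy()
    for h in config.horizons:
        try:
            horizon_cs[str(h)] = survival.horizon_c(
                scores["combined"][1], t_test, e_test, h
            )
        except ValueError:
            horizon_cs[str(h)] = None

    s_tr = scores["combined"][0]
    cut, chi2, p = survival.optimal_cutpoint(
        s_tr, cohort.loc[train_ids, "time_months"], cohort.loc[train_ids, "event"]
    )
    km = survival.km_logrank(
        t_test, e_test, (scores["combined"][1] > cut).astype(int)
    )
    report = {
        "config": dataclasses.asdict(config),
        "n_after_followup_filter": len(cohort),
        "selected_features": picked,
        "radiomic_cox_terms": list(rad_cox.params_.index),
        "clinical_cox_terms": list(clin_cox.params_.index),
        "combined_cox_terms": list(comb_cox.params_.index),
        "c_index": cindices,
        "horizon_c_combined_test": horizon_cs,
        "cutpoint": {"cutoff": cut, "logrank_chi2": chi2, "p": p},
        "km_test_logrank": {"chi2": km.chi2, "p": km.p},
    }
    _write(out_dir, "survival_report.json", report)
    if out_dir is not None:
        for lab, curve in km.curves.items():
            _write(out_dir, f"km_curve_group{lab}.csv", curve)
        config.to_yaml(Path(out_dir) / "config.yaml")
    report["_models"] = {"radiomic": rad_cox, "clinical": clin_cox, "combined": comb_cox}
    return report


# ---------------------------------------------------------------------------
# Radiology-pathology study
# ---------------------------------------------------------------------------


def run_radpath_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Latent-factor-coupled radiomic and pathologic tables -> correlation."""
    rng = np.random.default_rng(config.seed)
    n = config.n_scene_patients
    latent = rng.standard_normal(n)
    pids = [f"P{i:04d}" for i in range(n)]

    lam = config.latent_coupling
    rad = pd.DataFrame(index=pd.Index(pids, name="patient_id"))
    for j in range(3):
        rad[f"rad_planted_{j}"] = lam * latent + np.sqrt(1 - lam**2) * rng.standard_normal(n)
    for j in range(3):
        rad[f"rad_noise_{j}"] = rng.standard_normal(n)

    path_by_marker: dict[str, pd.DataFrame] = {}
    for marker in config.scene_markers:
        rows = {}
        for i, pid in enumerate(pids):
            spec = SceneSpec(
                canvas=(448, 448),
                n_clusters=3,
                cells_per_cluster=20,
                cluster_spread=24.0,
                major_axis=(12.0 + 2.5 * lam * latent[i], 1.5),
                minor_axis=(8.0, 1.0),
                positive_fraction=0.3 if marker != "HE" else 0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _, _, table = scene_with_morphometrics(spec)
            rows[pid] = pathomics.aggregate_nmf(table)
        path_by_marker[marker] = pd.DataFrame(rows).T

    result = correlation.correlate(rad, path_by_marker, config.fdr_threshold)
    summary = correlation.count_pairs(result)
    _write(out_dir, "correlation_result.csv", result)
    _write(out_dir, "correlation_summary.csv", summary)
    if out_dir is not None:
        config.to_yaml(Path(out_dir) / "config.yaml")
    return {"result": result, "summary": summary, "latent": latent}
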