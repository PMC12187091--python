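"""Immunotherapy-response modeling and its evaluation battery.

Covers: the seven-classifier comparison under stratified 5-fold CV, the
Radscore (predicted response probability of the winning classifier), stepwise
logistic clinical/combined models, ROC metrics with a Youden operating point
frozen on training data, DeLong's paired AUC test, calibration with the
Hosmer-Lemeshow statistic and a bootstrap bias-corrected curve, decision-curve
net benefit, and the Hanley-McNeil AUC-based sample-size computation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIERS",
    "compare_classifiers",
    "radscore",
    "stepwise_logistic",
    "roc_metrics",
    "delong",
    "calibration",
    "hosmer_lemeshow",
    "decision_curve",
    "auc_sample_size",
]


def _catboost_slot(seed: int):
    # LightGBM fills the "categorical boosting" slot: a boosting library with
    # native categorical-feature handling.
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        random_state=seed, deterministic=True, n_jobs=1, verbose=-1,
        force_col_wise=True,
    )


def classifier_grid(seed: int) -> dict[str, tuple[object, dict[str, list]]]:
    """The seven pluggable classifier slots with small fixed tuning grids."""
    return {
        "adaptive_boosting": (
            AdaBoostClassifier(random_state=seed),
            {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=seed, n_jobs=1),
            {"n_estimators": [100, 200], "max_depth": [None, 4]},
        ),
        "svm": (
            SVC(probability=True, random_state=seed),
            {"C": [0.5, 1.0, 2.0], "kernel": ["rbf", "linear"]},
        ),
        "logistic_regression": (
            LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
        ),
        "gaussian_process": (GaussianProcessClassifier(random_state=seed), {}),
        "gradient_boosting": (
            GradientBoostingClassifier(random_state=seed),
            {"n_estimators": [100], "learning_rate": [0.05, 0.1]},
        ),
        "categorical_boosting": (
            _catboost_slot(seed),
            {"n_estimators": [100], "learning_rate": [0.05, 0.1]},
        ),
    }


CLASSIFIERS = tuple(classifier_grid(0))


def compare_classifiers(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    algorithms: tuple[str, ...] = CLASSIFIERS,
    folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, object]:
    """Stratified k-fold CV AUC leaderboard; best model refit on all data.

    Each algorithm's small hyperparameter grid is scanned; the leaderboard
    reports the best grid point per algorithm (mean +/- sd CV AUC) sorted by
    mean AUC, and the overall winner is refit on the full training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    grid = classifier_grid(seed)
    rows = []
    best_est = {}
    for name in algorithms:
        est, params = grid[name]
        keys = list(params)
        combos = list(itertools.product(*params.values())) if keys else [()]
        best = None
        for combo in combos:
            model = clone(est).set_params(**dict(zip(keys, combo)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = cross_val_score(model, X, y, cv=cv, scoring="roc_auc")
            cand = (scores.mean(), scores.std(), dict(zip(keys, combo)), model)
            if best is None or cand[0] > best[0]:
                best = cand
        rows.append(
            {
                "algorithm": name,
                "cv_auc_mean": best[0],
                "cv_auc_sd": best[1],
                "params": best[2],
            }
        )
        best_est[name] = best[3]
    leaderboard = (
        pd.DataFrame(rows).sort_values("cv_auc_mean", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    winner = best_est[leaderboard.loc[0, "algorithm"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        winner.fit(X, y)
    return leaderboard, winner


def radscore(model, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-sample radiomic signature = predicted response probability."""
    return np.asarray(model.predict_proba(np.asarray(X, dtype=float))[:, 1])


# ---------------------------------------------------------------------------
# Stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    terms: list[str]
    result: object = field(repr=False)
    separation_flag: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        exog = sm.add_constant(X[self.terms], has_constant="add")
        return np.asarray(self.result.predict(exog))

    def odds_ratios(self) -> pd.DataFrame:
        params = self.result.params
        conf = self.result.conf_int()
        out = pd.DataFrame(
            {
                "odds_ratio": np.exp(params),
                "ci_low": np.exp(conf[0]),
                "ci_high": np.exp(conf[1]),
                "p": self.result.pvalues,
            }
        )
        return out.drop(index="const", errors="ignore")

    @property
    def aic(self) -> float:
        return float(self.result.aic)


def _fit_logit(y: np.ndarray, X: pd.DataFrame, terms: list[str]):
    exog = sm.add_constant(X[terms], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, exog)
        res = model.fit(disp=0, maxiter=200)
    return res


def stepwise_logistic(
    candidates: pd.DataFrame,
    y: np.ndarray | pd.Series,
    *,
    criterion: str = "bic",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_iter: int = 50,
) -> LogisticModel:
    """Bidirectional stepwise logistic regression.

    The default criterion is the BIC: at each step the add-or-drop move with
    the best BIC improvement is taken until no move improves.  The ln(n)
    complexity penalty makes pure-noise candidate sets collapse to the
    intercept-only model almost always, while a genuine predictor still
    enters easily.  ``criterion="aic"`` uses the classic lighter penalty
    (which retains a spurious noise term roughly half the time), and
    ``criterion="p_value"`` mirrors clinical forward-entry/backward-removal
    at ``alpha_enter``/``alpha_remove``.  Quasi-separated fits
    (|coefficient| > 15 on standardized-scale terms) are flagged.
    """
    y = np.asarray(y)
    selected: list[str] = []
    current = _fit_logit(y, candidates, selected)
    if criterion in ("aic", "bic"):
        def ic(res):
            return float(res.aic if criterion == "aic" else res.bic)

        best_ic = ic(current)
        for _ in range(max_iter):
            moves = []
            for term in candidates.columns:
                trial = selected + [term] if term not in selected else [
                    t for t in selected if t != term
                ]
                try:
                    res = _fit_logit(y, candidates, trial)
                except Exception:
                    continue
                if np.isfinite(ic(res)):
                    moves.append((ic(res), trial, res))
            if not moves:
                break
            moves.sort(key=lambda m: m[0])
            if moves[0][0] < best_ic - 1e-9:
                best_ic, selected, current = moves[0][0], moves[0][1], moves[0][2]
            else:
                break
    elif criterion == "p_value":
        for _ in range(max_iter):
            changed = False
            # forward step: best entering term by Wald p
            entries = []
            for term in candidates.columns:
                if term in selected:
                    continue
                try:
                    res = _fit_logit(y, candidates, selected + [term])
                except Exception:
                    continue
                p = res.pvalues.get(term, np.nan)
                if np.isfinite(p) and p < alpha_enter:
                    entries.append((p, term, res))
            if entries:
                entries.sort(key=lambda e: e[0])
                _, term, current = entries[0]
                selected = selected + [term]
                changed = True
            # backward step: drop the worst included term above alpha_remove
            while selected:
                pv = current.pvalues.drop(index="const", errors="ignore")
                worst = pv.idxmax()
                if pv[worst] > alpha_remove:
                    selected = [t for t in selected if t != worst]
                    current = _fit_logit(y, candidates, selected)
                    changed = True
                else:
                    break
            if not changed:
                break
    else:
        raise ValueError("criterion must be 'p_value' or 'aic'")
    sep = bool(np.any(np.abs(current.params.to_numpy()) > 15))
    if sep:
        warnings.warn("possible separation: coefficients are extreme")
    return LogisticModel(terms=selected, result=current, separation_flag=sep)


# ---------------------------------------------------------------------------
# ROC metrics
# ---------------------------------------------------------------------------


@dataclass
class RocReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float


def roc_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    threshold: float | None = None,
) -> RocReport:
    """Empirical ROC AUC plus confusion metrics at an operating threshold.

    With ``threshold=None`` the Youden index (max sensitivity+specificity-1)
    is optimized on the given data — do this on training data and pass the
    frozen threshold for test data.  The AUC CI is the DeLong Wald interval.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, scores))
    _, var = _delong_auc_variance(scores, y)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    if threshold is None:
        fpr, tpr, thr = roc_curve(y, scores)
        threshold = float(thr[np.argmax(tpr - fpr)])
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return RocReport(
        auc=auc,
        auc_ci=ci,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and placement values V10 (per positive) / V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if tie, else 0
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    return float(cmp_.mean()), v10, v01


def _delong_auc_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    auc, v10, v01 = _placements(np.asarray(scores, float), np.asarray(y).astype(int))
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    degenerate: bool = False


def delong(scores_a: np.ndarray, scores_b: np.ndarray, y: np.ndarray) -> DelongResult:
    """DeLong's paired test comparing two AUCs on the same samples.

    Uses the placement-value covariance estimator and a two-sided normal
    test; per-model CIs are Wald intervals on the AUC scale clipped to [0, 1].
    A degenerate (zero) variance of the difference is flagged and yields an
    undefined p (NaN).
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    y = np.asarray(y).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != y.shape:
        raise ValueError("paired scores require identical sample sets")
    auc_a, v10_a, v01_a = _placements(scores_a, y)
    auc_b, v10_b, v01_b = _placements(scores_b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    degenerate = var_diff <= 0
    if degenerate and auc_a == auc_b:
        z, p = 0.0, 1.0
    elif degenerate:
        z, p = np.inf, float("nan")
    else:
        z = float((auc_a - auc_b) / np.sqrt(var_diff))
        p = float(2 * stats.norm.sf(abs(z)))
    zq = 1.959963984540054

    def ci(auc, var):
        half = zq * np.sqrt(max(var, 0.0))
        return (max(0.0, auc - half), min(1.0, auc + half))

    return DelongResult(
        auc_a=auc_a, auc_b=auc_b,
        var_a=float(cov[0, 0]), var_b=float(cov[1, 1]), cov_ab=float(cov[0, 1]),
        z=float(z), p=p, ci_a=ci(auc_a, cov[0, 0]), ci_b=ci(auc_b, cov[1, 1]),
        degenerate=bool(degenerate),
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def hosmer_lemeshow(
    probs: np.ndarray, y: np.ndarray, groups: int = 10
) -> tuple[float, float, pd.DataFrame]:
    """Hosmer-Lemeshow goodness-of-fit over probability-decile groups.

    chi^2 = sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)) with g-2 df.  Groups
    emptied by ties are merged with their neighbor (quantile binning with
    duplicate edges dropped).
    """
    probs = np.asarray(probs, float)
    y = np.asarray(y).astype(int)
    bins = pd.qcut(probs, q=groups, duplicates="drop")
    tab = pd.DataFrame({"p": probs, "y": y, "bin": bins}).groupby("bin", observed=True)
    summary = tab.agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"),
                      mean_pred=("p", "mean"), obs_rate=("y", "mean"))
    g = len(summary)
    if g < 3:
        raise ValueError("too few distinct probability groups for the HL test")
    o = summary["observed"].to_numpy(float)
    e = summary["expected"].to_numpy(float)
    nn = summary["n"].to_numpy(float)
    denom = e * (1 - e / nn)
    denom = np.where(denom <= 0, np.nan, denom)
    chi2 = float(np.nansum((o - e) ** 2 / denom))
    p = float(stats.chi2.sf(chi2, df=g - 2))
    return chi2, p, summary.reset_index(drop=True)


def calibration(
    probs: np.ndarray,
    y: np.ndarray,
    bootstrap: int = 1000,
    groups: int = 10,
    seed: int = 0,
) -> dict:
    """Decile calibration curve with bootstrap bias correction + HL test.

    The apparent curve is (mean predicted, observed rate) per decile; the
    bias-corrected observed rates are ``2*apparent - mean(bootstrap)`` over
    ``bootstrap`` resamples binned at the apparent edges.
    """
    probs = np.asarray(probs, float)
    if np.any((probs <= 0) | (probs >= 1)):
        probs = np.clip(probs, 1e-6, 1 - 1e-6)
    y = np.asarray(y).astype(int)
    chi2, p, summary = hosmer_lemeshow(probs, y, groups)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, groups + 1)))
    rng = np.random.default_rng(seed)
    boot = np.full((bootstrap, len(summary)), np.nan)
    idx_bin = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, len(edges) - 2)
    for b in range(bootstrap):
        take = rng.integers(0, len(y), len(y))
        df = pd.DataFrame({"bin": idx_bin[take], "y": y[take]})
        rates = df.groupby("bin")["y"].mean()
        boot[b, rates.index.to_numpy()[: len(summary)]] = rates.to_numpy()[: len(summary)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boot_mean = np.nanmean(boot, axis=0)
    apparent = summary["obs_rate"].to_numpy()
    corrected = np.clip(2 * apparent - boot_mean, 0, 1)
    curve = pd.DataFrame(
        {
            "mean_predicted": summary["mean_pred"],
            "observed": apparent,
            "bias_corrected": corrected,
            "n": summary["n"],
        }
    )
    return {"hl_chi2": chi2, "hl_p": p, "curve": curve}


# ---------------------------------------------------------------------------
# Decision curves
# ---------------------------------------------------------------------------


def decision_curve(
    probs: np.ndarray, y: np.ndarray, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) vs treat-all/treat-none."""
    probs = np.asarray(probs, float)
    y = np.asarray(y).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = probs >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        w = pt / (1 - pt)
        rows.append(
            {
                "threshold": pt,
                "net_benefit": tp - fp * w,
                "treat_all": prev - (1 - prev) * w,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AUC sample size (Hanley-McNeil)
# ---------------------------------------------------------------------------


def _hanley_mcneil_var(theta: float, n_pos: int, n_neg: int) -> float:
    q1 = theta / (2 - theta)
    q2 = 2 * theta ** 2 / (1 + theta)
    return (
        theta * (1 - theta)
        + (n_pos - 1) * (q1 - theta ** 2)
        + (n_neg - 1) * (q2 - theta ** 2)
    ) / (n_pos * n_neg)


def auc_sample_size(
    auc_alt: float = 0.80,
    auc_null: float = 0.50,
    power: float = 0.90,
    alpha: float = 0.05,
    prevalence: float = 0.70,
    *,
    sided: str = "two",
    group_rounding: str = "floor",
    max_n: int = 100_000,
) -> int:
    """Smallest total N detecting ``auc_alt`` against ``auc_null``.

    Uses the Hanley-McNeil variance approximation (Q1 = theta/(2-theta),
    Q2 = 2 theta^2/(1+theta)); positives are ``prevalence`` of the cohort,
    with group sizes formed by the chosen integer rounding before power
    evaluation.  Power = Phi((theta1-theta0 - z_alpha*SE0)/SE1).
    """
    if not (auc_null < auc_alt < 1):
        raise ValueError("need auc_null < auc_alt < 1")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1 - alpha / (2 if sided == "two" else 1))
    z_beta = stats.norm.ppf(power)
    rounder = {"floor": np.floor, "nearest": np.round, "ceil": np.ceil}[group_rounding]
    for n in range(4, max_n):
        n_pos = int(rounder(prevalence * n))
        n_neg = n - n_pos
        if n_pos < 2 or n_neg < 2:
            continue
        se0 = np.sqrt(_hanley_mcneil_var(auc_null, n_pos, n_neg))
        se1 = np.sqrt(_hanley_mcneil_var(auc_alt, n_pos, n_neg))
        z = (auc_alt - auc_null - z_alpha * se0) / se1
        if z >= z_beta:
            return n
    raise ValueError("no feasible sample size below max_n")
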