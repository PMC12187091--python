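"""Overall-survival analysis stage.

SMOTE rebalancing of the training labels, Cox proportional-hazards models
(lifelines, Efron tie handling) with optional bidirectional AIC stepwise,
Harrell's concordance index and a horizon-restricted variant, Kaplan-Meier
curves with the log-rank test, and the maximally selected log-rank cutpoint
used to split patients into high-/low-risk groups.

The horizon-restricted C-index simply truncates the comparable-pair set to
pairs anchored on events before the horizon (no IPCW reweighting); it is an
approximation to inverse-probability-weighted time-dependent estimators and
is labeled as such in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "smote",
    "follow_up_filter",
    "cox_fit",
    "stepwise_cox",
    "harrell_c",
    "horizon_c",
    "km_logrank",
    "optimal_cutpoint",
]


def smote(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling: balance classes by interpolation.

    Each synthetic sample lies on the segment between a minority sample and
    one of its k minority-class nearest neighbors (lambda ~ U[0,1] per
    sample).  Original rows are returned unchanged, first, in input order.
    If the minority class has fewer than k+1 samples, k is reduced with a
    warning.
    """
    is_frame = isinstance(X, pd.DataFrame)
    Xa = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    if counts[0] == counts[1]:
        return (X.copy() if is_frame else Xa.copy()), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    minor = Xa[y == minority]
    if len(minor) < 2:
        raise ValueError("minority class needs >= 2 samples")
    if len(minor) <= k:
        k = len(minor) - 1
        warnings.warn(f"minority class small: k reduced to {k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minor)
    _, idx = nn.kneighbors(minor)  # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(minor), n_needed)
    pick = rng.integers(1, k + 1, n_needed)
    lam = rng.random(n_needed)[:, None]
    synth = minor[base] + lam * (minor[idx[base, pick]] - minor[base])
    X_out = np.vstack([Xa, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    if is_frame:
        synth_idx = [f"synthetic_{i}" for i in range(n_needed)]
        X_out = pd.DataFrame(
            X_out, columns=X.columns, index=list(X.index) + synth_idx
        )
    return X_out, y_out


def follow_up_filter(
    df: pd.DataFrame,
    min_months: float = 24.0,
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Keep subjects with an observed event or follow-up >= ``min_months``.

    Mirrors the cohort-assembly rule of excluding event-free subjects whose
    follow-up is shorter than 2 years.
    """
    keep = (df[event_col] == 1) | (df[time_col] >= min_months)
    return df.loc[keep]


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------


def _survival_frame(X, time, event) -> pd.DataFrame:
    df = pd.DataFrame(X).copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    if (df["_time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def cox_fit(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    *,
    stepwise: bool = False,
    penalizer: float = 0.0,
) -> CoxPHFitter:
    """Cox proportional-hazards fit (Efron partial likelihood for ties).

    Returns the fitted :class:`lifelines.CoxPHFitter`; hazard ratios with CIs
    are in ``fitter.summary``.  Perfect separation / monotone likelihood is
    reported by lifelines as a convergence warning; use a small ``penalizer``
    to stabilize such fits.  With ``stepwise=True`` a bidirectional AIC
    search over the columns of ``X`` is performed first.
    """
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events: Cox model undefined")
    if stepwise:
        terms = _stepwise_terms(X, time, event, penalizer)
        X = X[terms] if terms else X.iloc[:, :0]
    df = _survival_frame(X, time, event)
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event")
    return cph


def _stepwise_terms(X, time, event, penalizer) -> list[str]:
    def aic(terms: list[str]) -> float:
        if not terms:
            return np.inf  # lifelines needs >= 1 covariate; intercept-only skipped
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    _survival_frame(X[terms], time, event),
                    duration_col="_time", event_col="_event",
                )
            return float(cph.AIC_partial_)
        except Exception:
            return np.inf

    selected: list[str] = []
    best = np.inf
    for _ in range(50):
        moves = []
        for term in X.columns:
            trial = selected + [term] if term not in selected else [
                t for t in selected if t != term
            ]
            moves.append((aic(trial), trial))
        moves.sort(key=lambda m: m[0])
        if moves and moves[0][0] < best - 1e-9:
            best, selected = moves[0]
        else:
            break
    return selected


def stepwise_cox(X: pd.DataFrame, time, event, penalizer: float = 0.0) -> CoxPHFitter:
    return cox_fit(X, time, event, stepwise=True, penalizer=penalizer)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def _comparable_pairs(time, event, horizon=None):
    """Boolean matrix P[i, j]: pair (i anchor, j later) usable for concordance."""
    t = np.asarray(time, float)
    e = np.asarray(event, int).astype(bool)
    ti = t[:, None]
    tj = t[None, :]
    anchor = e[:, None]
    comp = anchor & ((ti < tj) | ((ti == tj) & ~e[None, :]))
    np.fill_diagonal(comp, False)
    if horizon is not None:
        comp &= ti < horizon
    return comp


def harrell_c(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C: concordant / comparable pairs, ties in risk credited 0.5.

    A pair is comparable when the earlier subject had an event (censored
    subjects anchor no pair); pairs whose ordering is hidden by censoring are
    excluded.
    """
    risk = np.asarray(risk, float)
    comp = _comparable_pairs(time, event)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = (ri > rj) & comp
    ties = (ri == rj) & comp
    return float((concordant.sum() + 0.5 * ties.sum()) / n_comp)


def horizon_c(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray, horizon: float
) -> float:
    """Harrell-type C restricted to pairs anchored on events before ``horizon``."""
    risk = np.asarray(risk, float)
    e = np.asarray(event, int)
    t = np.asarray(time, float)
    if not np.any((t < horizon) & (e == 1)):
        raise ValueError(f"no events before horizon {horizon}")
    comp = _comparable_pairs(t, e, horizon=horizon)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs before horizon")
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = (ri > rj) & comp
    ties = (ri == rj) & comp
    return float((concordant.sum() + 0.5 * ties.sum()) / n_comp)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / cutpoint
# ---------------------------------------------------------------------------


@dataclass
class KmResult:
    curves: dict[object, pd.DataFrame]
    chi2: float
    p: float


def km_logrank(time, event, groups) -> KmResult:
    """Product-limit curves per group plus the log-rank test across groups."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    curves = {}
    for lab in labels:
        sel = g == lab
        if not sel.any():
            raise ValueError(f"group {lab!r} empty")
        km = KaplanMeierFitter()
        km.fit(t[sel], e[sel])
        curves[lab] = km.survival_function_.rename(
            columns={"KM_estimate": "survival"}
        ).reset_index(names="time")
    res = multivariate_logrank_test(t, g, e)
    return KmResult(curves=curves, chi2=float(res.test_statistic), p=float(res.p_value))


def _logrank_chi2(time, event, split) -> float:
    res = multivariate_logrank_test(time, split.astype(int), event)
    return float(res.test_statistic)


def optimal_cutpoint(
    score: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    minprop: float = 0.1,
) -> tuple[float, float, float]:
    """Maximally selected log-rank cutpoint on a risk score.

    Scans candidate cutoffs (midpoints between consecutive distinct scores)
    leaving at least ``minprop`` of the cohort on each side, and returns
    ``(cutoff, chi2, p)`` for the split maximizing the log-rank statistic.
    The reported p is the naive log-rank p at the selected cutoff (not
    corrected for the maximal selection).
    """
    score = np.asarray(score, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    uniq = np.unique(score)
    if len(uniq) < 2:
        raise ValueError("constant score: no admissible cutoff")
    mids = (uniq[:-1] + uniq[1:]) / 2
    n = len(score)
    best = None
    for c in mids:
        high = score > c
        k = high.sum()
        if k < minprop * n or (n - k) < minprop * n:
            continue
        chi2 = _logrank_chi2(t, e, high)
        if best is None or chi2 > best[1]:
            best = (float(c), chi2)
    if best is None:
        raise ValueError("no cutoff satisfies the minprop constraint")
    from scipy import stats as _st

    return best[0], best[1], float(_st.chi2.sf(best[1], df=1))
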