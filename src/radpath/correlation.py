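"""Radiology-pathology correlation analysis.

Spearman rank correlations between selected radiomic features and slide-level
pathologic features (NMF/CSDF, per IHC marker), Benjamini-Hochberg FDR
control at 0.05 across the whole family of tests, strength classification of
the coefficients, and per-marker significant-pair summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman_matrix",
    "fdr_bh",
    "classify_strength",
    "correlate",
    "count_pairs",
]


def spearman_matrix(
    radiomic: pd.DataFrame, pathologic: pd.DataFrame, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average-rank Spearman rho and t-approximation p per feature pair.

    Rows are paired by index (patient id); missing values are handled
    pairwise-complete.  Cells with fewer than ``min_pairs`` complete pairs,
    or with a constant column, are NaN.
    """
    common = radiomic.index.intersection(pathologic.index)
    if len(common) < min_pairs:
        raise ValueError("too few paired samples")
    ra = radiomic.loc[common]
    pa = pathologic.loc[common]
    rho = pd.DataFrame(index=ra.columns, columns=pa.columns, dtype=float)
    pval = pd.DataFrame(index=ra.columns, columns=pa.columns, dtype=float)
    for rc in ra.columns:
        x = ra[rc].to_numpy(dtype=float)
        for pc in pa.columns:
            y = pa[pc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue
            res = stats.spearmanr(x[ok], y[ok])
            rho.loc[rc, pc] = float(res.statistic)
            pval.loc[rc, pc] = float(res.pvalue)
    return rho, pval


def fdr_bh(pvalues: np.ndarray, threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, significant flags).

    NaN p-values are excluded from the family and stay NaN / not significant.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    q = np.full(flat.shape, np.nan)
    sig = np.zeros(flat.shape, dtype=bool)
    if ok.any():
        rej, qv, _, _ = multipletests(flat[ok], alpha=threshold, method="fdr_bh")
        q[ok] = qv
        sig[ok] = rej
    return q.reshape(p.shape), sig.reshape(p.shape)


def classify_strength(rho: float) -> str:
    """|rho| < 0.3 weak; 0.3..0.7 (inclusive) moderate; > 0.7 strong."""
    a = abs(float(rho))
    if a > 1:
        raise ValueError("|rho| must not exceed 1")
    if a < 0.3:
        return "weak"
    if a <= 0.7:
        return "moderate"
    return "strong"


def correlate(
    radiomic: pd.DataFrame,
    pathologic_by_marker: dict[str, pd.DataFrame],
    threshold: float = 0.05,
    *,
    fdr_scope: str = "pooled",
) -> pd.DataFrame:
    """Full correlation analysis across markers; long-format result.

    ``fdr_scope="pooled"`` corrects one family across all
    (radiomic x pathologic x marker) tests; ``"per_marker"`` corrects each
    marker separately.  Columns: feature_rad, feature_path, marker, rho, p,
    q, significant, strength, sign.
    """
    frames = []
    for marker, path_df in pathologic_by_marker.items():
        rho, pval = spearman_matrix(radiomic, path_df)
        long = (
            rho.stack(future_stack=True).rename("rho").to_frame()
            .join(pval.stack(future_stack=True).rename("p"))
            .reset_index()
            .rename(columns={"level_0": "feature_rad", "level_1": "feature_path"})
        )
        long.insert(2, "marker", marker)
        frames.append(long)
    result = pd.concat(frames, ignore_index=True)
    if fdr_scope == "pooled":
        q, sig = fdr_bh(result["p"].to_numpy(), threshold)
        result["q"], result["significant"] = q, sig
    elif fdr_scope == "per_marker":
        result["q"] = np.nan
        result["significant"] = False
        for marker in result["marker"].unique():
            sel = result["marker"] == marker
            q, sig = fdr_bh(result.loc[sel, "p"].to_numpy(), threshold)
            result.loc[sel, "q"] = q
            result.loc[sel, "significant"] = sig
    else:
        raise ValueError("fdr_scope must be 'pooled' or 'per_marker'")
    result["strength"] = [
        classify_strength(r) if np.isfinite(r) else "undefined" for r in result["rho"]
    ]
    result["sign"] = np.sign(result["rho"]).fillna(0).astype(int)
    return result


def count_pairs(result: pd.DataFrame) -> pd.DataFrame:
    """Per-marker summary over significant pairs: count, |rho| range, signs."""
    sig = result[result["significant"] == True]  # noqa: E712
    if sig.empty:
        return pd.DataFrame(
            columns=["marker", "n_pairs", "abs_rho_min", "abs_rho_max",
                     "n_positive", "n_negative"]
        )
    rows = []
    for marker, grp in sig.groupby("marker", sort=True):
        rows.append(
            {
                "marker": marker,
                "n_pairs": len(grp),
                "abs_rho_min": grp["rho"].abs().min(),
                "abs_rho_max": grp["rho"].abs().max(),
                "n_positive": int((grp["rho"] > 0).sum()),
                "n_negative": int((grp["rho"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows)
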