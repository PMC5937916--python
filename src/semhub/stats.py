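"""Statistical summaries for the simulation results.

Wraps statsmodels for the repeated-measures ANOVA used on the homonym task
(each trained model is a case; impairment, dominance and cue are within-model
factors) and for the standardized-beta regressions of per-trial accuracy on
psycholinguistic predictors, including the hierarchical step that adds
probe-target co-occurrence rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools import add_constant

__all__ = ["rm_anova", "ols_standardized", "hierarchical_step",
           "correlation_matrix"]


def rm_anova(df: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> pd.DataFrame:
    """Repeated-measures ANOVA; returns the statsmodels effect table."""
    res = AnovaRM(df, depvar=dv, subject=subject, within=within).fit()
    return res.anova_table


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant predictor: rank-deficient design")
    return (x - x.mean()) / sd


def ols_standardized(y: np.ndarray, X: dict[str, np.ndarray]) -> dict:
    """OLS of y on the named predictors, all variables z-scored.

    Returns {"r2", "p_model", "beta": {name: beta}, "p": {name: p}, "n"}.
    """
    names = list(X)
    Z = np.column_stack([_zscore(np.asarray(X[k], dtype=float))
                         for k in names])
    yz = _zscore(np.asarray(y, dtype=float))
    fit = OLS(yz, add_constant(Z)).fit()
    return {
        "r2": float(fit.rsquared),
        "p_model": float(fit.f_pvalue),
        "beta": {k: float(fit.params[i + 1]) for i, k in enumerate(names)},
        "p": {k: float(fit.pvalues[i + 1]) for i, k in enumerate(names)},
        "n": int(len(yz)),
    }


def hierarchical_step(y: np.ndarray, base: dict[str, np.ndarray],
                      added: dict[str, np.ndarray]) -> dict:
    """F-change test for adding predictors to a regression.

    Returns {"delta_r2", "f_change", "p_change", "df"} plus the full-model
    standardized summary under "full".
    """
    fit0 = ols_standardized(y, base)
    full = {**base, **added}
    fit1 = ols_standardized(y, full)
    n = fit1["n"]
    q = len(added)
    df2 = n - len(full) - 1
    delta = fit1["r2"] - fit0["r2"]
    denom = (1 - fit1["r2"]) / df2
    f = delta / q / denom if denom > 0 else np.inf
    p = float(sps.f.sf(f, q, df2))
    return {"delta_r2": float(delta), "f_change": float(f), "p_change": p,
            "df": (q, df2), "full": fit1, "base": fit0}


def correlation_matrix(cols: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations (and p-values in a companion frame)."""
    names = list(cols)
    n = len(names)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = sps.pearsonr(cols[names[i]],
                                             cols[names[j]])[0]
    return pd.DataFrame(r, index=names, columns=names)
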