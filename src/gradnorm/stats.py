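"""Group-comparison statistics and multiple-testing correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def welch_t(x, y):
    """Welch (unequal-variance) two-sample t-test: returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_t_table(values: pd.DataFrame, group_a_idx, group_b_idx) -> pd.DataFrame:
    """Per-column Welch t of group A vs group B with BH-adjusted q.

    ``values`` is subjects x features; positive t means group A larger.
    """
    ts, ps = [], []
    for col in values.columns:
        t, p = welch_t(values.loc[group_a_idx, col], values.loc[group_b_idx, col])
        ts.append(t)
        ps.append(p)
    ps = np.asarray(ps)
    q = np.full(len(ps), np.nan)
    ok = np.isfinite(ps)  # degenerate (zero-variance) features stay NaN
    if ok.any():
        q[ok] = fdr_bh(ps[ok])
    return pd.DataFrame({"feature": values.columns, "t": ts, "p": ps,
                         "q": q})


def pearson_table(x, ys: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of ``x`` against each column of ``ys`` with BH q-values."""
    x = np.asarray(x, dtype=float)
    rows = []
    for col in ys.columns:
        y = ys[col].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 paired observations for {col}")
        if np.std(y[mask]) == 0 or np.std(x[mask]) == 0:
            raise ValueError(f"constant column in correlation: {col}")
        r, p = sps.pearsonr(x[mask], y[mask])
        rows.append({"scale": col, "r": float(r), "p": float(p),
                     "n": int(mask.sum())})
    out = pd.DataFrame(rows)
    out["q"] = fdr_bh(out["p"])
    return out
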