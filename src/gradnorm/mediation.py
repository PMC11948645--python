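"""Bootstrap mediation analysis (single mediator, standardized paths).

Decomposes a group -> outcome effect into a path through a mediator:

    a : X -> M            (mediator on group)
    b : M -> Y | X        (outcome on mediator, controlling group)
    c': X -> Y | M        (direct effect)
    c : X -> Y            (total effect; c = c' + a*b in the linear system)

All variables are standardized to unit variance so path weights are
standardized regression coefficients. Significance of the indirect effect
a*b comes from a subject-level percentile bootstrap (default 5,000
resamples): subjects are resampled with replacement, all paths refit, and
the CI/p-value read off the bootstrap distribution. Resamples in which the
group indicator collapses to a single level are redrawn (count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fdr_bh

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_redrawn: int
    seed: int


def _standardize(v):
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("constant variable in mediation model")
    return (v - v.mean()) / sd


def _paths(x, m, y):
    """Closed-form OLS paths for standardized (x, m, y) arrays.

    Supports batched input of shape (B, n); returns arrays of shape (B,).
    """
    xm = x.mean(axis=-1, keepdims=True)
    mm = m.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    xc, mc, yc = x - xm, m - mm, y - ym
    sxx = np.sum(xc * xc, axis=-1)
    sxm = np.sum(xc * mc, axis=-1)
    smm = np.sum(mc * mc, axis=-1)
    sxy = np.sum(xc * yc, axis=-1)
    smy = np.sum(mc * yc, axis=-1)
    syy = np.sum(yc * yc, axis=-1)
    # a: standardized slope of m ~ x
    a = sxm / np.sqrt(sxx * smm)
    # y ~ x + m, slopes rescaled to standardized variables
    det = sxx * smm - sxm**2
    c_prime = (smm * sxy - sxm * smy) / det * np.sqrt(sxx / syy)
    b = (sxx * smy - sxm * sxy) / det * np.sqrt(smm / syy)
    c = sxy / np.sqrt(sxx * syy)
    return a, b, c, c_prime


def mediate(x, m, y, n_boot: int = 5000, seed: int = 0,
            covariates=None) -> MediationResult:
    """Single-mediator bootstrap mediation of x -> m -> y.

    Parameters
    ----------
    x:
        Group indicator (two levels; any numeric/binary coding).
    m, y:
        Mediator and outcome values per subject.
    n_boot:
        Bootstrap resamples for the percentile CI and two-sided p.
    seed:
        Seed for the resampling RNG; results are deterministic given it.
    covariates:
        Optional nuisance matrix (n x q), e.g. age: x, m and y are
        residualized on it (with intercept) before path estimation, so
        shared within-sample trends cannot masquerade as mediation.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    if len(np.unique(x)) != 2:
        raise ValueError("x must have exactly two levels")
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, float)
                             .reshape(n, -1)])
        proj = C @ np.linalg.pinv(C)
        x, m, y = x - proj @ x, m - proj @ m, y - proj @ y
    xs, ms, ys = _standardize(x), _standardize(m), _standardize(y)
    a, b, c, c_prime = _paths(xs, ms, ys)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    filled = 0
    n_redrawn = 0
    while filled < n_boot:
        batch = n_boot - filled
        idx = rng.integers(0, n, size=(batch, n))
        xb = xs[idx]
        ok = xb.std(axis=1) > 0
        n_redrawn += int((~ok).sum())
        idx = idx[ok]
        if idx.shape[0] == 0:
            continue
        # re-standardize within each resample so paths stay standardized
        ab, bb, _, _ = _paths(_bstd(xs[idx]), _bstd(ms[idx]), _bstd(ys[idx]))
        boots[filled : filled + idx.shape[0]] = ab * bb
        filled += idx.shape[0]
    if n_redrawn:
        log.info("redrew %d bootstrap resamples with a single group level",
                 n_redrawn)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p_lo = np.mean(boots < 0) + 0.5 * np.mean(boots == 0)
    p = float(min(1.0, 2.0 * min(p_lo, 1.0 - p_lo)))
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), ci_low=float(ci_low), ci_high=float(ci_high),
        p=p, n_boot=n_boot, n_redrawn=n_redrawn, seed=seed,
    )


def _bstd(v):
    mu = v.mean(axis=-1, keepdims=True)
    sd = v.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (v - mu) / sd


def mediation_by_stage(mediators: pd.DataFrame, x, y, age,
                       bins=((5.0, 12.0), (12.0, 15.0), (15.0, 22.0)),
                       n_boot: int = 5000, seed: int = 0,
                       include_pooled: bool = True,
                       control_age: bool = True) -> pd.DataFrame:
    """Mediation per age bin and per mediator column, plus a pooled run.

    Bins are half-open [lo, hi) except the last, which includes its upper
    edge. Age is partialled out of every cell by default: the bins are
    wide enough that residual within-bin age trends in both mediator and
    outcome would otherwise masquerade as mediation. Bin-mediator cells
    whose resolved sample is too small or whose group indicator has one
    level are flagged and skipped. FDR (BH) is applied across all tested
    cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    rows = []
    stages = [(f"{lo:g}-{hi:g}", lo, hi) for lo, hi in bins]
    if include_pooled:
        stages.append(("all", -np.inf, np.inf))
    last_hi = bins[-1][1]
    for si, (name, lo, hi) in enumerate(stages):
        if name == "all":
            mask = np.ones(len(age), bool)
        else:
            mask = (age >= lo) & ((age < hi) | ((hi == last_hi) & (age == hi)))
        for mi, col in enumerate(mediators.columns):
            cell_seed = (seed * 100003 + si * 1009 + mi * 17) % (2**31)
            row = {"stage": name, "mediator": col, "n": int(mask.sum())}
            try:
                res = mediate(x[mask], mediators[col].to_numpy(float)[mask],
                              y[mask], n_boot=n_boot, seed=cell_seed,
                              covariates=age[mask] if control_age else None)
                row.update(a=res.a, b=res.b, c=res.c, c_prime=res.c_prime,
                           indirect=res.indirect, ci_low=res.ci_low,
                           ci_high=res.ci_high, p=res.p, skipped=False)
            except ValueError as err:
                log.warning("skipping %s / %s: %s", name, col, err)
                row.update(a=np.nan, b=np.nan, c=np.nan, c_prime=np.nan,
                           indirect=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p=np.nan, skipped=True)
            rows.append(row)
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = fdr_bh(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out
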