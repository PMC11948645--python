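"""SHASH normative growth models of age (GAMLSS-style).

A normative model describes the full age-conditional distribution of one
brain feature in a reference population. The response follows a
sinh-arcsinh (SHASH) distribution whose parameters are regressed on age:

    y ~ SHASH(mu, sigma, nu, tau)
    mu        = b0 + f(age) + sex * g(age)        (P-spline smooths)
    log sigma = c0 + h(age)                       (P-spline smooth)
    link(nu)  = constant       (default log link; identity available)
    log tau   = constant

Smooths are cubic P-splines (10 interior knots, second-order difference
penalty). Fitting maximizes the penalized log-likelihood blockwise:
alternating quasi-Newton (L-BFGS-B) steps over the mu block, the sigma
block and the (nu, tau) block until the penalized log-likelihood is stable.
Smoothing weights are either fixed by config or selected by generalized AIC
on a small grid.

Individuals are scored as centiles — the fitted CDF evaluated at their
observed value given their age and sex; 0.5 sits on the normative median.
A fitted model can be transferred to a new cohort by re-estimating only the
mu and log-sigma intercepts while freezing every age-dependent term
(intercept recalibration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .shash import shash_cdf, shash_quantile
from .splines import SplineBasis, basis_for

__all__ = [
    "NormativeConfig",
    "NormativeModel",
    "AgeEffectResult",
    "fit_normative",
    "transfer_recalibrate",
    "centile_scores",
    "normative_median_curve",
    "age_effect_test",
    "sigma_age_test",
]

_CENTILE_EPS = 1e-6


@dataclass(frozen=True)
class NormativeConfig:
    """Structural and fitting choices for one normative model."""

    n_knots: int = 10
    degree: int = 3
    penalty_order: int = 2
    lam_mu: float = 1.0
    lam_sigma: float = 1.0
    select_smoothing: bool = False
    smoothing_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gaic_k: float = 3.0
    nu_link: str = "log"  # "log" (as printed in the model family) or "identity"
    mu_terms: tuple[str, ...] = ("age", "age_sex")
    sigma_terms: tuple[str, ...] = ("age",)
    min_n: int = 50
    max_outer: int = 20
    tol: float = 1e-6
    ridge: float = 1e-8


@dataclass(frozen=True)
class NormativeModel:
    """Fitted per-feature SHASH model; immutable, transferable."""

    config: NormativeConfig
    basis: SplineBasis
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    theta_nu: float
    theta_tau: float
    age_lo: float
    age_hi: float
    meta: dict = field(default_factory=dict, repr=False)

    # ---- prediction -------------------------------------------------
    def predict_params(self, age, sex):
        """(mu, sigma, nu, tau) arrays at the given ages/sexes."""
        age = np.asarray(age, dtype=float)
        if np.any((age < self.age_lo) | (age > self.age_hi)):
            warnings.warn(
                "ages outside the fitted range; normative curves are "
                "extrapolated at the boundary",
                stacklevel=2,
            )
        Xmu = _design_mu(self.basis, age, _sex_indicator(sex, age.shape),
                         self.config.mu_terms)
        Xsg = _design_sigma(self.basis, age, self.config.sigma_terms)
        mu = Xmu @ self.beta_mu
        sigma = np.exp(np.clip(Xsg @ self.beta_sigma, -20.0, 20.0))
        nu = _nu_from_theta(self.theta_nu, self.config.nu_link)
        tau = float(np.exp(self.theta_tau))
        return mu, sigma, np.full_like(mu, nu), np.full_like(mu, tau)

    def median(self, age, sex):
        mu, sigma, nu, tau = self.predict_params(age, sex)
        return shash_quantile(0.5, (mu, sigma, nu, tau))

    def quantile(self, p, age, sex):
        mu, sigma, nu, tau = self.predict_params(age, sex)
        return shash_quantile(p, (mu, sigma, nu, tau))

    def loglik(self, y, age, sex):
        from .shash import shash_logpdf

        mu, sigma, nu, tau = self.predict_params(age, sex)
        return float(np.sum(shash_logpdf(np.asarray(y, float), (mu, sigma, nu, tau))))


@dataclass(frozen=True)
class AgeEffectResult:
    statistic: float
    df: float
    p: float
    sign: int = 0  # sign of the fitted trend (sigma test only)


# ---------------------------------------------------------------------------
# design matrices and links
# ---------------------------------------------------------------------------

def _sex_indicator(sex, shape=None):
    if sex is None:
        return None
    arr = np.asarray(sex)
    if arr.dtype.kind in "USO":
        ind = (np.char.lower(arr.astype(str)) == "female").astype(float)
    else:
        ind = arr.astype(float)
    if shape is not None and ind.shape == ():
        ind = np.full(shape, float(ind))
    return ind


def _design_mu(basis: SplineBasis, age, sex_ind, mu_terms):
    n = len(age)
    cols = [np.ones((n, 1))]
    if "age" in mu_terms or "age_sex" in mu_terms:
        B = basis.design(age)
        if "age" in mu_terms:
            cols.append(B)
        if "age_sex" in mu_terms:
            if sex_ind is None:
                raise ValueError("age_sex term requested but sex not provided")
            cols.append(sex_ind[:, None] * B)
    return np.concatenate(cols, axis=1)


def _design_sigma(basis: SplineBasis, age, sigma_terms):
    n = len(age)
    cols = [np.ones((n, 1))]
    if "age" in sigma_terms:
        cols.append(basis.design(age))
    return np.concatenate(cols, axis=1)


def _penalty_mu(basis: SplineBasis, lam, mu_terms):
    nb = basis.n_basis
    blocks = [np.zeros((1, 1))]
    P = basis.penalty()
    if "age" in mu_terms:
        blocks.append(lam * P)
    if "age_sex" in mu_terms:
        blocks.append(lam * P)
    return _blockdiag(blocks)


def _penalty_sigma(basis: SplineBasis, lam, sigma_terms):
    blocks = [np.zeros((1, 1))]
    if "age" in sigma_terms:
        blocks.append(lam * basis.penalty())
    return _blockdiag(blocks)


def _blockdiag(blocks):
    n = sum(b.shape[0] for b in blocks)
    out = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        out[i : i + k, i : i + k] = b
        i += k
    return out


def _nu_from_theta(theta, link):
    if link == "log":
        return float(np.exp(theta))
    if link == "identity":
        return float(theta)
    raise ValueError(f"unknown nu link: {link}")


# ---------------------------------------------------------------------------
# likelihood core (negative log-likelihood + analytic gradients)
# ---------------------------------------------------------------------------

def _nll_terms(y, mu, logsig, nu, tau):
    """Per-observation NLL pieces and the shared derivative terms."""
    sigma = np.exp(logsig)
    z = (y - mu) / sigma
    a = np.arcsinh(z)
    u = np.clip(tau * a - nu, -30.0, 30.0)
    r = np.sinh(u)
    logcosh = np.abs(u) + np.log1p(np.exp(-2.0 * np.abs(u))) - np.log(2.0)
    nll = (
        0.5 * r**2
        - np.log(tau)
        - logcosh
        + logsig
        + 0.5 * np.log1p(z**2)
        + 0.5 * np.log(2.0 * np.pi)
    )
    core = r * np.cosh(u) - np.tanh(u)  # d nll / d u
    sq = np.sqrt(1.0 + z**2)
    dz = core * tau / sq + z / (1.0 + z**2)  # d nll / d z
    return nll, core, dz, z, a, sigma


def _pack_state(y, Xmu, Xsg, Pmu, Psg, nu_link):
    y = np.asarray(y, dtype=float)

    def full_nll(beta_mu, beta_sg, th_nu, th_tau, with_penalty=True):
        mu = Xmu @ beta_mu
        logsig = np.clip(Xsg @ beta_sg, -20.0, 20.0)
        nu = np.exp(th_nu) if nu_link == "log" else th_nu
        tau = np.exp(np.clip(th_tau, -5.0, 5.0))
        nll, *_ = _nll_terms(y, mu, logsig, nu, tau)
        val = float(np.sum(nll))
        if with_penalty:
            val += 0.5 * float(beta_mu @ Pmu @ beta_mu)
            val += 0.5 * float(beta_sg @ Psg @ beta_sg)
        return val

    def mu_obj(beta_mu, beta_sg, th_nu, th_tau):
        mu = Xmu @ beta_mu
        logsig = np.clip(Xsg @ beta_sg, -20.0, 20.0)
        nu = np.exp(th_nu) if nu_link == "log" else th_nu
        tau = np.exp(np.clip(th_tau, -5.0, 5.0))
        nll, core, dz, z, a, sigma = _nll_terms(y, mu, logsig, nu, tau)
        val = float(np.sum(nll)) + 0.5 * float(beta_mu @ Pmu @ beta_mu)
        grad = Xmu.T @ (-dz / sigma) + Pmu @ beta_mu
        return val, grad

    def sg_obj(beta_sg, beta_mu, th_nu, th_tau):
        mu = Xmu @ beta_mu
        logsig = np.clip(Xsg @ beta_sg, -20.0, 20.0)
        nu = np.exp(th_nu) if nu_link == "log" else th_nu
        tau = np.exp(np.clip(th_tau, -5.0, 5.0))
        nll, core, dz, z, a, sigma = _nll_terms(y, mu, logsig, nu, tau)
        val = float(np.sum(nll)) + 0.5 * float(beta_sg @ Psg @ beta_sg)
        grad = Xsg.T @ (-dz * z + 1.0) + Psg @ beta_sg
        return val, grad

    def nt_obj(theta, beta_mu, beta_sg):
        th_nu, th_tau = theta
        mu = Xmu @ beta_mu
        logsig = np.clip(Xsg @ beta_sg, -20.0, 20.0)
        nu = np.exp(th_nu) if nu_link == "log" else th_nu
        tau = np.exp(np.clip(th_tau, -5.0, 5.0))
        nll, core, dz, z, a, sigma = _nll_terms(y, mu, logsig, nu, tau)
        val = float(np.sum(nll))
        g_nu = -float(np.sum(core))
        if nu_link == "log":
            g_nu *= nu
        g_tau = float(np.sum(core * a) * tau) - len(y)
        return val, np.array([g_nu, g_tau])

    def joint_obj(theta):
        p_mu = Xmu.shape[1]
        p_sg = Xsg.shape[1]
        beta_mu = theta[:p_mu]
        beta_sg = theta[p_mu : p_mu + p_sg]
        th_nu, th_tau = theta[p_mu + p_sg :]
        mu = Xmu @ beta_mu
        logsig = np.clip(Xsg @ beta_sg, -20.0, 20.0)
        nu = np.exp(th_nu) if nu_link == "log" else th_nu
        tau = np.exp(np.clip(th_tau, -5.0, 5.0))
        nll, core, dz, z, a, sigma = _nll_terms(y, mu, logsig, nu, tau)
        val = (float(np.sum(nll))
               + 0.5 * float(beta_mu @ Pmu @ beta_mu)
               + 0.5 * float(beta_sg @ Psg @ beta_sg))
        g_mu = Xmu.T @ (-dz / sigma) + Pmu @ beta_mu
        g_sg = Xsg.T @ (-dz * z + 1.0) + Psg @ beta_sg
        g_nu = -float(np.sum(core))
        if nu_link == "log":
            g_nu *= nu
        g_tau = float(np.sum(core * a) * tau) - len(y)
        return val, np.concatenate([g_mu, g_sg, [g_nu, g_tau]])

    return full_nll, mu_obj, sg_obj, nt_obj, joint_obj


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_normative(y, age, sex=None, config: NormativeConfig | None = None,
                  basis: SplineBasis | None = None) -> NormativeModel:
    """Fit one feature's SHASH normative model by blockwise penalized ML.

    Parameters
    ----------
    y, age:
        Feature values and ages (years), one entry per subject.
    sex:
        "male"/"female" strings or a 0/1 indicator (1 = female). Required
        when the mu structure contains the age-by-sex smooth.
    config:
        :class:`NormativeConfig`; defaults follow the module docstring.
    basis:
        Optional pre-built (centered) spline basis; otherwise built from
        the observed age range.
    """
    config = config or NormativeConfig()
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if y.shape != age.shape:
        raise ValueError("y and age must have the same length")
    if len(y) < config.min_n:
        raise ValueError(f"n={len(y)} below the configured minimum {config.min_n}")
    if np.ptp(age) <= 0:
        raise ValueError("age is constant; cannot model age effects")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite feature values")

    if basis is None:
        basis = basis_for(age, config.n_knots, config.degree, config.penalty_order)
    sex_ind = _sex_indicator(sex, age.shape)
    if "age_sex" in config.mu_terms and sex_ind is None:
        raise ValueError("sex is required for the age-by-sex smooth")

    if config.select_smoothing:
        best = None
        for lam in config.smoothing_grid:
            cand = replace(config, lam_mu=lam, lam_sigma=lam, select_smoothing=False)
            m = fit_normative(y, age, sex, cand, basis=basis)
            gaic = -2.0 * m.meta["loglik"] + config.gaic_k * m.meta["edf_total"]
            if best is None or gaic < best[0]:
                best = (gaic, m)
        model = best[1]
        model.meta["gaic"] = best[0]
        return model

    Xmu = _design_mu(basis, age, sex_ind, config.mu_terms)
    Xsg = _design_sigma(basis, age, config.sigma_terms)
    Pmu = _penalty_mu(basis, config.lam_mu, config.mu_terms)
    Psg = _penalty_sigma(basis, config.lam_sigma, config.sigma_terms)

    # fit on the standardized response: a fixed smoothing weight then means
    # the same thing regardless of the feature's units, and centiles are
    # exactly equivariant under affine transforms of the data
    y_loc = float(np.mean(y))
    y_scale = float(np.std(y))
    if y_scale <= 0:
        raise ValueError("feature is constant; nothing to model")
    y = (y - y_loc) / y_scale

    # deterministic initialization: penalized least squares for mu,
    # log residual SD for sigma, (near-)zero skew, unit tail weight
    A = Xmu.T @ Xmu + Pmu + config.ridge * np.eye(Xmu.shape[1])
    beta_mu = np.linalg.solve(A, Xmu.T @ y)
    resid = y - Xmu @ beta_mu
    beta_sg = np.zeros(Xsg.shape[1])
    beta_sg[0] = np.log(max(np.std(resid), 1e-8))
    th_nu = -6.0 if config.nu_link == "log" else 0.0
    th_tau = 0.0

    full_nll, mu_obj, sg_obj, nt_obj, joint_obj = _pack_state(
        y, Xmu, Xsg, Pmu, Psg, config.nu_link)
    nt_bounds = [(-12.0, 3.0) if config.nu_link == "log" else (-10.0, 10.0),
                 (-3.0, 3.0)]

    prev = full_nll(beta_mu, beta_sg, th_nu, th_tau)
    converged = False
    n_outer = 0
    for n_outer in range(1, config.max_outer + 1):
        res = optimize.minimize(mu_obj, beta_mu, args=(beta_sg, th_nu, th_tau),
                                jac=True, method="L-BFGS-B",
                                options={"maxiter": 100})
        beta_mu = res.x
        res = optimize.minimize(sg_obj, beta_sg, args=(beta_mu, th_nu, th_tau),
                                jac=True, method="L-BFGS-B",
                                options={"maxiter": 100})
        beta_sg = res.x
        res = optimize.minimize(nt_obj, np.array([th_nu, th_tau]),
                                args=(beta_mu, beta_sg), jac=True,
                                method="L-BFGS-B", bounds=nt_bounds,
                                options={"maxiter": 100})
        th_nu, th_tau = res.x
        cur = full_nll(beta_mu, beta_sg, th_nu, th_tau)
        if abs(prev - cur) < config.tol * (1.0 + abs(cur)):
            converged = True
            prev = cur
            break
        prev = cur

    # joint quasi-Newton polish: the blockwise sweep stalls when blocks are
    # strongly coupled (weak penalties), so finish on the full parameter
    # vector from the blockwise point
    theta0 = np.concatenate([beta_mu, beta_sg, [th_nu, th_tau]])
    bounds = ([(None, None)] * (len(beta_mu) + len(beta_sg))) + nt_bounds
    res = optimize.minimize(joint_obj, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-8})
    if res.fun <= prev:
        beta_mu = res.x[: len(beta_mu)]
        beta_sg = res.x[len(beta_mu) : len(beta_mu) + len(beta_sg)]
        th_nu, th_tau = res.x[-2:]
        prev = float(res.fun)
        converged = True
    if not converged:
        raise RuntimeError(
            f"normative fit did not converge in {config.max_outer} outer "
            f"iterations (last penalized NLL {prev:.6f})"
        )

    sigma_hat = np.exp(np.clip(Xsg @ beta_sg, -20.0, 20.0))
    edf_mu, edf_mu_test = _edf(Xmu, Pmu, 1.0 / sigma_hat**2, config.ridge)
    edf_sg, edf_sg_test = _edf(Xsg, Psg, np.full(len(y), 2.0), config.ridge)
    loglik = -full_nll(beta_mu, beta_sg, th_nu, th_tau, with_penalty=False)
    # map coefficients back to the feature's original units
    beta_mu = beta_mu * y_scale
    beta_mu[0] += y_loc
    beta_sg = beta_sg.copy()
    beta_sg[0] += np.log(y_scale)
    loglik -= len(y) * np.log(y_scale)
    meta = {
        "n": int(len(y)),
        "converged": converged,
        "n_outer": n_outer,
        "loglik": loglik,
        "pen_nll": prev,
        "edf_mu": edf_mu,
        "edf_sigma": edf_sg,
        "edf_mu_test": edf_mu_test,
        "edf_sigma_test": edf_sg_test,
        "edf_total": edf_mu + edf_sg + 2.0,
        "lam_mu": config.lam_mu,
        "lam_sigma": config.lam_sigma,
        "provenance": "fit",
    }
    return NormativeModel(
        config=config, basis=basis, beta_mu=beta_mu, beta_sigma=beta_sg,
        theta_nu=float(th_nu), theta_tau=float(th_tau),
        age_lo=float(np.min(age)), age_hi=float(np.max(age)), meta=meta,
    )


def _edf(X, P, w, ridge):
    """Effective df of a penalized block.

    Returns ``(tr(H), 2 tr(H) - tr(H^2))`` where ``H`` is the coefficient
    shrinkage operator: tr(H) enters model-complexity scores (GAIC); the
    second variant tracks the null mean of the likelihood-ratio statistic
    for dropping the block and is used as LR test df.
    """
    XtWX = X.T @ (w[:, None] * X)
    H = np.linalg.solve(XtWX + P + ridge * np.eye(X.shape[1]), XtWX)
    tr = float(np.trace(H))
    tr2 = float(np.trace(H @ H))
    return tr, 2.0 * tr - tr2


def transfer_recalibrate(model: NormativeModel, y_new, age_new, sex_new=None
                         ) -> NormativeModel:
    """Recalibrate a fitted model to a new cohort.

    Only the mu and log-sigma intercepts are re-estimated by maximum
    likelihood; every spline coefficient and the (nu, tau) constants stay
    frozen, preserving the nonlinear age effects learned on the reference
    cohort.
    """
    y_new = np.asarray(y_new, dtype=float)
    age_new = np.asarray(age_new, dtype=float)
    if len(y_new) == 0:
        raise ValueError("empty transfer cohort")
    cfg = model.config
    sex_ind = _sex_indicator(sex_new, age_new.shape)
    Xmu = _design_mu(model.basis, age_new, sex_ind, cfg.mu_terms)
    Xsg = _design_sigma(model.basis, age_new, cfg.sigma_terms)
    Pmu = np.zeros((Xmu.shape[1],) * 2)
    Psg = np.zeros((Xsg.shape[1],) * 2)
    full_nll, *_ = _pack_state(y_new, Xmu, Xsg, Pmu, Psg, cfg.nu_link)

    base_mu = model.beta_mu.copy()
    base_sg = model.beta_sigma.copy()

    def obj(theta):
        bm = base_mu.copy()
        bs = base_sg.copy()
        bm[0] = theta[0]
        bs[0] = theta[1]
        return full_nll(bm, bs, model.theta_nu, model.theta_tau,
                        with_penalty=False)

    res = optimize.minimize(obj, np.array([base_mu[0], base_sg[0]]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 2000})
    beta_mu = base_mu.copy()
    beta_sg = base_sg.copy()
    beta_mu[0], beta_sg[0] = res.x
    meta = dict(model.meta)
    meta.update(
        provenance="transfer",
        transfer_n=int(len(y_new)),
        intercept_shift_mu=float(beta_mu[0] - base_mu[0]),
        intercept_shift_logsigma=float(beta_sg[0] - base_sg[0]),
    )
    return replace(model, beta_mu=beta_mu, beta_sigma=beta_sg, meta=meta)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def centile_scores(model: NormativeModel, y, age, sex=None) -> np.ndarray:
    """Centile (fitted CDF) of each observation given its age and sex.

    Values are clipped to [1e-6, 1 - 1e-6]; a warning reports clipping.
    """
    y = np.asarray(y, dtype=float)
    mu, sigma, nu, tau = model.predict_params(np.asarray(age, float), sex)
    c = shash_cdf(y, (mu, sigma, nu, tau))
    n_clip = int(np.sum((c < _CENTILE_EPS) | (c > 1 - _CENTILE_EPS)))
    if n_clip:
        warnings.warn(f"{n_clip} centile(s) clipped to [{_CENTILE_EPS}, "
                      f"{1 - _CENTILE_EPS}]", stacklevel=2)
    return np.clip(c, _CENTILE_EPS, 1 - _CENTILE_EPS)


def normative_median_curve(model: NormativeModel, age_grid, sex) -> np.ndarray:
    """Median (50th centile) of the fitted distribution along an age grid."""
    return model.median(np.asarray(age_grid, dtype=float), sex)


# ---------------------------------------------------------------------------
# likelihood-ratio tests on smooth terms
# ---------------------------------------------------------------------------

_TEST_LAM = 1e-8  # smooth terms enter the LR test at full (unpenalized) rank


def _lr_models(y, age, sex, config, drop):
    """Full and nested near-unpenalized ML fits for a term-dropping LR test.

    The LR is computed on maximum-likelihood (not penalized) fits so that
    the dropped block contributes its full column rank as chi-square df; a
    Bartlett-type factor (n - p_full)/n absorbs the finite-sample inflation
    of the statistic.
    """
    test_cfg = replace(config, lam_mu=_TEST_LAM, lam_sigma=_TEST_LAM,
                       select_smoothing=False)
    n_b = config.n_knots + config.degree + 1
    p_full = 1 + n_b * (("age" in config.mu_terms)
                        + ("age_sex" in config.mu_terms)) \
        + 1 + n_b * ("age" in config.sigma_terms) + 2
    if len(np.asarray(y)) < p_full + 10:
        raise ValueError(
            f"n={len(np.asarray(y))} too small for an unpenalized "
            f"likelihood-ratio refit with {p_full} parameters")
    full = fit_normative(y, age, sex, test_cfg)
    null_cfg = replace(test_cfg, **drop)
    null = fit_normative(y, age, sex, null_cfg, basis=full.basis)
    p_full = len(full.beta_mu) + len(full.beta_sigma) + 2
    p_null = len(null.beta_mu) + len(null.beta_sigma) + 2
    df = float(p_full - p_null)
    n = full.meta["n"]
    lr = max(0.0, 2.0 * (full.meta["loglik"] - null.meta["loglik"]))
    lr *= (n - p_full) / n
    return full, lr, df


def age_effect_test(y, age, sex=None, config: NormativeConfig | None = None,
                    model_full: NormativeModel | None = None) -> AgeEffectResult:
    """Likelihood-ratio test of the mu age smooth(s).

    Compares the configured model against a nested fit whose mu structure
    is intercept-only (all age-dependent mu smooths dropped); the sigma, nu
    and tau structures are unchanged. Both fits are (near-)unpenalized ML,
    the df is the column rank of the dropped smooth block, and the LR
    carries a Bartlett-type small-sample correction. ``model_full`` is
    accepted for API symmetry but the test always refits at test settings.
    """
    config = config or NormativeConfig()
    if not config.mu_terms:
        raise ValueError("full model has no mu age terms; test is not nested")
    full, lr, df = _lr_models(y, age, sex, config, {"mu_terms": ()})
    p = float(chi2.sf(lr, df))
    return AgeEffectResult(statistic=lr, df=df, p=p)


def sigma_age_test(y, age, sex=None, config: NormativeConfig | None = None,
                   model_full: NormativeModel | None = None) -> AgeEffectResult:
    """Likelihood-ratio test of the log-sigma age smooth (variance trend).

    Same construction as :func:`age_effect_test`, dropping the sigma age
    smooth instead. The sign of the result is the sign of the fitted
    log-sigma change over the age range (negative = variance narrowing
    with age).
    """
    config = config or NormativeConfig()
    if not config.sigma_terms:
        raise ValueError("full model has no sigma age terms; test is not nested")
    full, lr, df = _lr_models(y, age, sex, config, {"sigma_terms": ()})
    p = float(chi2.sf(lr, df))
    grid = np.linspace(full.age_lo, full.age_hi, 50)
    Xsg = _design_sigma(full.basis, grid, config.sigma_terms)
    logsig = Xsg @ full.beta_sigma
    sign = int(np.sign(logsig[-1] - logsig[0]))
    return AgeEffectResult(statistic=lr, df=df, p=p, sign=sign)
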