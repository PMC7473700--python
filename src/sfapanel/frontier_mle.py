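"""Maximum likelihood for the time-invariant normal-truncated-normal panel frontier.

Model
-----
For unit i observed in periods t = 1..T_i,

    y_it = x_it' beta + v_it - u_i,
    v_it ~ N(0, sigma_v^2) iid,
    u_i  ~ N(mu, sigma_u^2) truncated at zero, independent of v.

u_i is the unit's time-invariant technical inefficiency. The marginal
likelihood integrates u_i out per unit and has a closed form: with
precisions a = 1/sigma_u^2, b = 1/sigma_v^2, A_i = T_i b + a and unit
residual sums S1_i = sum_t e_it, S2_i = sum_t e_it^2 (e_it = y - x'beta),

    mu*_i     = (a mu - b S1_i) / A_i      (posterior location of u_i)
    sigma*_i2 = 1 / A_i                    (posterior scale^2)

    ln f_i = -(T_i/2) ln 2pi + (T_i/2) ln b + (1/2) ln a - (1/2) ln A_i
             + ln Phi(mu*_i sqrt(A_i)) - ln Phi(mu sqrt(a))
             + (1/2) [ b (b S1_i^2 - a (2 mu S1_i + T_i mu^2)) / A_i - b S2_i ].

The quadratic term is kept in the cancellation-free form above so the
likelihood stays accurate as gamma -> 0 or 1. All normal CDFs are
evaluated in log space.

Reported parameterization mirrors the conventional frontier output:
sigma_u^2, sigma_v^2, sigma^2 = sigma_u^2 + sigma_v^2,
gamma = sigma_u^2 / sigma^2, ln sigma^2, inverse-logit gamma
(= ln(gamma/(1-gamma))) and mu. Optimization runs unconstrained in
(beta, ln sigma^2, ilgt gamma, mu).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import chi2

from .design_builder import DesignMatrix

_LOG_2PI = math.log(2.0 * math.pi)
#: unconstrained-coordinate box used by the optimizer (loose; keeps the
#: gamma logit and mu from wandering along the weak-identification ridge)
_BOUNDS = {"ln_sigma2": (-40.0, 10.0), "ilgt_gamma": (-30.0, 30.0), "mu": (-50.0, 50.0)}


class LikelihoodDomainError(ValueError):
    """Parameters outside the likelihood's domain (e.g. sigma_v^2 <= 0)."""


class NotConvergedError(RuntimeError):
    """An operation required a converged fit."""


# --------------------------------------------------------------------------
# variance parameterization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceParams:
    """Composed-error variance parameters and their reporting transforms."""

    sigma_u2: float
    sigma_v2: float
    mu: float
    sigma2: float
    gamma: float
    ln_sigma2: float
    ilgt_gamma: float


def param_transforms(sigma_u2: float, sigma_v2: float, mu: float) -> VarianceParams:
    """Fill sigma^2, gamma, ln sigma^2 and inverse-logit gamma consistently.

    gamma exactly 0 or 1 maps to an infinite logit marker (-inf / +inf).
    """
    if not (np.isfinite(sigma_u2) and np.isfinite(sigma_v2) and np.isfinite(mu)):
        raise LikelihoodDomainError("variance parameters must be finite")
    if sigma_v2 <= 0:
        raise LikelihoodDomainError(f"sigma_v2 must be > 0, got {sigma_v2}")
    if sigma_u2 < 0:
        raise LikelihoodDomainError(f"sigma_u2 must be >= 0, got {sigma_u2}")
    sigma2 = sigma_u2 + sigma_v2
    gamma = sigma_u2 / sigma2
    if gamma <= 0.0:
        ilgt = -math.inf
    elif gamma >= 1.0:
        ilgt = math.inf
    else:
        ilgt = math.log(gamma / (1.0 - gamma))
    return VarianceParams(sigma_u2=sigma_u2, sigma_v2=sigma_v2, mu=mu,
                          sigma2=sigma2, gamma=gamma,
                          ln_sigma2=math.log(sigma2), ilgt_gamma=ilgt)


def from_unconstrained(ln_sigma2: float, ilgt_gamma: float, mu: float) -> VarianceParams:
    """Inverse transform; round-trip with :func:`param_transforms` is identity."""
    sigma2 = math.exp(ln_sigma2)
    gamma = 1.0 / (1.0 + math.exp(-ilgt_gamma))
    return param_transforms(gamma * sigma2, (1.0 - gamma) * sigma2, mu)


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _unit_stats(design: DesignMatrix):
    """Group bookkeeping: first-occurrence-ordered unit codes per row."""
    codes, inv = np.unique(design.unit_index, return_inverse=True)
    T = np.bincount(inv).astype(float)
    return codes, inv, T


def _unit_logliks(beta: np.ndarray, variance: VarianceParams,
                  design: DesignMatrix) -> np.ndarray:
    """Per-unit marginal log-likelihood contributions (u_i integrated out)."""
    e = design.response - design.X @ np.asarray(beta, float)
    if not np.all(np.isfinite(e)):
        raise LikelihoodDomainError("non-finite residuals")
    _, inv, T = _unit_stats(design)
    S1 = np.bincount(inv, weights=e)
    S2 = np.bincount(inv, weights=e * e)
    mu = variance.mu

    if variance.sigma_u2 == 0.0:
        # degenerate inefficiency: u_i = max(mu, 0) with certainty
        u0 = max(mu, 0.0)
        b = 1.0 / variance.sigma_v2
        return (-0.5 * T * _LOG_2PI + 0.5 * T * np.log(b)
                - 0.5 * b * (S2 + 2.0 * u0 * S1 + T * u0 * u0))

    a = 1.0 / variance.sigma_u2
    b = 1.0 / variance.sigma_v2
    A = T * b + a
    mu_star = (a * mu - b * S1) / A
    quad = b * (b * S1 * S1 - a * (2.0 * mu * S1 + T * mu * mu)) / A - b * S2
    return (-0.5 * T * _LOG_2PI + 0.5 * T * math.log(b) + 0.5 * math.log(a)
            - 0.5 * np.log(A)
            + log_ndtr(mu_star * np.sqrt(A)) - log_ndtr(mu * math.sqrt(a))
            + 0.5 * quad)


def composed_loglik(beta: np.ndarray, variance: VarianceParams,
                    design: DesignMatrix) -> float:
    """Exact marginal log-likelihood of the composed-error panel model.

    At sigma_u^2 = 0 (gamma = 0) with mu = 0 this is exactly the pooled
    Gaussian log-likelihood of the residuals with variance sigma_v^2.
    """
    return float(_unit_logliks(beta, variance, design).sum())


def _mills_log(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z) computed in log space (stable for very negative z)."""
    z = np.asarray(z, float)
    return np.exp(-0.5 * z * z - 0.5 * _LOG_2PI - log_ndtr(z))


def loglik_gradient(beta: np.ndarray, variance: VarianceParams,
                    design: DesignMatrix) -> tuple[np.ndarray, float, float, float]:
    """Analytic gradient of :func:`composed_loglik`.

    Returns ``(d/dbeta, d/dsigma_u2, d/dsigma_v2, d/dmu)``. Requires
    sigma_u^2 > 0 (the interior of the parameter space).
    """
    if variance.sigma_u2 <= 0:
        raise LikelihoodDomainError("gradient requires sigma_u2 > 0")
    beta = np.asarray(beta, float)
    e = design.response - design.X @ beta
    _, inv, T = _unit_stats(design)
    S1 = np.bincount(inv, weights=e)
    S2 = np.bincount(inv, weights=e * e)
    mu = variance.mu
    a = 1.0 / variance.sigma_u2
    b = 1.0 / variance.sigma_v2
    A = T * b + a
    sqrtA = np.sqrt(A)
    mu_star = (a * mu - b * S1) / A
    D = _mills_log(mu_star * sqrtA)              # Mills ratio at z*
    z0 = mu * math.sqrt(a)
    D0 = float(_mills_log(np.array([z0]))[0])    # Mills ratio at mu/sigma_u

    # common factor dG/dmu* with G = lnPhi(mu* sqrtA) + 0.5 mu*^2 A
    dG_dmustar = D * sqrtA + mu_star * A
    # dG/dA holding mu*
    dG_dA = D * mu_star / (2.0 * sqrtA) + 0.5 * mu_star ** 2

    # beta: per-row weight from mu* channel plus direct residual channel
    c_unit = b * (D / sqrtA + mu_star)           # = dG_dmustar * b / A
    grad_beta = design.X.T @ (c_unit[inv] + b * e)

    # precision a = 1/sigma_u2
    dmustar_da = (mu - mu_star) / A
    dl_da = (0.5 / a - 0.5 / A + dG_dmustar * dmustar_da + dG_dA
             - D0 * mu / (2.0 * math.sqrt(a)) - 0.5 * mu * mu)
    # precision b = 1/sigma_v2
    dmustar_db = -(S1 + mu_star * T) / A
    dl_db = (0.5 * T / b - 0.5 * T / A + dG_dmustar * dmustar_db + dG_dA * T
             - 0.5 * S2)
    # mu
    dl_dmu = dG_dmustar * (a / A) - D0 * math.sqrt(a) - mu * a

    d_sigma_u2 = float(np.sum(dl_da) * (-a * a))
    d_sigma_v2 = float(np.sum(dl_db) * (-b * b))
    d_mu = float(np.sum(dl_dmu))
    return grad_beta, d_sigma_u2, d_sigma_v2, d_mu


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_frontier`."""

    n_starts: int = 5          # 1 deterministic COLS start + jittered restarts
    jitter_scale: float = 0.25
    seed: int = 20240          # jitter seed (fixed so fits are reproducible)
    maxiter: int = 2000
    gtol: float = 1e-9
    fix_mu: float | None = None   # pin mu (0.0 gives the half-normal variant)


@dataclass
class FrontierFit:
    """A fitted stochastic frontier: coefficients, variances, inference."""

    spec: object
    beta: pd.Series
    variance: VarianceParams
    loglik: float
    wald_chi2: float
    wald_df: int
    wald_p: float
    covariance: pd.DataFrame          # over free params (beta, ln s2, ilgt g, mu)
    se: pd.Series                     # incl. delta-method sigma_u2/sigma_v2/...
    converged: bool
    n_obs: int
    n_units: int
    design: DesignMatrix = field(repr=False, default=None)
    trace: list = field(default_factory=list, repr=False)
    gamma_pinned: bool = False

    def summary(self) -> str:
        """Conventional frontier-output text table."""
        lines = [f"Stochastic frontier ML fit: {self.spec.form} "
                 f"(n = {self.n_obs}, units = {self.n_units})",
                 f"{'parameter':<24}{'estimate':>12}{'std. err.':>12}"]
        for name, val in self.beta.items():
            se = self.se.get(name, float("nan"))
            lines.append(f"{name:<24}{val:>12.4f}{se:>12.4f}")
        v = self.variance
        for name, val in [("sigma_u2", v.sigma_u2), ("sigma_v2", v.sigma_v2),
                          ("sigma2", v.sigma2), ("ln_sigma2", v.ln_sigma2),
                          ("gamma", v.gamma), ("ilgt_gamma", v.ilgt_gamma),
                          ("mu", v.mu)]:
            se = self.se.get(name, float("nan"))
            lines.append(f"{name:<24}{val:>12.4f}{se:>12.4f}")
        lines.append(f"Wald chi2({self.wald_df}) = {self.wald_chi2:.2f} "
                     f"(p = {self.wald_p:.3g})")
        lines.append(f"Log likelihood = {self.loglik:.3f}")
        lines.append(f"Converged: {self.converged}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        v = self.variance
        return {
            "form": self.spec.form,
            "beta": {k: float(x) for k, x in self.beta.items()},
            "variance": {"sigma_u2": v.sigma_u2, "sigma_v2": v.sigma_v2,
                         "sigma2": v.sigma2, "gamma": v.gamma, "mu": v.mu,
                         "ln_sigma2": v.ln_sigma2, "ilgt_gamma": v.ilgt_gamma},
            "loglik": self.loglik,
            "wald_chi2": self.wald_chi2, "wald_df": self.wald_df,
            "wald_p": self.wald_p,
            "se": {k: float(x) for k, x in self.se.items()},
            "converged": self.converged,
            "n_obs": self.n_obs, "n_units": self.n_units,
            "gamma_pinned": self.gamma_pinned,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _pack_objective(design: DesignMatrix):
    """Negative log-likelihood and gradient in unconstrained coordinates."""
    p = design.X.shape[1]

    def unpack(theta):
        beta = theta[:p]
        return beta, from_unconstrained(theta[p], theta[p + 1], theta[p + 2])

    def negll(theta):
        try:
            beta, var = unpack(theta)
            return -composed_loglik(beta, var, design)
        except (LikelihoodDomainError, OverflowError):
            return 1e30

    def neggrad(theta):
        try:
            beta, var = unpack(theta)
            gb, gu2, gv2, gmu = loglik_gradient(beta, var, design)
        except (LikelihoodDomainError, OverflowError):
            return np.zeros_like(theta)
        g = np.empty_like(theta)
        g[:p] = gb
        s2, gam = var.sigma2, var.gamma
        # chain rule to (ln sigma2, ilgt gamma)
        g[p] = var.sigma_u2 * gu2 + var.sigma_v2 * gv2
        g[p + 1] = s2 * gam * (1.0 - gam) * (gu2 - gv2)
        g[p + 2] = gmu
        return -g

    return negll, neggrad, unpack, p


def _numerical_hessian(f, x, step=1e-4):
    """Central-difference Hessian with relative steps."""
    n = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            xi, xj = h[i], h[j]
            if i == j:
                f0 = f(x)
                xp = x.copy(); xp[i] += xi
                xm = x.copy(); xm[i] -= xi
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / xi**2
            else:
                xpp = x.copy(); xpp[i] += xi; xpp[j] += xj
                xpm = x.copy(); xpm[i] += xi; xpm[j] -= xj
                xmp = x.copy(); xmp[i] -= xi; xmp[j] += xj
                xmm = x.copy(); xmm[i] -= xi; xmm[j] -= xj
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * xi * xj)
    return H


def fit_frontier(design: DesignMatrix, options: FitOptions | None = None) -> FrontierFit:
    """Fit the panel frontier by maximum likelihood.

    Starting values are corrected-OLS style: OLS slopes, sigma^2 from the
    OLS residual variance, gamma = 0.5, mu = 0; quasi-Newton (L-BFGS-B
    with analytic gradient) from the deterministic start plus jittered
    restarts, keeping the best finite optimum. Standard errors come from
    the inverse observed information (numerical Hessian at the optimum in
    unconstrained coordinates) with the delta method for the derived
    variance quantities. Non-convergence is reported, never silent.
    """
    from scipy.optimize import minimize

    opts = options or FitOptions()
    codes, _, _ = _unit_stats(design)
    if len(codes) < 2:
        raise ValueError("need at least 2 units to separate noise from inefficiency")

    X, y = design.X, design.response
    p = X.shape[1]
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2_ols = float(resid @ resid) / max(len(y) - p, 1)

    if s2_ols < 1e-16:
        # noise-free data: the frontier is an exact linear solve
        var = param_transforms(0.0, 1e-16, 0.0)
        beta_s = pd.Series(beta_ols, index=design.columns)
        ll = composed_loglik(beta_ols, var, design)
        zero = pd.Series(0.0, index=list(design.columns)
                         + ["sigma_u2", "sigma_v2", "sigma2", "gamma", "mu",
                            "ln_sigma2", "ilgt_gamma"])
        cov = pd.DataFrame(np.zeros((p, p)), index=design.columns,
                           columns=design.columns)
        return FrontierFit(spec=design.spec, beta=beta_s, variance=var,
                           loglik=ll, wald_chi2=math.inf, wald_df=p - 1,
                           wald_p=0.0, covariance=cov, se=zero, converged=True,
                           n_obs=len(y), n_units=len(codes), design=design,
                           trace=[{"note": "degenerate perfect fit (zero residual variance)"}])

    # Optimize in a QR-orthonormalized regressor basis: X = Q R, alpha = R beta.
    # Translog/distance designs are severely collinear; the likelihood in
    # alpha-space is well conditioned while X beta = Q alpha is unchanged.
    # Estimates and covariance are mapped back through R^{-1} afterwards.
    from dataclasses import replace as _dc_replace
    Q, R = np.linalg.qr(X)
    design_q = _dc_replace(design, X=Q)
    negll, neggrad, unpack, _ = _pack_objective(design_q)
    alpha_ols = R @ beta_ols
    mu0 = opts.fix_mu if opts.fix_mu is not None else 0.0
    mu_bounds = ((opts.fix_mu, opts.fix_mu) if opts.fix_mu is not None
                 else _BOUNDS["mu"])
    theta0 = np.concatenate([alpha_ols, [math.log(s2_ols), 0.0, mu0]])
    bounds = ([(None, None)] * p
              + [_BOUNDS["ln_sigma2"], _BOUNDS["ilgt_gamma"], mu_bounds])

    rng = np.random.default_rng(opts.seed)
    trace: list[dict] = []
    best = None
    for k in range(max(opts.n_starts, 1)):
        start = theta0.copy()
        if k > 0:
            start[:p] += rng.normal(0.0, opts.jitter_scale * 0.1, p) * (1 + np.abs(start[:p]))
            start[p:] += rng.normal(0.0, opts.jitter_scale, 3)
            start[p:] = np.clip(start[p:], [b[0] for b in bounds[p:]],
                                [b[1] for b in bounds[p:]])
        res = minimize(negll, start, jac=neggrad, method="L-BFGS-B",
                       bounds=bounds,
                       options={"maxiter": opts.maxiter, "ftol": 1e-12,
                                "gtol": opts.gtol})
        trace.append({"start": k, "success": bool(res.success),
                      "loglik": float(-res.fun), "nit": int(res.nit),
                      "message": str(res.message)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res

    if best is None:
        raise RuntimeError("all optimizer starts returned non-finite likelihood")

    theta = best.x
    alpha_hat, var = unpack(theta)
    beta_hat = np.linalg.solve(R, alpha_hat)
    ll = float(-best.fun)
    converged = bool(best.success and np.isfinite(ll))
    gamma_pinned = bool(theta[p + 1] <= _BOUNDS["ilgt_gamma"][0] + 1e-6
                        or theta[p + 1] >= _BOUNDS["ilgt_gamma"][1] - 1e-6)
    if gamma_pinned:
        trace.append({"warning": "gamma pinned at parameter-space boundary"})

    # observed information (alpha space), mapped back to beta space
    H = _numerical_hessian(negll, theta)
    try:
        cov_alpha = np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        cov_alpha = np.full((len(theta), len(theta)), np.nan)
        converged = False
    J_full = np.eye(len(theta))
    J_full[:p, :p] = np.linalg.inv(R)
    cov = J_full @ cov_alpha @ J_full.T
    # clip tiny negative diagonal noise
    dvar = np.diag(cov).copy()
    dvar[(dvar < 0) & (dvar > -1e-10)] = 0.0
    se_free = np.sqrt(np.where(dvar >= 0, dvar, np.nan))

    names = list(design.columns) + ["ln_sigma2", "ilgt_gamma", "mu"]
    cov_df = pd.DataFrame(cov, index=names, columns=names)

    # delta method for derived variance quantities
    s2, gam = var.sigma2, var.gamma
    sub = cov[p:p + 2, p:p + 2]
    J = np.array([
        [gam * s2, s2 * gam * (1 - gam)],          # sigma_u2
        [(1 - gam) * s2, -s2 * gam * (1 - gam)],   # sigma_v2
        [s2, 0.0],                                 # sigma2
        [0.0, gam * (1 - gam)],                    # gamma
    ])
    dvars = np.einsum("ij,jk,ik->i", J, sub, J)
    dvars[(dvars < 0) & (dvars > -1e-12)] = 0.0
    se_derived = np.sqrt(np.where(dvars >= 0, dvars, np.nan))
    se = pd.Series(
        list(se_free[:p]) + [se_free[p], se_free[p + 1], se_free[p + 2]]
        + list(se_derived),
        index=names + ["sigma_u2", "sigma_v2", "sigma2", "gamma"],
    )

    # Wald joint test of all slope coefficients (constant excluded)
    Vbb = cov[1:p, 1:p]
    b = beta_hat[1:]
    try:
        wald = float(b @ np.linalg.solve(Vbb, b))
    except np.linalg.LinAlgError:
        wald = float(b @ np.linalg.pinv(Vbb) @ b)
    wald_df = p - 1
    wald_p = float(chi2.sf(wald, wald_df))

    return FrontierFit(
        spec=design.spec,
        beta=pd.Series(beta_hat, index=design.columns),
        variance=var,
        loglik=ll,
        wald_chi2=wald,
        wald_df=wald_df,
        wald_p=wald_p,
        covariance=cov_df,
        se=se,
        converged=converged,
        n_obs=len(y),
        n_units=len(codes),
        design=design,
        trace=trace,
        gamma_pinned=gamma_pinned,
    )
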