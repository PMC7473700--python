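"""Shared fixtures and independent numerical oracles.

The quadrature oracles integrate the composed-error densities directly
with adaptive quadrature (peak-aware, in log space) and are deliberately
independent of the closed forms they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

import sfapanel as sp


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def _log_joint(u: float, e: np.ndarray, sigma_u: float, sigma_v: float,
               mu: float) -> float:
    """log of prod_t N(e_t + u; 0, sv^2) * N+(u; mu, su^2) for u >= 0."""
    return (float(np.sum(norm.logpdf(e + u, 0.0, sigma_v)))
            + norm.logpdf(u, mu, sigma_u)
            - norm.logcdf(mu / sigma_u))


def quad_unit_loglik(e, sigma_u2: float, sigma_v2: float, mu: float) -> float:
    """Adaptive-quadrature unit log-likelihood (u integrated over [0, inf))."""
    e = np.asarray(e, float)
    su, sv = np.sqrt(sigma_u2), np.sqrt(sigma_v2)
    hi = max(abs(mu) + 10 * su + 10 * sv, 1.0)
    us = np.linspace(0.0, hi, 4001)
    lg = np.array([_log_joint(u, e, su, sv, mu) for u in us])
    m = float(lg.max())
    peak = float(us[lg.argmax()])
    f = lambda u: np.exp(_log_joint(u, e, su, sv, mu) - m)
    v1, _ = integrate.quad(f, 0.0, hi, points=[max(peak, 1e-9)], limit=400)
    v2, _ = integrate.quad(f, hi, np.inf)
    return float(np.log(v1 + v2) + m)


def quad_unit_te(e, sigma_u2: float, sigma_v2: float, mu: float) -> float:
    """Quadrature E[exp(-u) | e] under the truncated-normal posterior."""
    e = np.asarray(e, float)
    su, sv = np.sqrt(sigma_u2), np.sqrt(sigma_v2)
    hi = max(abs(mu) + 10 * su + 10 * sv, 1.0)
    us = np.linspace(0.0, hi, 4001)
    lg = np.array([_log_joint(u, e, su, sv, mu) for u in us])
    m = float(lg.max())
    peak = float(us[lg.argmax()])

    def denom_f(u):
        return np.exp(_log_joint(u, e, su, sv, mu) - m)

    def numer_f(u):
        return np.exp(_log_joint(u, e, su, sv, mu) - m - u)

    d1, _ = integrate.quad(denom_f, 0.0, hi, points=[max(peak, 1e-9)], limit=400)
    d2, _ = integrate.quad(denom_f, hi, np.inf)
    n1, _ = integrate.quad(numer_f, 0.0, hi, points=[max(peak, 1e-9)], limit=400)
    n2, _ = integrate.quad(numer_f, hi, np.inf)
    return float((n1 + n2) / (d1 + d2))


def single_unit_design(e: np.ndarray, label: str = "u1") -> sp.DesignMatrix:
    """A constant-only design whose residuals at beta=0 equal ``e``."""
    e = np.asarray(e, float)
    return sp.DesignMatrix(
        response=e,
        X=np.ones((len(e), 1)),
        columns=["const"],
        unit_index=np.array([label] * len(e)),
        term_catalog={"const": ("constant", ())},
        spec=sp.FrontierSpec(form="cobb_douglas", inputs=("x",)),
    )


#: the (gamma, mu, T) grid shared by the likelihood and efficiency checks
PARAM_GRID = [(g, m, T)
              for g in (0.05, 0.5, 0.95)
              for m in (-0.1, 0.0, 0.1)
              for T in (1, 3, 6)]
SIGMA2 = 0.05   # total composed-error variance used on the grid


def grid_residuals(T: int, seed: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(0.0, 0.2, size=T)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study_panel():
    panel, truth = sp.simulate_panel(sp.study_emulation_config())
    return panel, truth


@pytest.fixture(scope="session")
def benchmark_fit():
    """One benchmark-scale Cobb-Douglas fit, shared across tests."""
    cfg = sp.benchmark_config(n_units=200, n_years=6, seed=1)
    panel, truth = sp.simulate_panel(cfg)
    design = sp.build_design(panel, sp.FrontierSpec(form="cobb_douglas"))
    fit = sp.fit_frontier(design)
    return panel, truth, design, fit
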