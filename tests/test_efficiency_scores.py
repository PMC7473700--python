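"""Battese-Coelli scoring against quadrature, limits and summaries."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import sfapanel as sp
from sfapanel.frontier_mle import NotConvergedError
from conftest import (PARAM_GRID, SIGMA2, grid_residuals, quad_unit_te,
                      single_unit_design)


def _fit_for(design, sigma_u2, sigma_v2, mu, beta=None):
    """Assemble a FrontierFit with fixed parameters (no optimization)."""
    beta = np.zeros(design.X.shape[1]) if beta is None else np.asarray(beta)
    var = sp.param_transforms(sigma_u2, sigma_v2, mu)
    return sp.FrontierFit(
        spec=design.spec, beta=pd.Series(beta, index=design.columns),
        variance=var, loglik=0.0, wald_chi2=0.0, wald_df=1, wald_p=1.0,
        covariance=pd.DataFrame(), se=pd.Series(dtype=float), converged=True,
        n_obs=design.n_obs, n_units=len(set(design.unit_index)), design=design)


@pytest.mark.parametrize("gamma,mu,T", PARAM_GRID)
def test_scores_match_quadrature_oracle(gamma, mu, T):
    """E[exp(-u)|e] closed form equals posterior quadrature to 1e-6."""
    e = grid_residuals(T, seed=7000 + int(100 * gamma) + 10 * T + int(10 * (mu + 1)))
    d = single_unit_design(e)
    su2, sv2 = gamma * SIGMA2, (1 - gamma) * SIGMA2
    fit = _fit_for(d, su2, sv2, mu)
    score = sp.unit_efficiency(fit).iloc[0]
    oracle = quad_unit_te(e, su2, sv2, mu)
    assert 0.0 < score <= 1.0
    assert score == pytest.approx(oracle, abs=1e-6)


def test_three_unit_toy_panel_scores_vs_quadrature():
    rng = np.random.default_rng(11)
    X = np.ones((9, 1))
    e = rng.normal(0, 0.25, 9)
    units = np.repeat(["a", "b", "c"], 3)
    spec = sp.FrontierSpec(form="cobb_douglas", inputs=("x",))
    d = sp.DesignMatrix(e, X * 0.0, ["const"], units,
                        {"const": ("constant", ())}, spec)
    fit = _fit_for(d, 0.03, 0.015, 0.02)
    scores = sp.unit_efficiency(fit)
    for i, u in enumerate(["a", "b", "c"]):
        oracle = quad_unit_te(e[3 * i:3 * i + 3], 0.03, 0.015, 0.02)
        assert scores[u] == pytest.approx(oracle, abs=1e-6)


def test_vanishing_inefficiency_variance_drives_scores_to_one():
    e = grid_residuals(4, seed=1)
    d = single_unit_design(e)
    for su2 in (1e-6, 1e-10):
        fit = _fit_for(d, su2, SIGMA2, 0.0)
        assert sp.unit_efficiency(fit).iloc[0] == pytest.approx(1.0, abs=2e-3)
    fit0 = _fit_for(d, 0.0, SIGMA2, 0.0)
    assert sp.unit_efficiency(fit0).iloc[0] == 1.0


def test_identical_residual_vectors_get_identical_scores():
    e = np.array([0.1, -0.05, 0.02])
    units = np.repeat(["a", "b"], 3)
    spec = sp.FrontierSpec(form="cobb_douglas", inputs=("x",))
    d = sp.DesignMatrix(np.tile(e, 2), np.zeros((6, 1)), ["const"], units,
                        {"const": ("constant", ())}, spec)
    fit = _fit_for(d, 0.02, 0.01, 0.05)
    scores = sp.unit_efficiency(fit)
    assert scores["a"] == scores["b"]


def test_score_monotone_in_residual_sum():
    """A unit sitting higher relative to the frontier scores at least as
    efficient, at fixed variance parameters."""
    spec = sp.FrontierSpec(form="cobb_douglas", inputs=("x",))
    base = np.array([-0.1, 0.0, 0.1])
    shifts = [-0.3, -0.1, 0.0, 0.2, 0.5]
    units = np.repeat([f"u{i}" for i in range(len(shifts))], 3)
    resp = np.concatenate([base + s for s in shifts])
    d = sp.DesignMatrix(resp, np.zeros((len(resp), 1)), ["const"], units,
                        {"const": ("constant", ())}, spec)
    for gamma, mu in [(0.05, 0.0), (0.5, 0.1), (0.95, -0.1)]:
        fit = _fit_for(d, gamma * SIGMA2, (1 - gamma) * SIGMA2, mu)
        scores = sp.unit_efficiency(fit)
        ordered = [scores[f"u{i}"] for i in range(len(shifts))]
        assert all(a <= b + 1e-12 for a, b in zip(ordered, ordered[1:]))


def test_bc_efficiency_refuses_non_converged_fit(benchmark_fit):
    _, _, design, fit = benchmark_fit
    bad = dataclasses.replace(fit, converged=False)
    with pytest.raises(NotConvergedError):
        sp.bc_efficiency(bad)


def test_time_invariant_scores_broadcast_across_unit_years(benchmark_fit):
    _, _, _, fit = benchmark_fit
    table = sp.bc_efficiency(fit)
    per_unit = table.frame.groupby("hospital_id")["score"].nunique()
    assert (per_unit == 1).all()
    assert len(table.frame) == fit.n_obs


def test_estimated_mean_te_tracks_true_mean(benchmark_fit):
    _, truth, _, fit = benchmark_fit
    table = sp.bc_efficiency(fit)
    summ = sp.summarize_efficiency(table)
    true_mean = float(truth.te.loc[table.frame["hospital_id"]].mean())
    assert summ.mean == pytest.approx(true_mean, abs=0.05)


def test_summary_degenerate_when_all_scores_equal():
    frame = pd.DataFrame({"hospital_id": ["a", "b"], "year": [2001, 2001],
                          "score": [0.8, 0.8], "form": "cobb_douglas"})
    table = sp.EfficiencyTable(frame=frame,
                               unit_scores=pd.Series([0.8, 0.8], index=["a", "b"]),
                               form="cobb_douglas")
    summ = sp.summarize_efficiency(table)
    assert summ.mean == 0.8 and summ.sd == 0.0 and summ.ci == (0.8, 0.8)


def test_summary_window_weighted_average_identity(benchmark_fit):
    _, _, _, fit = benchmark_fit
    table = sp.bc_efficiency(fit)
    years = sorted(table.frame["year"].unique())
    split = years[len(years) // 2]
    s1 = sp.summarize_efficiency(table, window=(years[0], split - 1))
    s2 = sp.summarize_efficiency(table, window=(split, years[-1]))
    full = sp.summarize_efficiency(table)
    weighted = (s1.mean * s1.n + s2.mean * s2.n) / (s1.n + s2.n)
    assert full.mean == pytest.approx(weighted, rel=1e-12)


def test_empty_window_is_error(benchmark_fit):
    _, _, _, fit = benchmark_fit
    table = sp.bc_efficiency(fit)
    with pytest.raises(ValueError):
        sp.summarize_efficiency(table, window=(1800, 1801))
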