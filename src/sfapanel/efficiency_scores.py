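"""Battese-Coelli technical-efficiency scores and period summaries.

Under the time-invariant model the posterior of u_i given the unit's
residual vector e_i is N(mu*_i, sigma*_i^2) truncated at zero, with
mu*_i and sigma*_i^2 as in :mod:`sfapanel.frontier_mle`. The point score

    TE_i = E[exp(-u_i) | e_i]
         = exp(-mu*_i + sigma*_i^2 / 2) *
           Phi(mu*_i/sigma*_i - sigma*_i) / Phi(mu*_i/sigma*_i)

lies in (0, 1]. Scores are computed once per unit and broadcast to that
unit's years for reporting (the model itself is time-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import t as t_dist

from .design_builder import DesignMatrix
from .frontier_mle import FrontierFit, NotConvergedError, _unit_stats

#: numerical clipping tolerance: scores above 1 by less than this are set
#: to 1; anything larger signals an internal inconsistency
CLIP_TOL = 1e-12


class EfficiencyError(RuntimeError):
    """Internal-consistency failure in efficiency scoring."""


@dataclass
class EfficiencyTable:
    """Per unit-year technical-efficiency scores for one fitted spec."""

    frame: pd.DataFrame        # columns: hospital_id, year, score, form
    unit_scores: pd.Series     # one score per unit
    form: str

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class EfficiencySummary:
    """Mean/sd/CI of scores over a period window."""

    mean: float
    sd: float
    ci: tuple[float, float]
    n: int
    period: str
    ci_level: float

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "ci_low": self.ci[0],
                "ci_high": self.ci[1], "n": self.n, "period": self.period,
                "ci_level": self.ci_level}


def unit_efficiency(fit: FrontierFit, design: DesignMatrix | None = None) -> pd.Series:
    """One Battese-Coelli score per unit, indexed by unit label."""
    design = design if design is not None else fit.design
    v = fit.variance
    codes, inv, T = _unit_stats(design)
    e = design.response - design.X @ fit.beta.to_numpy()
    S1 = np.bincount(inv, weights=e)

    if v.sigma_u2 == 0.0:
        u0 = max(v.mu, 0.0)
        scores = np.full(len(codes), np.exp(-u0))
    else:
        a = 1.0 / v.sigma_u2
        b = 1.0 / v.sigma_v2
        A = T * b + a
        mu_star = (a * v.mu - b * S1) / A
        sig_star = 1.0 / np.sqrt(A)
        z = mu_star / sig_star
        ln_te = (-mu_star + 0.5 * sig_star**2
                 + log_ndtr(z - sig_star) - log_ndtr(z))
        scores = np.exp(ln_te)
    if np.any(scores > 1.0 + CLIP_TOL) or np.any(scores <= 0.0):
        raise EfficiencyError(
            f"scores outside (0, 1] beyond tolerance: "
            f"min={scores.min():.6g}, max={scores.max():.6g}")
    scores = np.minimum(scores, 1.0)
    return pd.Series(scores, index=codes, name="score")


def bc_efficiency(fit: FrontierFit, design: DesignMatrix | None = None) -> EfficiencyTable:
    """Battese-Coelli efficiency table, broadcast to unit-years.

    Refuses a non-converged fit: scores from a failed optimization are
    not interpretable.
    """
    if not fit.converged:
        raise NotConvergedError(
            "fit did not converge; efficiency scores would be meaningless "
            f"(trace: {fit.trace[-1] if fit.trace else 'empty'})")
    design = design if design is not None else fit.design
    per_unit = unit_efficiency(fit, design)

    units = design.unit_index
    years = _years_for(design)
    frame = pd.DataFrame({
        "hospital_id": units,
        "year": years,
        "score": per_unit.loc[units].to_numpy(),
        "form": fit.spec.form,
    })
    return EfficiencyTable(frame=frame, unit_scores=per_unit, form=fit.spec.form)


def _years_for(design: DesignMatrix) -> np.ndarray:
    if design.years is not None:
        return design.years
    # designs assembled by hand may lack years; use a per-unit counter
    counter: dict[str, int] = {}
    out = np.empty(design.n_obs, dtype=int)
    for i, u in enumerate(design.unit_index):
        counter[u] = counter.get(u, -1) + 1
        out[i] = counter[u]
    return out


def summarize_efficiency(table: EfficiencyTable,
                         window: tuple[int, int] | None = None,
                         ci_level: float = 0.95) -> EfficiencySummary:
    """Mean, sd and a t-interval over unit-year scores in a year window."""
    df = table.frame
    if window is not None:
        lo, hi = window
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        period = f"{lo}-{hi}"
    else:
        period = f"{int(df['year'].min())}-{int(df['year'].max())}"
    if len(df) == 0:
        raise ValueError(f"no scores in window {window}")
    s = df["score"].to_numpy()
    mean = float(s.mean())
    n = len(s)
    if n == 1 or np.allclose(s, s[0]):
        sd = 0.0 if n > 1 else float("nan")
        ci = (mean, mean)
    else:
        sd = float(s.std(ddof=1))
        half = t_dist.ppf(0.5 + ci_level / 2.0, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    return EfficiencySummary(mean=mean, sd=sd, ci=ci, n=n, period=period,
                             ci_level=ci_level)
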