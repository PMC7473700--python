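"""Functional-form selection and paired comparison of efficiency series.

The likelihood-ratio test compares nested frontiers (Cobb-Douglas inside
translog: the null restricts the 6 interaction and 4 half-square
coefficients to zero, df = 10) against a chi-square reference. The
boundary-parameter mixed chi-square refinement applies only when gamma
itself is on trial, which is not the comparison made here.

The paired t-test compares technical-efficiency series between two
specifications, matched by unit-year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design_builder import FrontierSpec

#: slack for a likelihood ratio that is negative only through optimizer noise
LR_TOL = 1e-6


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "method": self.method}
        if self.ci is not None:
            d["ci_low"], d["ci_high"] = self.ci
        return d

    def one_line(self) -> str:
        s = f"{self.method}: stat = {self.statistic:.4g}, df = {self.df}, p = {self.p_value:.3g}"
        if self.ci is not None:
            s += f", 95% CI [{self.ci[0]:.4g}, {self.ci[1]:.4g}]"
        return s


def lr_df(restricted: FrontierSpec, full: FrontierSpec) -> int:
    """Degrees of freedom for nested frontier specs (slope-count difference)."""
    d = full.n_slopes - restricted.n_slopes
    if d < 1:
        raise ValueError("specs are not nested in the stated order")
    return d


def lr_test(loglik_restricted: float, loglik_full: float, df: int) -> TestResult:
    """Likelihood-ratio test: 2*(lnL_full - lnL_restricted) ~ chi2(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (loglik_full - loglik_restricted)
    if stat < -LR_TOL:
        raise ValueError(
            f"negative LR statistic ({stat:.3g}): models not nested or the "
            "full-model optimization failed to reach its optimum")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(statistic=float(stat), df=df, p_value=p,
                      method=f"LR test, chi2({df})")


def paired_t(scores_a, scores_b, ci_level: float = 0.95) -> TestResult:
    """Paired t-test on matched score series.

    Reports t, two-sided p and a CI on the mean difference b - a (so a
    positive difference means series b scores higher). Swapping the two
    series negates t and reflects the CI.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape:
        raise ValueError(f"pairing error: lengths {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 matched pairs")
    d = b - a
    n = len(d)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        if mean_d == 0.0:
            return TestResult(statistic=0.0, df=n - 1, p_value=1.0,
                              method="paired t-test", ci=(0.0, 0.0))
        raise ValueError("degenerate case: constant nonzero differences")
    t_stat = mean_d / (sd_d / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t_stat), n - 1))
    half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd_d / np.sqrt(n)
    return TestResult(statistic=float(t_stat), df=n - 1, p_value=p,
                      method="paired t-test", ci=(mean_d - half, mean_d + half))
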