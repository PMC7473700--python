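"""Synthetic hospital panels with known frontier and inefficiency truth.

The generator emulates the study design this pipeline targets: five
regional hospitals observed yearly over a disaggregated window
(2001-2006), then a single combined pseudo-unit ("ALL") over 2007-2017
where only aggregate figures exist — 41 hospital-year records in the
default layout. Inputs are drawn log-uniformly within per-input level
ranges; the default ranges and the composed-error scale are calibrated
to the magnitudes of the study's descriptive table (combined scale for
all units, mirroring how its 41 observations were evidently pooled —
the resulting scale mix is flagged in the ground truth's metadata).

Data-generating process (production frontier in logs):

    ln y_it = f(ln x_it; beta_true) + v_it - u_i,
    u_i ~ N(mu, sigma_u^2) truncated at zero (one draw per unit),
    v_it ~ N(0, sigma_v^2) iid,

with true unit efficiency TE_i = exp(-u_i). Total output y is split into
outpatients/inpatients by a fixed outpatient share (optionally jittered)
so the output-mix ratio Y* of the multi-output form is well defined.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .panel_data import INPUT_VARS, HospitalPanel

#: input level ranges at combined (all-hospitals) scale, from the study's
#: descriptive table min/max
_STUDY_RANGES: dict[str, tuple[float, float]] = {
    "beds": (2603.0, 3699.0),
    "doctors": (808.0, 1514.0),
    "nurses": (3051.0, 4016.0),
    "nonmedical": (2560.0, 3699.0),
}

#: Cobb-Douglas slope truth (the study's reported point estimates); the
#: intercept is calibrated so mean inputs map to the observed mean total
#: output net of mean inefficiency (see docs/methods.md)
_STUDY_BETA: dict[str, float] = {
    "const": 5.13,
    "ln_beds": 0.232,
    "ln_doctors": 0.618,
    "ln_nurses": 0.165,
    "ln_nonmedical": 0.228,
}

#: wide-range benchmark levels (roughly a decade per input) used for the
#: parameter-recovery and test-calibration harnesses, where the translog
#: second-order columns must be numerically identifiable
_BENCHMARK_RANGES: dict[str, tuple[float, float]] = {
    "beds": (80.0, 800.0),
    "doctors": (25.0, 250.0),
    "nurses": (80.0, 800.0),
    "nonmedical": (80.0, 800.0),
}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic panel generator."""

    n_hospitals: int = 5
    disaggregated_window: tuple[int, int] = (2001, 2006)
    combined_window: tuple[int, int] | None = (2007, 2017)
    form: str = "cobb_douglas"
    true_beta: dict = field(default_factory=lambda: dict(_STUDY_BETA))
    sigma_u: float = math.sqrt(0.018)
    sigma_v: float = math.sqrt(0.004)
    mu: float = 0.045
    input_level_ranges: dict = field(default_factory=lambda: dict(_STUDY_RANGES))
    outpatient_share: float = 0.886
    stochastic_split: bool = False
    split_jitter_sd: float = 0.10     # on the logit of the share
    integerize: bool = True           # round counts to integers >= 1
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.outpatient_share < 1.0):
            raise GeneratorError("outpatient_share must lie in (0, 1)")
        if self.sigma_u < 0 or self.sigma_v < 0:
            raise GeneratorError("sigma_u and sigma_v must be >= 0")
        for name, (lo, hi) in self.input_level_ranges.items():
            if lo <= 0 or hi < lo:
                raise GeneratorError(f"bad range for {name}: ({lo}, {hi})")
        if self.combined_window is not None:
            d_hi = self.disaggregated_window[1]
            if self.combined_window[0] <= d_hi:
                raise GeneratorError("windows must be disjoint and ordered")


@dataclass
class GroundTruth:
    """What the generator knows and the estimator must recover."""

    true_beta: dict
    u: pd.Series                 # per-unit inefficiency draws (>= 0)
    te: pd.Series                # per-unit true efficiency exp(-u)
    v: np.ndarray                # per-record noise draws
    config: GeneratorConfig
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_beta": self.true_beta,
            "u": {k: float(x) for k, x in self.u.items()},
            "te": {k: float(x) for k, x in self.te.items()},
            "v": [float(x) for x in self.v],
            "config": _config_dict(self.config),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _config_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["disaggregated_window"] = list(config.disaggregated_window)
    if config.combined_window is not None:
        d["combined_window"] = list(config.combined_window)
    return d


def study_emulation_config() -> GeneratorConfig:
    """The packaged study-design emulation (41 records, seed 1).

    Pure function: every call returns an identical config.
    """
    return GeneratorConfig()


def benchmark_config(n_units: int = 200, n_years: int = 6, seed: int = 1,
                     form: str = "cobb_douglas") -> GeneratorConfig:
    """Generator settings for estimator benchmarking at chosen power.

    ``n_units`` hospitals x ``n_years`` years, no combined pseudo-unit,
    input levels spanning roughly a decade so second-order frontier
    terms are identifiable; error-scale truth as in the study defaults.
    """
    return GeneratorConfig(
        n_hospitals=n_units,
        disaggregated_window=(2001, 2000 + n_years),
        combined_window=None,
        form=form,
        input_level_ranges=dict(_BENCHMARK_RANGES),
        seed=seed,
    )


def _frontier_value(ln_x: dict[str, np.ndarray], beta: dict, form: str,
                    inputs: tuple[str, ...]) -> np.ndarray:
    """Evaluate the chosen frontier form at given ln-input levels."""
    out = np.full_like(next(iter(ln_x.values())), float(beta.get("const", 0.0)))
    for a in inputs:
        out = out + beta.get(f"ln_{a}", 0.0) * ln_x[a]
    if form == "translog":
        names = list(inputs)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                out = out + beta.get(f"ln_{a}:ln_{b}", 0.0) * ln_x[a] * ln_x[b]
            out = out + beta.get(f"half_ln_{a}_sq", 0.0) * 0.5 * ln_x[a] ** 2
    elif form != "cobb_douglas":
        raise GeneratorError(
            f"generation supports cobb_douglas and translog truths, not {form!r}"
            " (a multi-output truth would make the output mix endogenous)")
    return out


def expected_te(mu: float, sigma_u: float) -> float:
    """Closed-form E[exp(-u)] for u ~ N(mu, sigma_u^2) truncated at zero."""
    if sigma_u == 0.0:
        return math.exp(-max(mu, 0.0))
    z = mu / sigma_u
    return math.exp(-mu + 0.5 * sigma_u**2) * norm.cdf(z - sigma_u) / norm.cdf(z)


def simulate_panel(config: GeneratorConfig | None = None
                   ) -> tuple[HospitalPanel, GroundTruth]:
    """Draw a synthetic hospital panel with known ground truth.

    Identical config (including seed) gives a bit-identical panel.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    units: list[str] = []
    years: list[int] = []
    d_lo, d_hi = cfg.disaggregated_window
    unit_names = [f"H{i + 1}" for i in range(cfg.n_hospitals)]
    for u in unit_names:
        for yr in range(d_lo, d_hi + 1):
            units.append(u)
            years.append(yr)
    if cfg.combined_window is not None:
        c_lo, c_hi = cfg.combined_window
        for yr in range(c_lo, c_hi + 1):
            units.append("ALL")
            years.append(yr)
    n = len(units)
    distinct = unit_names + (["ALL"] if cfg.combined_window is not None else [])

    # inputs: log-uniform within level ranges (positivity guaranteed)
    ln_x: dict[str, np.ndarray] = {}
    for name in INPUT_VARS:
        lo, hi = cfg.input_level_ranges[name]
        draw = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
        if cfg.integerize:
            draw = np.maximum(np.rint(draw), 1.0)
        ln_x[name] = np.log(draw)

    # one inefficiency draw per unit, noise per record
    if cfg.sigma_u == 0.0:
        u_draws = np.zeros(len(distinct))
    else:
        a0 = (0.0 - cfg.mu) / cfg.sigma_u
        u_draws = truncnorm.rvs(a0, np.inf, loc=cfg.mu, scale=cfg.sigma_u,
                                size=len(distinct), random_state=rng)
    u_by_unit = pd.Series(u_draws, index=distinct)
    v = (rng.normal(0.0, cfg.sigma_v, size=n) if cfg.sigma_v > 0
         else np.zeros(n))

    ln_total = (_frontier_value(ln_x, cfg.true_beta, cfg.form, INPUT_VARS)
                + v - u_by_unit.loc[units].to_numpy())
    total = np.exp(ln_total)

    share = np.full(n, cfg.outpatient_share)
    if cfg.stochastic_split:
        logit = math.log(cfg.outpatient_share / (1 - cfg.outpatient_share))
        share = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, cfg.split_jitter_sd, n))))
    outpatients = share * total
    inpatients = (1.0 - share) * total
    if cfg.integerize:
        outpatients = np.maximum(np.rint(outpatients), 1.0)
        inpatients = np.maximum(np.rint(inpatients), 1.0)
    if np.any(outpatients <= 0) or np.any(inpatients <= 0):
        raise GeneratorError("configured ranges produced non-positive outputs")

    frame = pd.DataFrame({
        "hospital_id": units,
        "year": years,
        **{name: np.exp(ln_x[name]) for name in INPUT_VARS},
        "inpatients": inpatients,
        "outpatients": outpatients,
    })
    if cfg.integerize:
        for name in INPUT_VARS + ("inpatients", "outpatients"):
            frame[name] = frame[name].astype(int)
    panel = HospitalPanel(frame)

    truth = GroundTruth(
        true_beta=dict(cfg.true_beta),
        u=u_by_unit,
        te=np.exp(-u_by_unit).rename("te"),
        v=v,
        config=cfg,
        metadata={
            "layout": "disaggregated+combined" if cfg.combined_window else "balanced",
            "scale_mix": bool(cfg.combined_window),
            "scale_mix_note": (
                "disaggregated hospital-years and the combined pseudo-unit "
                "share one input scale, mirroring the emulated study design"
                if cfg.combined_window else ""),
            "expected_te": expected_te(cfg.mu, cfg.sigma_u),
        },
    )
    return panel, truth
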