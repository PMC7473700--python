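"""Regressor-matrix expansion for the three frontier functional forms.

Three specifications of the log production frontier are supported:

* ``cobb_douglas`` — ln(inpatients + outpatients) on the four ln-inputs;
  constant input elasticities by construction.
* ``translog`` — adds all pairwise interactions ln x_j * ln x_h (j < h)
  and own-squared terms carrying an explicit 1/2 factor, so the reported
  second-order coefficients follow the "beta_jj * 0.5 (ln x_j)^2"
  convention.
* ``multi_output`` — an output distance form: the response is
  ln(outpatients) and the translog term set is augmented with ln Y*,
  its interactions with each ln-input and 0.5 (ln Y*)^2, where
  Y* = outpatients / inpatients (the output-mix ratio). This is the
  printed specification; note Y* contains the response by construction.

Slope (non-constant) parameter counts are 4 / 14 / 20 respectively.
Column order is deterministic: constant, first-order terms in input
order, interactions in lexicographic pair order, half-squares in input
order, then the Y* block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_data import INPUT_VARS, HospitalPanel

FORMS = ("cobb_douglas", "translog", "multi_output")
YSTAR = "ystar"


class DesignError(ValueError):
    """Invalid functional-form request or undefined logs."""


@dataclass(frozen=True)
class FrontierSpec:
    """A functional-form recipe for the frontier."""

    form: str = "cobb_douglas"
    inputs: tuple[str, ...] = INPUT_VARS

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise DesignError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if not self.inputs or len(set(self.inputs)) != len(self.inputs):
            raise DesignError("inputs must be non-empty and distinct")

    @property
    def output_mode(self) -> str:
        """``aggregate`` (ln of summed outputs) or ``distance`` (ln outpatients)."""
        return "distance" if self.form == "multi_output" else "aggregate"

    @property
    def n_slopes(self) -> int:
        """Number of non-constant parameters: 4 / 14 / 20 for k = 4 inputs."""
        k = len(self.inputs)
        if self.form == "cobb_douglas":
            return k
        second = k * (k - 1) // 2 + k
        if self.form == "translog":
            return k + second
        return k + second + 1 + k + 1    # + lnY*, Y* x inputs, half (lnY*)^2


@dataclass
class DesignMatrix:
    """Response and named regressor columns for one frontier spec."""

    response: np.ndarray                 # ln-output, shape (n,)
    X: np.ndarray                        # regressors incl. constant, (n, 1+p)
    columns: list[str]                   # column names, constant first
    unit_index: np.ndarray               # unit label per row, shape (n,)
    term_catalog: dict[str, tuple[str, tuple[str, ...]]]   # name -> (kind, parents)
    spec: FrontierSpec
    ln_levels: pd.DataFrame = field(repr=False, default=None)  # per-row ln x (and lnY*)
    years: np.ndarray = field(repr=False, default=None)        # per-row calendar year

    @property
    def n_obs(self) -> int:
        return len(self.response)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "response", self.response)
        df.insert(0, "unit", self.unit_index)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def mean_ln_point(self) -> dict[str, float]:
        """Sample mean of ln-levels (geometric mean of levels) — the default
        evaluation point for elasticities."""
        return {c: float(v) for c, v in self.ln_levels.mean().items()}

    def drop_second_order(self) -> "DesignMatrix":
        """Restrict to the nested Cobb-Douglas column set (same response).

        Used by the likelihood-ratio nesting test; only defined for the
        aggregate-output forms.
        """
        if self.spec.form != "translog":
            raise DesignError("drop_second_order is defined for translog designs")
        keep = [i for i, c in enumerate(self.columns)
                if self.term_catalog[c][0] in ("constant", "first_order")]
        cols = [self.columns[i] for i in keep]
        return DesignMatrix(
            response=self.response,
            X=self.X[:, keep],
            columns=cols,
            unit_index=self.unit_index,
            term_catalog={c: self.term_catalog[c] for c in cols},
            spec=replace(self.spec, form="cobb_douglas"),
            ln_levels=self.ln_levels,
            years=self.years,
        )


def _interaction_name(a: str, b: str) -> str:
    return f"ln_{a}:ln_{b}"


def build_design(panel: HospitalPanel, spec: FrontierSpec) -> DesignMatrix:
    """Expand a panel into the regressor matrix for ``spec``.

    Raises
    ------
    DesignError
        If any count is non-positive (logs undefined), or inpatients is
        zero in distance mode (Y* undefined).
    """
    df = panel.frame
    for col in spec.inputs:
        if col not in df.columns:
            raise DesignError(f"panel lacks input column {col!r}")
        if (df[col] <= 0).any():
            raise DesignError(f"non-positive values in {col!r}: log undefined")
    if (df["inpatients"] <= 0).any() or (df["outpatients"] <= 0).any():
        raise DesignError("non-positive output counts: log undefined")

    ln = {name: np.log(df[name].to_numpy(float)) for name in spec.inputs}
    if spec.output_mode == "aggregate":
        y = np.log(df["outpatients"].to_numpy(float) + df["inpatients"].to_numpy(float))
    else:
        y = np.log(df["outpatients"].to_numpy(float))
        ln[YSTAR] = np.log(df["outpatients"].to_numpy(float)
                           / df["inpatients"].to_numpy(float))

    n = len(df)
    columns: list[str] = ["const"]
    catalog: dict[str, tuple[str, tuple[str, ...]]] = {"const": ("constant", ())}
    data: list[np.ndarray] = [np.ones(n)]

    for a in spec.inputs:
        columns.append(f"ln_{a}")
        catalog[columns[-1]] = ("first_order", (a,))
        data.append(ln[a])

    if spec.form in ("translog", "multi_output"):
        for a, b in combinations(spec.inputs, 2):
            columns.append(_interaction_name(a, b))
            catalog[columns[-1]] = ("interaction", (a, b))
            data.append(ln[a] * ln[b])
        for a in spec.inputs:
            columns.append(f"half_ln_{a}_sq")
            catalog[columns[-1]] = ("half_square", (a, a))
            data.append(0.5 * ln[a] ** 2)

    if spec.form == "multi_output":
        columns.append("ln_ystar")
        catalog[columns[-1]] = ("ystar", (YSTAR,))
        data.append(ln[YSTAR])
        for a in spec.inputs:
            columns.append(_interaction_name(a, YSTAR))
            catalog[columns[-1]] = ("ystar_interaction", (a, YSTAR))
            data.append(ln[a] * ln[YSTAR])
        columns.append("half_ln_ystar_sq")
        catalog[columns[-1]] = ("half_ystar_square", (YSTAR, YSTAR))
        data.append(0.5 * ln[YSTAR] ** 2)

    X = np.column_stack(data)
    assert X.shape[1] == 1 + spec.n_slopes
    return DesignMatrix(
        response=y,
        X=X,
        columns=columns,
        unit_index=df["hospital_id"].to_numpy(str),
        term_catalog=catalog,
        spec=spec,
        ln_levels=pd.DataFrame(ln, index=df.index),
        years=df["year"].to_numpy(int),
    )
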