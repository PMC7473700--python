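"""Output elasticities, scale elasticity and returns-to-scale class.

For the translog frontier the elasticity of output with respect to input
j at an evaluation point (given in ln-levels) is

    e_j = beta_j + sum_{h != j} beta_jh ln x_h + beta_jj ln x_j,

where the half-square design convention makes beta_jj enter once. For
Cobb-Douglas, e_j = beta_j at every point. For the multi-output distance
form, the Y*-interaction coefficient of input j contributes
beta_{j,Y*} ln Y* at the evaluation point's output mix.

The scale elasticity is the sum of input elasticities; returns to scale
are increasing / constant / decreasing as the sum is above / at / below
1. The default evaluation point is the per-input sample mean of
ln-levels (the geometric mean of levels), which is the point at which
translog first-order coefficients are interpretable; every report states
the point used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .design_builder import YSTAR
from .frontier_mle import FrontierFit

#: tolerance on the sum-vs-1 comparison for exact arithmetic
RTS_TOL = 1e-9


@dataclass
class ElasticityTable:
    """Per-input output elasticities at one evaluation point."""

    elasticities: pd.Series              # index: input name
    point: dict[str, float] | None       # ln-levels used (None for CD/by-value)
    form: str

    @classmethod
    def from_values(cls, values: Mapping[str, float],
                    form: str = "external") -> "ElasticityTable":
        """Wrap already-computed elasticities (e.g. a published table)."""
        return cls(elasticities=pd.Series(dict(values), dtype=float),
                   point=None, form=form)

    @property
    def scale_elasticity(self) -> float:
        return float(self.elasticities.sum())

    @property
    def rts_class(self) -> str:
        return classify_rts(self.scale_elasticity)

    def to_csv(self, path: str | Path) -> None:
        df = self.elasticities.rename("elasticity").to_frame()
        df.loc["TOTAL"] = self.scale_elasticity
        df.to_csv(path)

    def one_line(self) -> str:
        total = self.scale_elasticity
        return (f"scale elasticity = {total:.4g} ({self.rts_class} returns "
                f"to scale), form = {self.form}")


def classify_rts(total: float, tol: float = RTS_TOL) -> str:
    if total > 1.0 + tol:
        return "increasing"
    if total < 1.0 - tol:
        return "decreasing"
    return "constant"


def input_elasticities(fit: FrontierFit,
                       point: Mapping[str, float] | None = None) -> ElasticityTable:
    """Per-input elasticities of the fitted frontier at ``point``.

    ``point`` maps input names (and ``"ystar"`` for the multi-output
    form) to ln-levels; defaults to the estimation sample's mean
    ln-levels.
    """
    spec = fit.spec
    if point is None:
        if fit.design is None:
            raise ValueError("no evaluation point given and fit carries no design")
        point = fit.design.mean_ln_point()
    needed = set(spec.inputs) | ({YSTAR} if spec.form == "multi_output" else set())
    missing = needed - set(point)
    if missing:
        raise ValueError(f"evaluation point missing ln-levels for {sorted(missing)}")

    elas = {name: 0.0 for name in spec.inputs}
    catalog = fit.design.term_catalog if fit.design is not None else None
    if catalog is None:
        raise ValueError("fit carries no design/term catalog")
    for col, (kind, parents) in catalog.items():
        b = float(fit.beta[col])
        if kind == "first_order":
            elas[parents[0]] += b
        elif kind == "interaction":
            j, h = parents
            elas[j] += b * point[h]
            elas[h] += b * point[j]
        elif kind == "half_square":
            j = parents[0]
            elas[j] += b * point[j]
        elif kind == "ystar_interaction":
            j = parents[0]
            elas[j] += b * point[YSTAR]
        # constant, ystar first-order and half_ystar_square do not enter
        # the input elasticities
    return ElasticityTable(elasticities=pd.Series(elas, dtype=float),
                           point=dict(point), form=spec.form)


def scale_elasticity(table: ElasticityTable,
                     exclude: Iterable[str] | None = None,
                     tol: float = RTS_TOL) -> tuple[float, str]:
    """Sum of elasticities over included inputs, with the RTS class.

    ``exclude`` drops inputs from the sum (holding them fixed), e.g. to
    ask what output response remains when one staff category is frozen.
    """
    excl = set(exclude or ())
    unknown = excl - set(table.elasticities.index)
    if unknown:
        raise ValueError(f"cannot exclude unknown inputs {sorted(unknown)}")
    kept = table.elasticities.drop(index=list(excl))
    if len(kept) == 0:
        raise ValueError("exclusion removes every input")
    total = float(kept.sum())
    return total, classify_rts(total, tol)
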