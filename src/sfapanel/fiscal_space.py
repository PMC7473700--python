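"""Fiscal-space scenarios: efficiency gaps converted to budget savings.

With all care free at the point of use, a public hospital system's only
revenue is its budget allocation G. The share of G that could be
released if the mean technical-efficiency score rose from a baseline to
a target is

    Rev = (eff_target - eff_baseline) * G,

in the budget's currency units (here MUR million). Reported cells are
rounded half-up to the nearest million; the unrounded value is retained.
When a General Government Health Expenditure (GGHE) level is supplied,
savings are also expressed as a percentage of GGHE (one decimal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


class ScenarioError(ValueError):
    """Invalid scenario configuration (bad scores, missing budgets)."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (4.5 -> 5), as in printed budget tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SavingsScenario:
    """One (baseline, target, budget) cell."""

    eff_baseline: float
    eff_target: float
    budget: float                       # MUR million
    savings: float                      # unrounded, MUR million
    savings_rounded: float              # half-up to nearest million
    gghe: float | None = None           # MUR million
    share_of_gghe: float | None = None  # percent, one decimal


def savings(eff_baseline: float, eff_target: float, budget: float,
            gghe: float | None = None) -> SavingsScenario:
    """Potential savings from lifting efficiency from baseline to target.

    A target below the baseline yields negative savings and a
    "disinvestment scenario" warning rather than an error.
    """
    for name, e in (("eff_baseline", eff_baseline), ("eff_target", eff_target)):
        if not (0.0 < e <= 1.0):
            raise ScenarioError(f"{name} must lie in (0, 1], got {e}")
    if budget <= 0:
        raise ScenarioError(f"budget must be > 0, got {budget}")
    raw = (eff_target - eff_baseline) * budget
    if raw < 0:
        warnings.warn("eff_target below baseline: disinvestment scenario",
                      stacklevel=2)
    share = None
    if gghe is not None:
        if gghe <= 0:
            raise ScenarioError(f"gghe must be > 0, got {gghe}")
        share = round_half_up(100.0 * raw / gghe, 1)
    return SavingsScenario(eff_baseline=eff_baseline, eff_target=eff_target,
                           budget=budget, savings=raw,
                           savings_rounded=round_half_up(raw),
                           gghe=gghe, share_of_gghe=share)


def scenario_grid(baselines: Sequence[float], targets: Sequence[float],
                  budgets: Mapping[str, float],
                  gghe: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Full baselines x targets x fiscal-year grid of savings cells.

    ``budgets`` (and optional ``gghe``) are keyed by fiscal-year label;
    a GGHE mapping must cover every budget year. Columns:
    fiscal_year, eff_baseline, eff_target, budget, savings,
    savings_rounded (+ gghe, share_of_gghe when supplied).
    """
    if not baselines or not targets or not budgets:
        raise ScenarioError("baselines, targets and budgets must be non-empty")
    if gghe is not None:
        missing = [y for y in budgets if y not in gghe]
        if missing:
            raise ScenarioError(f"no GGHE value for fiscal year(s) {missing}")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # grid cells may legitimately be negative
        for year, budget in budgets.items():
            g = gghe[year] if gghe is not None else None
            for base in baselines:
                for target in targets:
                    cell = savings(base, target, budget, gghe=g)
                    row = {"fiscal_year": year, "eff_baseline": base,
                           "eff_target": target, "budget": budget,
                           "savings": cell.savings,
                           "savings_rounded": cell.savings_rounded}
                    if g is not None:
                        row["gghe"] = g
                        row["share_of_gghe"] = cell.share_of_gghe
                    rows.append(row)
    return pd.DataFrame(rows)


def grid_to_csv(grid: pd.DataFrame, path: str | Path) -> None:
    grid.to_csv(path, index=False)
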