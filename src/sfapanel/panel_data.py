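"""Hospital-year panel: data model, CSV IO and validation.

The unit of observation is a hospital-year. Inputs are capital (active
beds) and three labour categories (doctors, nurses, non-medical staff);
outputs are annual inpatient admissions and outpatient visits. Panels may
be unbalanced: each hospital contributes its own run of years, and an
aggregated pseudo-unit (e.g. ``"ALL"`` for years where only combined
figures exist) is treated as one more unit with its own T_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

#: ordered production inputs, used everywhere downstream
INPUT_VARS: tuple[str, ...] = ("beds", "doctors", "nurses", "nonmedical")
#: production outputs
OUTPUT_VARS: tuple[str, ...] = ("inpatients", "outpatients")
#: numeric columns that must be strictly positive
COUNT_VARS: tuple[str, ...] = INPUT_VARS + OUTPUT_VARS
#: full required column set
REQUIRED_COLUMNS: tuple[str, ...] = ("hospital_id", "year") + COUNT_VARS

#: sanity window for calendar years (panels outside it are rejected)
DEFAULT_YEAR_WINDOW: tuple[int, int] = (1900, 2100)


class PanelSchemaError(ValueError):
    """The file/table does not have the expected columns or is empty."""


class PanelValidationError(ValueError):
    """Rows violate the panel invariants (positivity, uniqueness, years)."""


@dataclass(frozen=True)
class HospitalRecord:
    """One hospital-year observation."""

    hospital_id: str
    year: int
    beds: float
    doctors: float
    nurses: float
    nonmedical: float
    inpatients: float
    outpatients: float


class HospitalPanel:
    """An ordered, validated collection of hospital-year records.

    Wraps a :class:`pandas.DataFrame` with the canonical column set.
    Row order is preserved from the source; units are retrievable as
    groups and may have differing numbers of years (unbalanced panel).
    """

    def __init__(self, frame: pd.DataFrame, *, validate: bool = True,
                 year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW) -> None:
        frame = frame.reset_index(drop=True)
        if validate:
            _validate_frame(frame, year_window)
        extras = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        df = frame.loc[:, list(REQUIRED_COLUMNS) + extras].copy()
        df["hospital_id"] = df["hospital_id"].astype(str)
        df["year"] = df["year"].astype(int)
        for col in COUNT_VARS:
            df[col] = pd.to_numeric(df[col])
        self._frame = df

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[HospitalRecord], **kw) -> "HospitalPanel":
        rows = [vars(r) for r in records]
        if not rows:
            raise PanelSchemaError("cannot build a panel from zero records")
        return cls(pd.DataFrame(rows), **kw)

    # -- basic properties --------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (copy-on-write discipline: do not mutate)."""
        return self._frame

    @property
    def units(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self._frame["hospital_id"]:
            seen.setdefault(u)
        return list(seen)

    @property
    def n_obs(self) -> int:
        return len(self._frame)

    @property
    def years(self) -> tuple[int, int]:
        return int(self._frame["year"].min()), int(self._frame["year"].max())

    @property
    def unbalanced(self) -> bool:
        counts = self._frame.groupby("hospital_id").size()
        return counts.nunique() > 1

    def __len__(self) -> int:
        return self.n_obs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HospitalPanel):
            return NotImplemented
        return self._frame.equals(other._frame)

    def records(self) -> Iterator[HospitalRecord]:
        core = self._frame.loc[:, list(REQUIRED_COLUMNS)]
        for row in core.itertuples(index=False):
            yield HospitalRecord(**row._asdict())

    def group_by_unit(self) -> dict[str, pd.DataFrame]:
        return {str(k): g for k, g in self._frame.groupby("hospital_id", sort=False)}

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def _validate_frame(frame: pd.DataFrame, year_window: tuple[int, int]) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelSchemaError(f"missing required columns: {missing}")
    if len(frame) == 0:
        raise PanelSchemaError("panel table has no rows")

    bad_rows: list[str] = []
    for col in COUNT_VARS + ("year",):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        nn = numeric.isna()
        if nn.any():
            bad_rows += [f"row {i}: {col}={frame[col][i]!r} is not numeric"
                         for i in frame.index[nn]]
            continue
        if col == "year":
            lo, hi = year_window
            out = (numeric < lo) | (numeric > hi)
            bad_rows += [f"row {i}: year={int(numeric[i])} outside {lo}-{hi}"
                         for i in frame.index[out]]
        else:
            nonpos = numeric <= 0
            bad_rows += [f"row {i}: {col}={numeric[i]} must be > 0"
                         for i in frame.index[nonpos]]
    if bad_rows:
        raise PanelValidationError("invalid panel rows:\n  " + "\n  ".join(bad_rows))

    dup = frame.duplicated(subset=["hospital_id", "year"], keep=False)
    if dup.any():
        pairs = frame.loc[dup, ["hospital_id", "year"]].drop_duplicates()
        raise PanelValidationError(
            "duplicate (hospital_id, year) pairs: "
            + ", ".join(f"({r.hospital_id}, {r.year})" for r in pairs.itertuples())
        )


def load_panel(path: str | Path, schema: Mapping[str, str] | None = None,
               year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW) -> HospitalPanel:
    """Read a hospital-year panel from CSV.

    Parameters
    ----------
    path
        CSV file with a header row, comma-separated, UTF-8.
    schema
        Optional mapping from the file's column names to the canonical
        names in :data:`REQUIRED_COLUMNS` (e.g. ``{"lits": "beds"}``).
    year_window
        Acceptable calendar-year range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise PanelSchemaError(f"{path} is empty or has no header") from exc
    if schema:
        raw = raw.rename(columns=dict(schema))
    return HospitalPanel(raw, year_window=year_window)


def write_panel(panel: HospitalPanel, path: str | Path) -> None:
    """Write a panel back to CSV (numeric content round-trips exactly)."""
    panel.to_csv(path)


@dataclass
class PanelSummary:
    """Per-variable descriptive statistics (sample sd, n-1 convention)."""

    table: pd.DataFrame            # index: variable; cols: mean, sd, min, max
    n_obs: int
    derived: dict = field(default_factory=dict)   # e.g. bed-occupancy rate

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def summarize(panel: HospitalPanel) -> PanelSummary:
    """Descriptive statistics of inputs and outputs.

    Mirrors a standard descriptive table: mean, sample standard deviation,
    min and max per variable. With a single record the sd is reported as
    NaN (undefined), never zero. If the panel's source frame carried an
    optional ``hospital_days`` column, a mean bed-occupancy rate
    (hospital-days / (beds x 365)) is attached under ``derived``.
    """
    df = panel.frame
    stats = pd.DataFrame({
        "mean": df[list(COUNT_VARS)].mean(),
        "sd": df[list(COUNT_VARS)].std(ddof=1),   # NaN when n == 1
        "min": df[list(COUNT_VARS)].min(),
        "max": df[list(COUNT_VARS)].max(),
    })
    derived: dict = {}
    if "hospital_days" in df.columns:
        occ = df["hospital_days"] / (df["beds"] * 365.0)
        derived["bed_occupancy_rate"] = float(occ.mean())
    bad = stats.dropna(subset=["sd"])
    if not ((bad["min"] <= bad["mean"] + 1e-9) & (bad["mean"] <= bad["max"] + 1e-9)).all():
        raise AssertionError("summary invariant min <= mean <= max violated")
    return PanelSummary(table=stats, n_obs=len(df), derived=derived)
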