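"""Shared domain types: trial design, phenology calendar, long-format trait tables.

Every downstream module reads and writes the tidy trait table defined here:
one row per (plot_id, trait, date) with columns
``plot_id,trait,date,value,uncertainty``.  Dates are ISO-8601 calendar dates;
within-season arithmetic is done in integer days after sowing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "TrialDesign",
    "PhenologyCalendar",
    "TraitSeries",
    "load_design",
    "stage_at",
]


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """Input violates a domain invariant (duplicates, bad ordering, ...)."""


WATER_TREATMENTS = ("WW", "WD")
NITROGEN_TREATMENTS = ("N+", "N0")

#: Canonical phenological stages in season order.  ``stage_at`` returns the
#: latest stage whose date is <= the query date.
STAGE_ORDER = ("sowing", "emergence", "heading", "flowering", "maturity", "harvest")

_DESIGN_COLUMNS = ("plot_id", "genotype", "water_treatment", "nitrogen_treatment", "replicate")


@dataclass(frozen=True)
class PlotGeometry:
    """Axis-aligned plot rectangle in platform metres (x east, y north,
    origin at the platform's southwest corner)."""

    x: float
    y: float
    width: float = 1.0
    length: float = 6.0

    def overlaps(self, other: "PlotGeometry") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.length <= other.y
            or other.y + other.length <= self.y
        )


@dataclass
class TrialDesign:
    """Plot-to-treatment mapping for a split-plot shelter trial.

    The reference layout is 22 genotypes x {N+, N0} x {WW, WD} x 3 replicates
    (264 plots) distributed over shelters (1-8), each with two spans.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        dup = self.table["plot_id"][self.table["plot_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate plot_id values: {sorted(set(dup))}")
        bad_w = set(self.table["water_treatment"]) - set(WATER_TREATMENTS)
        if bad_w:
            raise ValidationError(f"unknown water treatment(s): {sorted(bad_w)}")
        bad_n = set(self.table["nitrogen_treatment"]) - set(NITROGEN_TREATMENTS)
        if bad_n:
            raise ValidationError(f"unknown nitrogen treatment(s): {sorted(bad_n)}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def plot_ids(self) -> list:
        return list(self.table["plot_id"])

    def treatment_of(self, plot_id) -> tuple[str, str]:
        row = self.table.loc[self.table["plot_id"] == plot_id]
        if row.empty:
            raise KeyError(f"unknown plot_id {plot_id!r}")
        return (row.iloc[0]["water_treatment"], row.iloc[0]["nitrogen_treatment"])

    @classmethod
    def full_factorial(
        cls,
        genotypes: Sequence[str],
        replicates: int = 3,
        shelters: Sequence[int] = (1, 2, 3, 4, 5, 6),
    ) -> "TrialDesign":
        """Build a complete genotype x nitrogen x water x replicate design.

        Water treatment alternates per shelter, nitrogen per span, mirroring
        the platform layout (stress factors applied at shelter/span scale).
        """
        rows = []
        i = 0
        for rep in range(1, replicates + 1):
            for wi, water in enumerate(WATER_TREATMENTS):
                shelter = shelters[(rep - 1) * 2 + wi] if len(shelters) >= 2 * replicates else shelters[i % len(shelters)]
                for span, nitro in enumerate(NITROGEN_TREATMENTS, start=1):
                    for g in genotypes:
                        rows.append(
                            {
                                "plot_id": f"P{i + 1:04d}",
                                "genotype": g,
                                "water_treatment": water,
                                "nitrogen_treatment": nitro,
                                "replicate": rep,
                                "shelter": shelter,
                                "span": span,
                            }
                        )
                        i += 1
        return cls(pd.DataFrame(rows))


def load_design(path: str | Path) -> TrialDesign:
    """Read and validate a trial-design CSV.

    Raises :class:`SchemaError` on missing columns and
    :class:`ValidationError` on duplicated plot ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return TrialDesign(pd.read_csv(path))


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


def _as_date_or_day(d):
    """Trait-table dates may be calendar dates or numeric days after sowing."""
    if isinstance(d, (int, float)) and not isinstance(d, bool):
        return float(d)
    try:
        return _as_date(d)
    except ValueError:
        return float(d)


@dataclass
class PhenologyCalendar:
    """Key dates of a plot's (or treatment's) growth cycle.

    Dates must be strictly increasing in the order sowing < emergence <
    heading < flowering < maturity < harvest (missing stages allowed).
    """

    dates: dict[str, _dt.date]
    zadoks: dict[_dt.date, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dates = {k: _as_date(v) for k, v in self.dates.items()}
        unknown = set(self.dates) - set(STAGE_ORDER)
        if unknown:
            raise ValidationError(f"unknown stage name(s): {sorted(unknown)}")
        if "sowing" not in self.dates:
            raise ValidationError("calendar requires at least a sowing date")
        present = [(s, self.dates[s]) for s in STAGE_ORDER if s in self.dates]
        for (s1, d1), (s2, d2) in zip(present, present[1:]):
            if d2 <= d1:
                raise ValidationError(f"{s2} ({d2}) must be after {s1} ({d1})")
        self.zadoks = {_as_date(k): v for k, v in self.zadoks.items()}

    def days_after_sowing(self, date) -> int:
        return (_as_date(date) - self.dates["sowing"]).days

    def date_of(self, stage: str) -> _dt.date:
        return self.dates[stage]

    def zadoks_at(self, date) -> str | None:
        """Latest Zadoks stage entered on or before ``date`` (None if unknown)."""
        d = _as_date(date)
        hits = [s for dd, s in sorted(self.zadoks.items()) if dd <= d]
        return hits[-1] if hits else None


def stage_at(calendar: PhenologyCalendar, date) -> str:
    """Return the phenological stage active at ``date``.

    Piecewise constant: the latest stage whose date is <= the query;
    "pre-emergence" between sowing and emergence.  Queries before sowing are
    out of range.
    """
    d = _as_date(date)
    if d < calendar.dates["sowing"]:
        raise ValidationError(f"date {d} precedes sowing {calendar.dates['sowing']}")
    current = "sowing"
    for stage in STAGE_ORDER:
        if stage in calendar.dates and calendar.dates[stage] <= d:
            current = stage
    if current == "sowing" and "emergence" in calendar.dates and d < calendar.dates["emergence"] and d > calendar.dates["sowing"]:
        return "pre-emergence"
    return current


_TRAIT_COLUMNS = ("plot_id", "trait", "date", "value", "uncertainty")


@dataclass
class TraitSeries:
    """Tidy per-plot trait table: one row per (plot_id, trait, date).

    The unit all temporal analyses operate on.  ``uncertainty`` is optional
    (NaN where absent).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("plot_id", "trait", "date", "value") if c not in self.table.columns]
        if missing:
            raise SchemaError(f"trait table missing columns: {missing}")
        t = self.table.copy()
        if "uncertainty" not in t.columns:
            t["uncertainty"] = float("nan")
        t["date"] = t["date"].map(_as_date_or_day)
        if t.duplicated(subset=["plot_id", "trait", "date"]).any():
            raise ValidationError("duplicate (plot_id, trait, date) rows")
        self.table = t.sort_values(["plot_id", "trait", "date"]).reset_index(drop=True)[list(_TRAIT_COLUMNS)]

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "TraitSeries":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def single(cls, plot_id, trait: str, dates, values, uncertainty=None) -> "TraitSeries":
        """Build a one-plot one-trait series from parallel date/value arrays."""
        df = pd.DataFrame({"plot_id": plot_id, "trait": trait, "date": list(dates), "value": list(values)})
        if uncertainty is not None:
            df["uncertainty"] = list(uncertainty)
        return cls(df)

    def select(self, plot_id=None, trait: str | None = None) -> "TraitSeries":
        t = self.table
        if plot_id is not None:
            t = t[t["plot_id"] == plot_id]
        if trait is not None:
            t = t[t["trait"] == trait]
        return TraitSeries(t.copy())

    def dates_values(self) -> tuple[list[_dt.date], list[float]]:
        """(dates, values) of a single-plot single-trait series, date-sorted."""
        if self.table["plot_id"].nunique() > 1 or self.table["trait"].nunique() > 1:
            raise ValidationError("series spans several plots or traits; select() first")
        return list(self.table["date"]), list(self.table["value"].astype(float))

    def concat(self, other: "TraitSeries") -> "TraitSeries":
        return TraitSeries(pd.concat([self.table, other.table], ignore_index=True))

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["date"] = out["date"].map(lambda d: d.isoformat() if isinstance(d, _dt.date) else repr(d))
        # repr round-trips float64 exactly through pandas' parser
        out.to_csv(path, index=False, float_format=lambda v: repr(float(v)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "TraitSeries":
        return cls(pd.read_csv(path))

    def to_wide(self, trait: str) -> pd.DataFrame:
        """Convenience wide export: rows = dates, columns = plots, one trait."""
        t = self.table[self.table["trait"] == trait]
        return t.pivot(index="date", columns="plot_id", values="value")


def load_phenology(path: str | Path) -> dict[str, PhenologyCalendar]:
    """Read a phenology CSV (columns: key + stage-name date columns).

    ``key`` may hold plot ids or treatment labels; plot-level calendars take
    precedence over treatment-level ones when both are supplied downstream.
    """
    df = pd.read_csv(path)
    if "key" not in df.columns:
        raise SchemaError("phenology CSV requires a 'key' column")
    out = {}
    for _, row in df.iterrows():
        dates = {s: row[s] for s in STAGE_ORDER if s in df.columns and pd.notna(row[s])}
        out[str(row["key"])] = PhenologyCalendar(dates)
    return out
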