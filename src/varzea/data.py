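"""Survey data model: detection records, traits, the hydrological season calendar.

A survey is a long-format table of detection records: one row per
(lake, year-month, sampling unit, species) with the number of individuals
caught and their summed wet mass in grams.  Absence is implicit — zero-count
rows are rejected rather than stored, so occupancy downstream is defined
purely by detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "SeasonCalendar",
    "DEFAULT_CALENDAR",
    "SEASONS",
    "SurveyTable",
    "parse_survey_table",
    "parse_traits_table",
    "write_survey_table",
    "assign_seasons",
    "species_summaries",
    "validation_report",
    "load_schema",
]

#: canonical column names of the survey dialect
CANONICAL_COLUMNS = ("lake", "year_month", "unit", "species", "count", "biomass_g")

#: hydrological seasons of the Amazonian floodplain, in water-cycle order:
#: high water, falling water, low water, rising water.
SEASONS = ("cheia", "vazante", "seca", "enchente")


class SchemaError(ValueError):
    """A required column cannot be resolved in an input file."""


class ValidationError(ValueError):
    """Input rows violate the data model's invariants."""


@dataclass(frozen=True)
class SeasonCalendar:
    """Total mapping from calendar month (1-12) to one of four season labels.

    The default maps May-July to *cheia* (high water), August to *vazante*
    (falling water), September-November to *seca* (low water) and
    December-April to *enchente* (rising water).  Seasons pool across
    calendar years: October of any year is *seca*.
    """

    month_to_season: Mapping[int, str]

    def __post_init__(self) -> None:
        months = set(self.month_to_season)
        if months != set(range(1, 13)):
            missing = sorted(set(range(1, 13)) - months)
            raise ValidationError(f"calendar must cover months 1-12; missing {missing}")
        labels = set(self.month_to_season.values())
        if len(labels) != 4:
            raise ValidationError(f"calendar must use exactly 4 season labels, got {sorted(labels)}")
        object.__setattr__(self, "month_to_season", dict(self.month_to_season))

    @property
    def seasons(self) -> tuple[str, ...]:
        """Season labels in first-month-of-appearance order (Jan..Dec)."""
        seen: list[str] = []
        for m in range(1, 13):
            s = self.month_to_season[m]
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def season_of_month(self, month: int) -> str:
        try:
            return self.month_to_season[int(month)]
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"month {month!r} outside calendar") from exc

    def season_of(self, year_month: str) -> str:
        """Season of an ISO ``YYYY-MM`` string (year is ignored: seasons pool)."""
        return self.season_of_month(_parse_month(year_month))


def _parse_month(year_month: str) -> int:
    parts = str(year_month).split("-")
    if len(parts) != 2 or len(parts[0]) != 4:
        raise ValidationError(f"year_month {year_month!r} is not ISO 'YYYY-MM'")
    try:
        year, month = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValidationError(f"year_month {year_month!r} is not ISO 'YYYY-MM'") from exc
    if not 1 <= month <= 12:
        raise ValidationError(f"year_month {year_month!r} has month outside 1-12")
    return month


DEFAULT_CALENDAR = SeasonCalendar(
    {
        1: "enchente", 2: "enchente", 3: "enchente", 4: "enchente",
        5: "cheia", 6: "cheia", 7: "cheia",
        8: "vazante",
        9: "seca", 10: "seca", 11: "seca",
        12: "enchente",
    }
)


@dataclass
class SurveyTable:
    """Validated survey: detection records plus optional traits and a calendar.

    ``records`` holds the canonical columns (and ``season`` once
    :func:`assign_seasons` has run).  ``traits`` is an optional frame indexed
    by species with a ``mean_wet_weight_g`` column; when present it takes
    precedence over the biomass/count ratio in :func:`species_summaries`.
    """

    records: pd.DataFrame
    traits: pd.DataFrame | None = None
    calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)

    def __post_init__(self) -> None:
        problems = _validate_records(self.records)
        if problems:
            raise ValidationError("; ".join(problems[:10]))
        self.records = _canonicalize(self.records)
        if self.traits is not None:
            self.traits = _validate_traits(self.traits)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def lakes(self) -> list[str]:
        return sorted(self.records["lake"].unique())

    @property
    def n_species(self) -> int:
        return self.records["species"].nunique()

    @property
    def has_seasons(self) -> bool:
        return "season" in self.records.columns

    def with_records(self, records: pd.DataFrame) -> "SurveyTable":
        return SurveyTable(records=records, traits=self.traits, calendar=self.calendar)


def _canonicalize(records: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in CANONICAL_COLUMNS if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    out = records[cols + extra].copy()
    out["count"] = out["count"].astype(int)
    out["biomass_g"] = out["biomass_g"].astype(float)
    out["lake"] = out["lake"].astype(str)
    out["species"] = out["species"].astype(str)
    out["year_month"] = out["year_month"].astype(str)
    out["unit"] = out["unit"].astype(int)
    out = out.sort_values(["lake", "year_month", "unit", "species"], kind="mergesort")
    return out.reset_index(drop=True)


def _validate_records(records: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    missing = [c for c in CANONICAL_COLUMNS if c not in records.columns]
    if missing:
        return [f"missing required columns {missing}"]
    if len(records) == 0:
        return problems  # empty tables are valid containers; summaries reject them
    counts = pd.to_numeric(records["count"], errors="coerce")
    bad = records.index[counts.isna() | (counts < 1) | (counts % 1 != 0)]
    if len(bad):
        problems.append(f"count must be a positive integer; offending rows {list(bad[:20])}")
    biomass = pd.to_numeric(records["biomass_g"], errors="coerce")
    bad = records.index[biomass.isna() | (biomass <= 0)]
    if len(bad):
        problems.append(f"biomass_g must be > 0; offending rows {list(bad[:20])}")
    for ym in records["year_month"].unique():
        try:
            _parse_month(ym)
        except ValidationError as exc:
            problems.append(str(exc))
    key = ["lake", "year_month", "unit", "species"]
    dup = records.duplicated(subset=key)
    if dup.any():
        problems.append(
            f"duplicate (sample, species) records; offending rows {list(records.index[dup][:20])}"
        )
    return problems


def _validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    t = traits.copy()
    if "species" in t.columns:
        t = t.set_index("species")
    if "mean_wet_weight_g" not in t.columns:
        raise SchemaError("traits table needs a mean_wet_weight_g column")
    if t.index.has_duplicates:
        raise ValidationError("traits table has duplicate species rows")
    w = pd.to_numeric(t["mean_wet_weight_g"], errors="coerce")
    if (w.isna() | (w <= 0)).any():
        bad = list(t.index[w.isna() | (w <= 0)][:20])
        raise ValidationError(f"mean_wet_weight_g must be > 0; offending species {bad}")
    t["mean_wet_weight_g"] = w.astype(float)
    t.index = t.index.astype(str)
    return t.sort_index()


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a canonical-to-actual column-name map from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict):
        raise SchemaError(f"schema file {path} must hold a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def parse_survey_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
    traits: pd.DataFrame | None = None,
    calendar: SeasonCalendar | None = None,
) -> SurveyTable:
    """Read a delimited survey file into a validated :class:`SurveyTable`.

    Parameters
    ----------
    schema
        Optional map from canonical column names (``lake``, ``year_month``,
        ``unit``, ``species``, ``count``, ``biomass_g``) to the file's actual
        header names.
    sep
        Field delimiter; ``None`` sniffs comma (default) versus tab.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        header = path.open(encoding="utf-8").readline()
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    if schema:
        rename = {actual: canonical for canonical, actual in schema.items()}
        missing = [a for a in rename if a not in frame.columns]
        if missing:
            raise SchemaError(f"schema names columns absent from {path.name}: {missing}")
        frame = frame.rename(columns=rename)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name} lacks required columns {missing}")
    frame["count"] = pd.to_numeric(frame["count"], errors="coerce")
    frame["biomass_g"] = pd.to_numeric(frame["biomass_g"], errors="coerce")
    frame["unit"] = pd.to_numeric(frame["unit"], errors="coerce").astype("Int64")
    return SurveyTable(
        records=frame,
        traits=traits,
        calendar=calendar if calendar is not None else DEFAULT_CALENDAR,
    )


def parse_traits_table(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    return _validate_traits(frame)


def write_survey_table(table: SurveyTable, path: str | Path) -> None:
    """Write the canonical form (sorted rows, canonical column order)."""
    cols = list(CANONICAL_COLUMNS) + (["season"] if table.has_seasons else [])
    table.records[cols].to_csv(path, index=False, float_format="%.10g")


def assign_seasons(table: SurveyTable, calendar: SeasonCalendar | None = None) -> SurveyTable:
    """Annotate every record with its hydrological season.

    Seasons pool across calendar years: October 2003 and October 2004 both
    map to *seca* and count as one season downstream.
    """
    cal = calendar if calendar is not None else table.calendar
    records = table.records.copy()
    records["season"] = [cal.season_of(ym) for ym in records["year_month"]]
    return SurveyTable(records=records, traits=table.traits, calendar=cal)


def species_summaries(table: SurveyTable) -> pd.DataFrame:
    """Per-species totals in both currencies.

    Returns a frame indexed by species with columns ``n_individuals``,
    ``biomass_g`` and ``mean_wet_weight_g``.  Mean weight comes from the
    traits table when available, otherwise from total biomass / total count.
    """
    if len(table.records) == 0:
        raise ValidationError("empty survey table: no records to summarise")
    g = table.records.groupby("species")
    out = pd.DataFrame(
        {
            "n_individuals": g["count"].sum().astype(int),
            "biomass_g": g["biomass_g"].sum(),
        }
    )
    out["mean_wet_weight_g"] = out["biomass_g"] / out["n_individuals"]
    if table.traits is not None:
        known = table.traits["mean_wet_weight_g"].reindex(out.index)
        out.loc[known.notna(), "mean_wet_weight_g"] = known[known.notna()]
    return out.sort_index()


def validation_report(path: str | Path, schema: Mapping[str, str] | None = None) -> dict:
    """Validate a survey file and return a JSON-serialisable report."""
    try:
        table = parse_survey_table(path, schema=schema)
    except (SchemaError, ValidationError) as exc:
        return {"valid": False, "error_type": type(exc).__name__, "detail": str(exc)}
    return {
        "valid": True,
        "n_records": int(len(table.records)),
        "n_species": int(table.n_species),
        "n_lakes": int(table.records["lake"].nunique()),
        "n_months": int(table.records["year_month"].nunique()),
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
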