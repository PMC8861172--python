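"""Wildlife-vehicle-collision (WVC) record database and summaries.

One record is one study × species × country entry from the roadkill
literature: how many individuals were found and over how many study years.
The convention for incomplete reports is that a missing individual count or a
missing study duration counts as one, so every record contributes at least
one roadkill and one study-year.  A record's annual rate is individuals per
study-year; country maps are built from the sum of these rates ("WVC in a
single year") and from the total study-years ("sampling effort").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SOURCE_KINDS = {"article", "proceedings", "book_chapter", "database", "report", "news", "thesis"}

#: Calendar span of the collated roadkill literature; records outside it are
#: flagged, not rejected.
YEAR_SPAN = (1963, 2021)

CSV_COLUMNS = ["species", "country", "individuals", "study_years", "year_start", "year_end", "source_kind"]


class WVCValidationError(ValueError):
    pass


@dataclass(frozen=True)
class WVCRecord:
    species: str
    country: str
    individuals: int = 1
    study_years: float = 1.0
    year_start: int | None = None
    year_end: int | None = None
    source_kind: str | None = None
    out_of_span: bool = False

    @property
    def annual_rate(self) -> float:
        return self.individuals / self.study_years


def _canonical(s: str) -> str:
    return " ".join(str(s).strip().split())


def normalize_record(raw: dict, *, row: int | None = None) -> WVCRecord:
    """Normalize one raw record dict into a :class:`WVCRecord`.

    Missing ``individuals`` or ``study_years`` become 1.  Species and country
    are required; their strings are trimmed and whitespace-collapsed.
    """
    where = f" (row {row})" if row is not None else ""

    def missing(v):
        return v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and not v.strip())

    species = raw.get("species")
    country = raw.get("country")
    if missing(species) or missing(country):
        raise WVCValidationError(f"record missing species or country{where}: {raw!r}")
    individuals = raw.get("individuals")
    individuals = 1 if missing(individuals) else int(individuals)
    years = raw.get("study_years")
    years = 1.0 if missing(years) else float(years)
    if individuals < 1 or years <= 0:
        raise WVCValidationError(f"nonpositive individuals/study_years{where}: {raw!r}")
    y0 = raw.get("year_start")
    y1 = raw.get("year_end")
    y0 = None if missing(y0) else int(y0)
    y1 = None if missing(y1) else int(y1)
    if y0 is not None and y1 is not None and y0 > y1:
        raise WVCValidationError(f"year_start > year_end{where}: {raw!r}")
    out_of_span = any(
        y is not None and not (YEAR_SPAN[0] <= y <= YEAR_SPAN[1]) for y in (y0, y1)
    )
    kind = raw.get("source_kind")
    kind = None if missing(kind) else _canonical(kind).lower()
    return WVCRecord(
        species=_canonical(species),
        country=_canonical(country),
        individuals=individuals,
        study_years=max(1.0, years),
        year_start=y0,
        year_end=y1,
        source_kind=kind,
        out_of_span=out_of_span,
    )


def annual_rate(record: WVCRecord) -> float:
    """Roadkilled individuals per year: individuals / study_years."""
    return record.annual_rate


def read_records(path) -> list[WVCRecord]:
    """Read and normalize a WVC record CSV (blank cells = missing)."""
    df = pd.read_csv(path)
    return [normalize_record(rec, row=i) for i, rec in enumerate(df.to_dict("records"))]


def country_summary(records: Iterable[WVCRecord], *, mode: str = "sum_rates") -> pd.DataFrame:
    """Per-country WVC totals and sampling effort.

    ``single_year_wvc`` is, by default, the sum over the country's records of
    each record's annual rate (every study contributes its per-year roadkill
    rate); ``effort_years`` is the sum of study durations.  ``mode=
    'per_year_max'`` is an experimental alternative that takes the maximum
    annual rate over records instead of the sum.
    """
    rows = [
        {"country": r.country, "rate": r.annual_rate, "years": r.study_years} for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["country", "single_year_wvc", "effort_years", "n_records"]).set_index("country")
    df = pd.DataFrame(rows)
    if mode == "sum_rates":
        wvc = df.groupby("country")["rate"].sum()
    elif mode == "per_year_max":
        wvc = df.groupby("country")["rate"].max()
    else:
        raise ValueError(f"unknown country summary mode {mode!r}")
    out = pd.DataFrame(
        {
            "single_year_wvc": wvc,
            "effort_years": df.groupby("country")["years"].sum(),
            "n_records": df.groupby("country").size(),
        }
    ).sort_index()
    return out


def species_summary(
    records: Iterable[WVCRecord], species_universe: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    """Per-species totals and the coverage count over an analysed species set.

    Returns ``(table, coverage)`` where coverage is the number of universe
    species with at least one record.  Names are matched case-insensitively
    on canonical binomials; records naming species outside the universe are
    kept in the table and flagged ``in_universe=False``.
    """
    universe = {_canonical(s).lower(): _canonical(s) for s in species_universe}
    rows = [
        {
            "species": _canonical(r.species),
            "key": _canonical(r.species).lower(),
            "individuals": r.individuals,
            "rate": r.annual_rate,
        }
        for r in records
    ]
    if rows:
        df = pd.DataFrame(rows)
        table = pd.DataFrame(
            {
                "total_individuals": df.groupby("species")["individuals"].sum(),
                "n_records": df.groupby("species").size(),
                "max_annual_rate": df.groupby("species")["rate"].max(),
                "in_universe": df.groupby("species")["key"].first().isin(universe),
            }
        ).sort_index()
        covered = {k for k in df["key"].unique() if k in universe}
    else:
        table = pd.DataFrame(
            columns=["total_individuals", "n_records", "max_annual_rate", "in_universe"]
        )
        table.index.name = "species"
        covered = set()
    return table, len(covered)
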