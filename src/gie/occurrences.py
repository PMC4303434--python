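"""Reading, validation and profiling of species point-occurrence tables.

An occurrence record is one (species, longitude, latitude) triple in decimal
degrees (WGS84, lon/lat order internally). A record means a species was
collected at least once at that locality; multiplicity carries no weight, so
exact duplicate triples collapse to a single record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column names of the internal table
COLUMNS = ("species", "lon", "lat")

#: record-count bins used to profile collection effort: singletons, then a
#: long tail (2-15, 16-60, 61-100, >100 records per species)
COUNT_BINS = ((1, 1), (2, 15), (16, 60), (61, 100), (101, np.inf))
COUNT_BIN_LABELS = ("1", "2-15", "16-60", "61-100", ">100")


class OccurrenceError(ValueError):
    """Raised for unreadable or empty occurrence input."""


@dataclass
class CleaningReport:
    """What validation did to the raw rows of an input file."""

    n_rows_in: int = 0
    n_bad_coordinates: int = 0
    n_missing_fields: int = 0
    n_duplicates_collapsed: int = 0
    n_records_out: int = 0
    messages: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows_in": self.n_rows_in,
                "n_bad_coordinates": self.n_bad_coordinates,
                "n_missing_fields": self.n_missing_fields,
                "n_duplicates_collapsed": self.n_duplicates_collapsed,
                "n_records_out": self.n_records_out,
                "messages": self.messages,
            },
            indent=2,
        )


@dataclass(frozen=True)
class OccurrenceTable:
    """Validated, de-duplicated occurrence records.

    ``df`` has exactly the columns ``species`` (str), ``lon``, ``lat``
    (float64, decimal degrees) and a clean RangeIndex. Construct via
    :func:`read_occurrences` or :meth:`from_dataframe`.
    """

    df: pd.DataFrame

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, strict: bool = False
    ) -> tuple["OccurrenceTable", CleaningReport]:
        report = CleaningReport(n_rows_in=len(df))
        out = df.loc[:, list(COLUMNS)].copy()
        out["species"] = out["species"].astype("string").str.strip()
        out["lon"] = pd.to_numeric(out["lon"], errors="coerce")
        out["lat"] = pd.to_numeric(out["lat"], errors="coerce")

        missing = out["species"].isna() | (out["species"] == "")
        if missing.any():
            report.n_missing_fields = int(missing.sum())
            report.messages.append(f"{missing.sum()} rows without a species label")
            if strict:
                raise OccurrenceError(report.messages[-1])
            out = out[~missing]

        bad = (
            out["lon"].isna()
            | out["lat"].isna()
            | (out["lon"].abs() > 180)
            | (out["lat"].abs() > 90)
        )
        if bad.any():
            report.n_bad_coordinates = int(bad.sum())
            report.messages.append(
                f"{bad.sum()} rows with unparseable or out-of-range coordinates dropped"
            )
            if strict:
                raise OccurrenceError(report.messages[-1])
            out = out[~bad]

        n_before = len(out)
        out = out.drop_duplicates(subset=list(COLUMNS))
        report.n_duplicates_collapsed = n_before - len(out)
        if report.n_duplicates_collapsed:
            report.messages.append(
                f"{report.n_duplicates_collapsed} exact duplicate records collapsed"
            )

        if out.empty:
            raise OccurrenceError("no valid occurrence records after cleaning")

        out = out.astype({"species": str, "lon": float, "lat": float})
        out = out.reset_index(drop=True)
        report.n_records_out = len(out)
        for msg in report.messages:
            logger.warning(msg)
        return cls(out), report

    # -- basic views -------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_species(self) -> int:
        return self.df["species"].nunique()

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def species_index(self) -> Mapping[str, pd.DataFrame]:
        """species id -> DataFrame of its records."""
        return dict(tuple(self.df.groupby("species", sort=True)))

    def records_of(self, species_id: str) -> pd.DataFrame:
        sub = self.df[self.df["species"] == species_id]
        if sub.empty:
            raise KeyError(species_id)
        return sub

    def coords_of(self, species_id: str) -> np.ndarray:
        """(n, 2) array of lon/lat for one species."""
        return self.records_of(species_id)[["lon", "lat"]].to_numpy()

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)


def read_occurrences(
    path: str | Path,
    *,
    delimiter: str = ",",
    species_col: str | int = "species",
    lon_col: str | int = "lon",
    lat_col: str | int = "lat",
    header: bool = True,
    strict: bool = False,
) -> tuple[OccurrenceTable, CleaningReport]:
    """Read a delimited occurrence file into a validated table.

    Columns may be addressed by header name or 0-based position. Rows with
    unparseable or out-of-range coordinates are dropped (and reported) unless
    ``strict`` is set, in which case the first problem raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, header=0 if header else None, dtype=str)
    if raw.empty:
        raise OccurrenceError(f"{path}: no data rows")

    def resolve(col: str | int, role: str) -> pd.Series:
        if isinstance(col, int):
            if col >= raw.shape[1]:
                raise OccurrenceError(f"{path}: no column {col} for {role}")
            return raw.iloc[:, col]
        if col not in raw.columns:
            raise OccurrenceError(f"{path}: no column {col!r} for {role}")
        return raw[col]

    df = pd.DataFrame(
        {
            "species": resolve(species_col, "species"),
            "lon": resolve(lon_col, "lon"),
            "lat": resolve(lat_col, "lat"),
        }
    )
    return OccurrenceTable.from_dataframe(df, strict=strict)


def species_record_counts(table: OccurrenceTable) -> pd.Series:
    """Number of records per species, indexed by species id."""
    return table.df.groupby("species").size().sort_index()


def summarize_table(table: OccurrenceTable) -> dict:
    """Record-count profile of a table.

    Returns per-species counts, the fraction of singleton species, and the
    fraction of species in each record-count bin (the bin fractions always
    sum to 1).
    """
    counts = species_record_counts(table)
    n_sp = len(counts)
    bin_fractions = {}
    for (lo, hi), label in zip(COUNT_BINS, COUNT_BIN_LABELS):
        bin_fractions[label] = float(((counts >= lo) & (counts <= hi)).sum() / n_sp)
    return {
        "n_species": n_sp,
        "n_records": table.n_records,
        "per_species_counts": counts,
        "singleton_fraction": float((counts == 1).sum() / n_sp),
        "bin_fractions": bin_fractions,
    }
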