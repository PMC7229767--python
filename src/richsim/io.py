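"""File formats: incidence CSV, occurrence records, result tables, config.

The incidence CSV dialect is: UTF-8, comma-separated, header row required;
first column holds the species id, remaining columns are effort-unit ids,
cells are 0/1.  Occurrence records are raw "taxon, date" rows aggregated to
day-level incidence (one column per distinct calendar date).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .community import AbundanceProfile, IncidenceMatrix
from .errors import FormatError
from .estimators import FrequencyCounts, RichnessEstimate

__all__ = [
    "OccurrenceRecord",
    "records_to_incidence",
    "read_occurrence_csv",
    "read_incidence_csv",
    "write_incidence_csv",
    "write_profile_csv",
    "write_estimates_csv",
    "read_config",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    """One primary biodiversity record: a taxon at a point in time."""

    taxon: str
    date: _dt.date
    site: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon:
            raise FormatError("taxon name must be nonempty")
        if not isinstance(self.date, _dt.date):
            raise FormatError(f"date must be a calendar date, got {self.date!r}")


def records_to_incidence(records: list[OccurrenceRecord]) -> IncidenceMatrix:
    """Aggregate raw occurrence records into day-level incidence.

    One row per distinct taxon, one column per distinct calendar date
    (sorted); a cell is 1 iff the taxon was recorded at least once on that
    date, so duplicate records collapse.
    """
    if not records:
        raise FormatError("no occurrence records supplied")
    taxa = sorted({r.taxon for r in records})
    dates = sorted({r.date for r in records})
    t_idx = {t: i for i, t in enumerate(taxa)}
    d_idx = {d: j for j, d in enumerate(dates)}
    values = np.zeros((len(taxa), len(dates)), dtype=np.uint8)
    for r in records:
        values[t_idx[r.taxon], d_idx[r.date]] = 1
    return IncidenceMatrix(values, taxa, [d.isoformat() for d in dates])


def read_occurrence_csv(path: str | Path) -> list[OccurrenceRecord]:
    """Read "taxon,date[,site]" rows; dates must be ISO 8601.

    Unparseable dates raise a :class:`FormatError` naming the line number
    (header = line 1).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty occurrence file") from exc
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "taxon" or cols[1] != "date":
        raise FormatError(f"{path}: expected header 'taxon,date[,site]', got {list(df.columns)}")
    if df.empty:
        raise FormatError(f"{path}: no occurrence records")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        taxon, raw_date = row[0], row[1]
        if not isinstance(taxon, str) or not taxon.strip():
            raise FormatError(f"{path}: line {i}: empty taxon name")
        try:
            date = _dt.date.fromisoformat(str(raw_date).strip())
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: unparseable date {raw_date!r}") from exc
        site = str(row[2]) if len(row) > 2 and pd.notna(row[2]) else None
        records.append(OccurrenceRecord(taxon.strip(), date, site))
    return records


def write_incidence_csv(matrix: IncidenceMatrix, path: str | Path) -> None:
    """Write the incidence CSV dialect (species id column + 0/1 unit columns)."""
    df = pd.DataFrame(matrix.values, index=matrix.species_ids, columns=matrix.unit_ids)
    df.index.name = "species"
    df.to_csv(path)


def read_incidence_csv(path: str | Path) -> IncidenceMatrix:
    """Read an incidence CSV, validating shape, labels and binary cells.

    Errors name the offending cell (species id, unit id).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty incidence file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a species column plus at least one unit column")
    species = df.iloc[:, 0].tolist()
    units = [str(c) for c in df.columns[1:]]
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise FormatError(f"{path}: duplicate species id(s): {dupes}")
    values = np.zeros((len(species), len(units)), dtype=np.uint8)
    for j, unit in enumerate(units, start=1):
        col = df.iloc[:, j].str.strip()
        bad = ~col.isin(["0", "1"])
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"{path}: non-binary cell at species {species[i]!r}, "
                f"unit {unit!r}: {col.iloc[i]!r}"
            )
        values[:, j - 1] = col.astype(np.uint8)
    return IncidenceMatrix(values, [str(s) for s in species], units)


def write_profile_csv(profile: AbundanceProfile, path: str | Path) -> None:
    """Export species_id, lambda, is_error."""
    pd.DataFrame(
        {
            "species_id": profile.species_ids(),
            "lambda": profile.lambdas,
            "is_error": profile.is_error.astype(int),
        }
    ).to_csv(path, index=False)


def write_estimates_csv(
    estimates: list[RichnessEstimate], counts: FrequencyCounts, path: str | Path
) -> None:
    """One row per estimator: estimator, S_obs, T, Q1..Q4, estimate, fallback_used."""
    rows = [
        {
            "estimator": e.estimator,
            "S_obs": counts.S_obs,
            "T": counts.T,
            "Q1": counts.q(1),
            "Q2": counts.q(2),
            "Q3": counts.q(3),
            "Q4": counts.q(4),
            "estimate": e.estimate,
            "fallback_used": e.fallback_used,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment; keys lowercase."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise FormatError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = stripped.split("=", 1)
        out[key.strip().lower()] = value.strip()
    return out
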