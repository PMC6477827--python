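"""Reading and writing count tables in the standard 15-column CSV schema.

Columns (canonical order): id, date, time, species, number, north, station,
location, age, sex, morph, health, remark, dcremark, filter.  Dates are
YYYY-MM-DD, times hh:mm:ss (naive local times).  Missing values are written
as empty strings; empty strings and literal ``NA`` both read as absent.
The delimiter is auto-detected among comma, semicolon and tab; output is
always comma-separated.
"""

from __future__ import annotations

import datetime as dt
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import pandas as pd

from .records import COLUMNS, CountRecord
from .taxonomy import Hierarchy

_MISSING = {"", "NA"}
_MANDATORY = ("id", "date", "time", "species", "number", "station")


class TableFormatError(ValueError):
    """Raised in strict mode on any malformed row or missing column."""


@dataclass
class ReadReport:
    """What the reader accepted and what it had to skip."""

    n_rows: int = 0
    n_accepted: int = 0
    issues: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, key: str, kind: str, message: str) -> None:
        self.issues.append((key, kind, message))


def parse_remark_flags(remark: str) -> dict[str, bool]:
    """Detect observer ``single count`` / ``double count`` flags in a remark."""
    text = (remark or "").lower()
    return {
        "single_count": re.search(r"single\s*count", text) is not None,
        "double_count": re.search(r"double\s*count", text) is not None,
    }


def _opt(value: str) -> Optional[str]:
    return None if value in _MISSING else value


def _parse_row(
    row: dict[str, str], hierarchy: Optional[Hierarchy]
) -> CountRecord:
    try:
        date = dt.date.fromisoformat(row["date"])
    except ValueError as exc:
        raise ValueError(f"unparseable date {row['date']!r}: {exc}") from None
    time_txt = row.get("time", "")
    time = None
    if time_txt not in _MISSING:
        try:
            time = dt.time.fromisoformat(time_txt)
        except ValueError:
            raise ValueError(f"unparseable time {time_txt!r}") from None
    species = row["species"]
    if hierarchy is not None:
        species = hierarchy.resolve(species)
    north_txt = row.get("north", "")
    rec = CountRecord(
        id=int(row["id"]),
        date=date,
        time=time,
        species=species,
        number=int(row["number"]),
        north=int(north_txt) if north_txt not in _MISSING else 0,
        station=int(row["station"]),
        location=_opt(row.get("location", "")),
        age=_opt(row.get("age", "")),
        sex=_opt(row.get("sex", "")),
        morph=_opt(row.get("morph", "")),
        health=_opt(row.get("health", "")),
        remark=row.get("remark", "") if row.get("remark", "") != "NA" else "",
        dcremark=(
            row.get("dcremark", "") if row.get("dcremark", "") != "NA" else ""
        ),
        filter=int(row.get("filter", "1") or 1),
    )
    errs = rec.field_errors()
    if errs:
        raise ValueError("; ".join(errs))
    return rec


def read_count_table(
    source: Union[str, Path, TextIO],
    hierarchy: Optional[Hierarchy] = None,
    strict: bool = False,
) -> tuple[list[CountRecord], ReadReport]:
    """Read a count table; returns accepted records and a read report.

    In strict mode the first violation raises :class:`TableFormatError`;
    otherwise offending rows are skipped and reported.
    """
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(
            source, sep=None, engine="python", dtype=str, keep_default_na=False
        )
    else:
        frame = pd.read_csv(
            source, sep=None, engine="python", dtype=str, keep_default_na=False
        )
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise TableFormatError(f"missing mandatory column(s): {missing}")

    report = ReadReport(n_rows=len(frame))
    records: list[CountRecord] = []
    for row in frame.to_dict("records"):
        key = str(row.get("id", "?"))
        try:
            records.append(_parse_row(row, hierarchy))
        except Exception as exc:  # noqa: BLE001 - every defect becomes an issue
            if strict:
                raise TableFormatError(f"row id={key}: {exc}") from exc
            report.add(key, type(exc).__name__, str(exc))
        else:
            report.n_accepted += 1
    return records, report


def records_to_frame(records: Iterable[CountRecord]) -> pd.DataFrame:
    """Records as a DataFrame in canonical column order (strings for output)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "date": r.date.isoformat(),
                "time": r.time.isoformat() if r.time is not None else "",
                "species": r.species,
                "number": r.number,
                "north": r.north,
                "station": r.station,
                "location": r.location or "",
                "age": r.age or "",
                "sex": r.sex or "",
                "morph": r.morph or "",
                "health": r.health or "",
                "remark": r.remark,
                "dcremark": r.dcremark,
                "filter": r.filter,
            }
        )
    return pd.DataFrame(rows, columns=list(COLUMNS))


def write_count_table(
    records: Sequence[CountRecord],
    destination: Union[str, Path, TextIO],
) -> None:
    """Write records as comma-separated text; round-trips with the reader."""
    frame = records_to_frame(records)
    frame.to_csv(destination, index=False)


def write_count_table_string(records: Sequence[CountRecord]) -> str:
    buf = _io.StringIO()
    write_count_table(records, buf)
    return buf.getvalue()
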