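"""The count-record row type and its enumerated field values.

One record is a group of one or more birds of identical classification
(species/group code, age, sex, morph) passing a station.  A record may be a
solitary bird, a whole flock, or a slice of a larger stream accumulated
over several minutes — ``number`` carries no flock-size meaning.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

ZONES = ("W3", "W2", "W1", "O", "E1", "E2", "E3", "E4")
AGES = ("ad", "imm", "nonjuv", "juv")
SEXES = ("f", "fc", "m")
MORPHS = ("dark", "light", "ful", "mel", "leu")
HEALTH = ("kil", "inj")
FILTERS = (0, 1, 2)
STATIONS = (1, 2)

#: canonical column order of the exchanged CSV tables
COLUMNS = (
    "id", "date", "time", "species", "number", "north", "station",
    "location", "age", "sex", "morph", "health", "remark", "dcremark",
    "filter",
)


@dataclass
class CountRecord:
    """One row of a processed count table."""

    id: int
    date: dt.date
    species: str
    number: int
    station: int
    time: Optional[dt.time] = None
    north: int = 0
    location: Optional[str] = None
    age: Optional[str] = None
    sex: Optional[str] = None
    morph: Optional[str] = None
    health: Optional[str] = None
    remark: str = ""
    dcremark: str = ""
    filter: int = 1

    def copy(self, **changes) -> "CountRecord":
        return replace(self, **changes)

    def field_errors(self) -> list[str]:
        """Schema-level problems of this record (empty list if clean)."""
        errs = []
        if self.number < 1:
            errs.append(f"number must be >= 1, got {self.number}")
        if not 0 <= self.north <= self.number:
            errs.append(f"north must be in [0, number], got {self.north}")
        if self.station not in STATIONS:
            errs.append(f"station must be 1 or 2, got {self.station}")
        if self.location is not None and self.location not in ZONES:
            errs.append(f"location not a distance zone: {self.location!r}")
        if self.age is not None and self.age not in AGES:
            errs.append(f"age not in {AGES}: {self.age!r}")
        if self.sex is not None and self.sex not in SEXES:
            errs.append(f"sex not in {SEXES}: {self.sex!r}")
        if self.morph is not None and self.morph not in MORPHS:
            errs.append(f"morph not in {MORPHS}: {self.morph!r}")
        if self.health is not None and self.health not in HEALTH:
            errs.append(f"health not in {HEALTH}: {self.health!r}")
        if self.filter not in FILTERS:
            errs.append(f"filter must be 0/1/2, got {self.filter}")
        return errs
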