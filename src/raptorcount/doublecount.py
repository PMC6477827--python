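"""Detection and removal of birds recorded by both count stations.

Two hilltop stations watch the same corridor, so a bird passing between
them can enter the data twice.  Candidate double counts are pairs of
records from different stations on the same day whose codes are
taxonomically compatible (species vs. species, or species vs. an ancestor
group), whose entry times differ by at most the detection window of the
size class (+/-10 min small, +/-15 min large species), and whose distance
zones form a configured overlap pair.  Matching is greedy by time gap;
each individual participates in at most one adjustment.  When a pair is
resolved the record with more detail is kept untouched and the partner's
``number`` is reduced, with an audit trail written to both ``dcremark``
fields (``<partner id>:+q`` on the kept record, ``<partner id>:-q`` on the
reduced one).

The procedure is deliberately conservative — it estimates the minimum
number of individuals passing — and idempotent: adjusted records carry a
``dcremark`` link and are excluded from further matching.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import ProtocolConfig
from .records import CountRecord
from .tableio import parse_remark_flags
from .taxonomy import Hierarchy


@dataclass(frozen=True)
class MatchCandidate:
    """A potential double count between one record of each station."""

    id_station1: int
    id_station2: int
    gap_minutes: float
    matched_taxon: str
    quantity: int
    observer_flagged: bool = False


@dataclass
class DedupReport:
    n_candidates: int = 0
    n_individuals_removed: int = 0
    per_species_removed: dict[str, int] = field(default_factory=dict)
    adjustments: list[tuple[int, int, int]] = field(default_factory=list)
    unmatched_flagged: list[int] = field(default_factory=list)
    skipped_no_time: list[int] = field(default_factory=list)
    skipped_no_location: list[int] = field(default_factory=list)


def detail_rank(r: CountRecord, hierarchy: Hierarchy) -> int:
    """Detail score: species-level beats group-level, then attribute count."""
    species_level = 0 if hierarchy.is_group(r.species) else 1
    attrs = sum(x is not None for x in (r.age, r.sex, r.morph))
    return 4 * species_level + attrs


def _gap_minutes(a: dt.time, b: dt.time) -> float:
    da = a.hour * 60 + a.minute + a.second / 60
    db = b.hour * 60 + b.minute + b.second / 60
    return abs(da - db)


def is_candidate_pair(
    a: CountRecord,
    b: CountRecord,
    config: ProtocolConfig,
    hierarchy: Hierarchy,
) -> bool:
    """Whether two records could denote the same birds seen from both hills."""
    if a.station == b.station or a.date != b.date:
        return False
    if a.time is None or b.time is None:
        return False
    if a.location is None or b.location is None:
        return False
    if parse_remark_flags(a.remark)["single_count"]:
        return False
    if parse_remark_flags(b.remark)["single_count"]:
        return False
    if not hierarchy.compatible(a.species, b.species):
        return False
    taxon = hierarchy.more_general(a.species, b.species)
    size = config.size_of(taxon)
    if _gap_minutes(a.time, b.time) > config.window_minutes[size]:
        return False
    s1, s2 = (a, b) if a.station == 1 else (b, a)
    return (s1.location, s2.location) in config.overlap_zones[size]


def _eligible(
    records: Iterable[CountRecord],
    report: DedupReport,
    hierarchy: Hierarchy,
):
    """Records that may enter matching; skips are noted in the report."""
    out = []
    for r in records:
        if r.dcremark:
            continue  # already adjusted in an earlier pass
        if r.species in hierarchy.age_protocol:
            continue  # age-protocol samples are not abundance records
        if r.time is None:
            report.skipped_no_time.append(r.id)
            continue
        if r.location is None:
            report.skipped_no_location.append(r.id)
            continue
        out.append(r)
    return out


def match_records(
    records: Sequence[CountRecord],
    config: ProtocolConfig,
    hierarchy: Hierarchy,
    report: Optional[DedupReport] = None,
) -> list[MatchCandidate]:
    """Greedy chronological matching of cross-station candidate pairs.

    Candidates are resolved in order of (observer ``double count`` flag
    first, then smaller time gap, earlier time, lower record ids); the
    quantity of each resolved pair is the minimum of the individuals still
    unmatched on either side.  Observer-flagged pairs are reported even
    when their remaining quantity is zero.
    """
    report = report if report is not None else DedupReport()
    eligible = _eligible(records, report, hierarchy)
    by_day: dict[dt.date, dict[int, list[CountRecord]]] = defaultdict(
        lambda: {1: [], 2: []}
    )
    for r in eligible:
        by_day[r.date][r.station].append(r)

    raw: list[tuple] = []
    for day, stations in by_day.items():
        for a in stations[1]:
            a_dc = parse_remark_flags(a.remark)["double_count"]
            for b in stations[2]:
                if not is_candidate_pair(a, b, config, hierarchy):
                    continue
                gap = _gap_minutes(a.time, b.time)
                flagged = a_dc or parse_remark_flags(b.remark)["double_count"]
                first = min(
                    (a.time, a.id), (b.time, b.id)
                )
                raw.append((not flagged, gap, first[0], a.id, b.id, a, b))

    raw.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))

    remaining = {r.id: r.number for r in eligible}
    flagged_ids = {
        r.id for r in eligible if parse_remark_flags(r.remark)["double_count"]
    }
    out: list[MatchCandidate] = []
    matched_flagged: set[int] = set()
    for not_flagged, gap, _first, ida, idb, a, b in raw:
        q = min(remaining[ida], remaining[idb])
        flagged = not not_flagged
        if q <= 0 and not flagged:
            continue
        if q <= 0 and flagged and (ida in matched_flagged or idb in matched_flagged):
            continue
        out.append(
            MatchCandidate(
                id_station1=ida,
                id_station2=idb,
                gap_minutes=gap,
                matched_taxon=hierarchy.more_general(a.species, b.species),
                quantity=q,
                observer_flagged=flagged,
            )
        )
        if flagged:
            matched_flagged.update((ida, idb))
        remaining[ida] -= q
        remaining[idb] -= q

    for rid in flagged_ids:
        if rid not in matched_flagged and not any(
            rid in (c.id_station1, c.id_station2) for c in out
        ):
            report.unmatched_flagged.append(rid)
    return out


def apply_matches(
    records: Sequence[CountRecord],
    candidates: Sequence[MatchCandidate],
    hierarchy: Hierarchy,
    report: Optional[DedupReport] = None,
) -> tuple[list[CountRecord], DedupReport]:
    """Subtract matched quantities from the less detailed record of each pair.

    On a rank tie the species-level record wins (already encoded in the
    rank), then the earlier-entered (lower id) record.  Records reduced to
    zero are dropped.  Both partners receive a ``dcremark`` audit entry.
    """
    report = report if report is not None else DedupReport()
    by_id = {r.id: r.copy() for r in records}
    order = [r.id for r in records]

    for cand in candidates:
        report.n_candidates += 1
        if cand.quantity <= 0:
            continue
        a = by_id[cand.id_station1]
        b = by_id[cand.id_station2]
        ra, rb = detail_rank(a, hierarchy), detail_rank(b, hierarchy)
        if ra > rb:
            keep, cut = a, b
        elif rb > ra:
            keep, cut = b, a
        else:
            keep, cut = (a, b) if a.id < b.id else (b, a)
        q = cand.quantity
        if q > cut.number:
            raise RuntimeError(
                f"reduction below zero on record {cut.id} (q={q})"
            )
        cut.number -= q
        cut.north = min(cut.north, cut.number)
        sep_keep = ";" if keep.dcremark else ""
        sep_cut = ";" if cut.dcremark else ""
        keep.dcremark += f"{sep_keep}{cut.id}:+{q}"
        cut.dcremark += f"{sep_cut}{keep.id}:-{q}"
        report.adjustments.append((keep.id, cut.id, q))
        report.n_individuals_removed += q
        report.per_species_removed[cand.matched_taxon] = (
            report.per_species_removed.get(cand.matched_taxon, 0) + q
        )

    out = [by_id[i] for i in order if by_id[i].number > 0]
    return out, report


def remove_double_counts(
    records: Sequence[CountRecord],
    config: ProtocolConfig,
    hierarchy: Hierarchy,
) -> tuple[list[CountRecord], DedupReport]:
    """Full detection + resolution pass.  Idempotent across repeated runs."""
    report = DedupReport()
    candidates = match_records(records, config, hierarchy, report)
    return apply_matches(records, candidates, hierarchy, report)
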