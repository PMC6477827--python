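"""Proportional reallocation of unidentified birds to species level.

Birds that could not be identified to species enter the data under a
morphological-group code.  To estimate daily species totals the group
counts are redistributed over the species of each group's allocation pool,
proportionally to the *running* species totals of the day, iterating
bottom-up through the nested hierarchy.  E.g. a ``Buzzard_SPEC`` count is
split among the buzzards by their identified daily proportions and added
to their totals; the ``MediumRaptor`` count is then split among buzzards
and kites using those already-augmented totals; and so on up to
``Raptor_SPEC``.  Fractions are kept unrounded throughout; rounding is a
reporting decision.

When a group has a count on a day where none of its pool species was
identified, a configurable fallback applies: season-wide pool proportions
(default, keeps conservation), an equal split, or skipping the group (the
remainder is reported as unallocated).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .config import ProtocolConfig
from .records import CountRecord
from .taxonomy import Hierarchy


@dataclass
class DailyTotalsTable:
    """Species x date totals before and after unidentified-bird allocation.

    ``raw_identified`` holds integer sums of identified (species-level)
    records; ``allocated`` additionally contains each species' share of the
    group counts and is generally fractional.  ``unallocated`` maps date ->
    group -> individuals that no fallback could place.
    """

    raw_identified: pd.DataFrame  # index: date, columns: species
    allocated: pd.DataFrame
    unallocated: dict[dt.date, dict[str, float]] = field(default_factory=dict)


def daily_raw_totals(
    records: Iterable[CountRecord],
    hierarchy: Hierarchy,
    filterset: frozenset[int] = frozenset({1}),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum ``number`` per code per date, split into species and group tables.

    Separate-age-protocol records (``HB_JUV`` etc.) sample age structure
    rather than abundance and are excluded.
    """
    rows = [
        (r.date, r.species, r.number)
        for r in records
        if r.filter in filterset and r.species not in hierarchy.age_protocol
    ]
    if not rows:
        empty = pd.DataFrame()
        return empty, empty.copy()
    frame = pd.DataFrame(rows, columns=["date", "code", "number"])
    pivot = frame.pivot_table(
        index="date", columns="code", values="number", aggfunc="sum"
    ).fillna(0.0)
    is_group = [hierarchy.is_group(c) for c in pivot.columns]
    species_tbl = pivot.loc[:, [not g for g in is_group]]
    group_tbl = pivot.loc[:, is_group]
    return species_tbl, group_tbl


def _season_pool_proportions(
    species_tbl: pd.DataFrame, pool: Sequence[str]
) -> Optional[pd.Series]:
    """Season-wide identified proportions within a pool, or None if all zero."""
    present = [s for s in pool if s in species_tbl.columns]
    if not present:
        return None
    totals = species_tbl[present].sum(axis=0)
    if totals.sum() <= 0:
        return None
    return totals / totals.sum()


def allocate_day(
    date: dt.date,
    species_totals: pd.Series,
    group_totals: pd.Series,
    hierarchy: Hierarchy,
    fallback: str = "season_proportions",
    season_species_tbl: Optional[pd.DataFrame] = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Allocate one day's group counts onto the species totals.

    Groups are processed most specific first; each group's count is split
    over its pool proportionally to the running (already augmented)
    species totals.  Returns the augmented series and any unallocated
    remainders.
    """
    running = species_totals.astype(float).copy()
    unallocated: dict[str, float] = {}
    for group in hierarchy.group_order():
        n_g = float(group_totals.get(group, 0.0))
        if n_g <= 0:
            continue
        pool = [s for s in hierarchy.pool(group)]
        for s in pool:
            if s not in running.index:
                running[s] = 0.0
        weights = running[pool]
        total = weights.sum()
        if total > 0:
            running[pool] = weights + n_g * weights / total
            continue
        # degenerate pool: no identified birds of the pool today
        if fallback == "season_proportions" and season_species_tbl is not None:
            props = _season_pool_proportions(season_species_tbl, pool)
            if props is not None:
                for s, p in props.items():
                    running[s] += n_g * p
                continue
        if fallback == "equal_split":
            for s in pool:
                running[s] += n_g / len(pool)
            continue
        unallocated[group] = n_g
    return running, unallocated


def estimate_daily_species_totals(
    records: Iterable[CountRecord],
    config: ProtocolConfig,
    hierarchy: Hierarchy,
    filterset: frozenset[int] = frozenset({1}),
) -> DailyTotalsTable:
    """Daily species totals with and without unidentified-bird allocation."""
    species_tbl, group_tbl = daily_raw_totals(records, hierarchy, filterset)
    if species_tbl.empty and group_tbl.empty:
        return DailyTotalsTable(species_tbl, group_tbl.copy())

    all_dates = sorted(set(species_tbl.index) | set(group_tbl.index))
    all_species = sorted(
        set(species_tbl.columns)
        | {
            s
            for g in group_tbl.columns
            for s in hierarchy.pool(g)
        }
    )
    raw = species_tbl.reindex(
        index=all_dates, columns=all_species, fill_value=0.0
    ).fillna(0.0)

    allocated_rows = {}
    unallocated: dict[dt.date, dict[str, float]] = {}
    for date in all_dates:
        g_row = (
            group_tbl.loc[date]
            if date in group_tbl.index
            else pd.Series(dtype=float)
        )
        alloc, rest = allocate_day(
            date,
            raw.loc[date],
            g_row,
            hierarchy,
            fallback=config.empty_pool_fallback,
            season_species_tbl=raw,
        )
        allocated_rows[date] = alloc
        if rest:
            unallocated[date] = rest
    allocated = pd.DataFrame.from_dict(allocated_rows, orient="index")
    allocated = allocated.reindex(columns=sorted(allocated.columns)).fillna(0.0)
    allocated.index.name = raw.index.name
    return DailyTotalsTable(raw, allocated, unallocated)
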