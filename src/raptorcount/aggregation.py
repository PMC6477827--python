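"""Standardization filtering, annual totals, phenology, and age structure.

The ``filter`` column partitions records into non-standardized (0),
standardized (1), and standardized early-morning (2) observations; most
analyses use filter 1, harrier analyses filter {1, 2}.  Phenology is
summarized by passage quantiles (the earliest date at which the cumulative
season total reaches a fraction q), which also anchor the season window:
three days before the 1% passage date of the earliest priority species to
three days after the 99% passage date of the latest.

Age structure for the three mass species comes exclusively from their
separate age protocols (codes ``HB_JUV``/``HB_NONJUV``...); daily class
proportions scale the (allocated) daily species totals into class totals.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .allocation import DailyTotalsTable
from .config import ProtocolConfig
from .records import CountRecord
from .taxonomy import Hierarchy

#: species whose age structure comes only from the separate age protocol
AGE_PROTOCOL_SPECIES = ("HB", "BlackKite", "StepBuz")


@dataclass(frozen=True)
class SeasonWindow:
    start: dt.date
    end: dt.date
    basis: tuple[tuple[str, float, int], tuple[str, float, int]]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("season window start is after its end")


def round_half_up(x: float) -> int:
    """Round halves away from zero (reporting convention for percentages)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def select_standardized(
    records: Iterable[CountRecord], filter_values: Iterable[int]
) -> list[CountRecord]:
    """Records whose ``filter`` flag is in ``filter_values``."""
    keep = set(filter_values)
    return [r for r in records if r.filter in keep]


def annual_totals(
    daily: pd.DataFrame, year: int, variant: Optional[str] = None
) -> pd.Series:
    """Per-species sums of daily cells within one calendar year.

    ``daily`` may be a date-indexed frame or a :class:`DailyTotalsTable`
    (then ``variant`` selects ``"raw_identified"`` or ``"allocated"``).
    """
    if isinstance(daily, DailyTotalsTable):
        daily = getattr(daily, variant or "allocated")
    mask = [d.year == year for d in daily.index]
    return daily.loc[mask].sum(axis=0)


def passage_quantile(daily: pd.DataFrame, species: str, q: float) -> dt.date:
    """Earliest date whose cumulative total reaches q x season total."""
    if not 0 < q < 1:
        raise ValueError("quantile must be strictly between 0 and 1")
    if isinstance(daily, DailyTotalsTable):
        daily = daily.allocated
    if species not in daily.columns:
        raise KeyError(f"species {species!r} absent from the daily table")
    series = daily[species].sort_index()
    total = series.sum()
    if total <= 0:
        raise ValueError(f"zero season total for {species!r}")
    cumulative = series.cumsum()
    for date, value in cumulative.items():
        if value >= q * total - 1e-9:
            return date
    return series.index[-1]  # pragma: no cover - cumsum always reaches total


def season_window(
    daily: pd.DataFrame, config: ProtocolConfig
) -> SeasonWindow:
    """Season window from the configured start/end quantile rules."""
    start_rule, end_rule = config.season_start, config.season_end
    if isinstance(daily, DailyTotalsTable):
        daily = daily.allocated
    for rule in (start_rule, end_rule):
        if rule.species not in daily.columns or daily[rule.species].sum() <= 0:
            raise ValueError(
                f"season rule species {rule.species!r} missing from totals"
            )
    start = passage_quantile(daily, start_rule.species, start_rule.quantile)
    end = passage_quantile(daily, end_rule.species, end_rule.quantile)
    return SeasonWindow(
        start=start + dt.timedelta(days=start_rule.offset_days),
        end=end + dt.timedelta(days=end_rule.offset_days),
        basis=(
            (start_rule.species, start_rule.quantile, start_rule.offset_days),
            (end_rule.species, end_rule.quantile, end_rule.offset_days),
        ),
    )


def _age_class_of(record: CountRecord, hierarchy: Hierarchy) -> Optional[str]:
    if record.species in hierarchy.age_protocol:
        return "juv" if record.species.endswith("_JUV") else "nonjuv"
    return record.age


def daily_age_counts(
    records: Iterable[CountRecord],
    species: str,
    hierarchy: Hierarchy,
    filterset: frozenset[int] = frozenset({1, 2}),
) -> pd.DataFrame:
    """Aged individuals per date and age class for one species.

    For the mass species with a separate age protocol only the protocol
    codes are used; aged regular records are used for all other species.
    """
    use_protocol = species in AGE_PROTOCOL_SPECIES
    rows = []
    for r in records:
        if r.filter not in filterset:
            continue
        if use_protocol:
            if hierarchy.age_protocol.get(r.species) != species:
                continue
        elif r.species != species or r.age is None:
            continue
        cls = _age_class_of(r, hierarchy)
        if cls is not None:
            rows.append((r.date, cls, r.number))
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(rows, columns=["date", "age", "number"])
    return frame.pivot_table(
        index="date", columns="age", values="number", aggfunc="sum"
    ).fillna(0.0)


def age_proportions(
    records: Iterable[CountRecord],
    species: str,
    hierarchy: Hierarchy,
    date: Optional[dt.date] = None,
    filterset: frozenset[int] = frozenset({1, 2}),
) -> pd.DataFrame | dict[str, float]:
    """Daily age-class fractions among aged birds (sums to 1 per day).

    With ``date`` given, returns that day's mapping (empty dict if no aged
    individuals were recorded that day).
    """
    counts = daily_age_counts(records, species, hierarchy, filterset)
    if counts.empty:
        return {} if date is not None else counts
    fractions = counts.div(counts.sum(axis=1), axis=0)
    if date is not None:
        if date not in fractions.index:
            return {}
        return fractions.loc[date].to_dict()
    return fractions


def age_class_totals(
    species_daily: pd.Series,
    proportions: pd.DataFrame,
    fallback: Optional[Mapping[str, float]] = "season",
    counts: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Daily class totals = species total x class fraction.

    Days without observed proportions use ``fallback``: ``"season"`` pools
    the season's aged individuals (requires ``counts`` or uses the mean of
    daily fractions), a mapping uses fixed fractions, ``None`` leaves the
    day's classes as NaN (flagged for the caller).
    """
    if proportions is None or len(proportions) == 0:
        classes = ["juv", "nonjuv"]
        out = pd.DataFrame(
            float("nan"), index=species_daily.index, columns=classes
        )
        proportions = pd.DataFrame(columns=classes)
    else:
        out = proportions.reindex(index=species_daily.index)
    if isinstance(fallback, str) and fallback == "season":
        if counts is not None and not counts.empty:
            pooled = counts.sum(axis=0)
            season_props = pooled / pooled.sum()
        elif len(proportions):
            season_props = proportions.mean(axis=0)
        else:
            season_props = None
        if season_props is not None:
            for date in out.index[out.isna().all(axis=1)]:
                out.loc[date] = season_props
    elif isinstance(fallback, Mapping):
        for date in out.index[out.isna().all(axis=1)]:
            out.loc[date] = pd.Series(dict(fallback))
    return out.mul(species_daily, axis=0)


def world_population_percentage(
    count: float, pop_low: float, pop_high: float
) -> tuple[int, int]:
    """Count as a (low%, high%) share of a world population bracket.

    The low percentage divides by the high population estimate and vice
    versa; both are rounded to the nearest integer.
    """
    if pop_low <= 0 or pop_high <= 0:
        raise ValueError("population estimates must be positive")
    if pop_low > pop_high:
        raise ValueError("pop_low must not exceed pop_high")
    return (
        round_half_up(100.0 * count / pop_high),
        round_half_up(100.0 * count / pop_low),
    )


def early_morning_addition(
    total_with: float, total_standard: float
) -> int:
    """Percent added by early-morning counts over the standard daily window."""
    if total_standard <= 0:
        raise ValueError("standard total must be positive")
    return round_half_up(
        100.0 * (total_with - total_standard) / total_standard
    )
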