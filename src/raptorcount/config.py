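"""Protocol configuration: windows, overlap geometry, season rules, policies.

All protocol parameters live in a structured YAML file; a packaged default
encodes the standard two-station setup (detection windows of +/-10 min for
small and +/-15 min for large species, the overlap-zone pairs, the
season-window quantile rules, validation policy).  ``load_protocol`` reads
the default and deep-merges an optional user file over it, returning the
taxonomy and the protocol config together.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .taxonomy import Hierarchy

ZonePair = tuple[str, str]


@dataclass(frozen=True)
class SeasonRule:
    species: str
    quantile: float
    offset_days: int


@dataclass(frozen=True)
class DayPeriod:
    start: dt.time
    end: dt.time
    early_morning_start: dt.time


@dataclass(frozen=True)
class ValidationPolicy:
    degrade_lesser_spotted_without_age: bool = False
    rare_flock_threshold: int = 5
    morph_protocol: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"BootedE": ("dark", "light"), "Mar": ("dark",)}
    )


@dataclass(frozen=True)
class ProtocolConfig:
    size_class: Mapping[str, str]          # code -> "small" | "large"
    window_minutes: Mapping[str, int]      # size class -> minutes
    overlap_zones: Mapping[str, frozenset[ZonePair]]
    season_start: SeasonRule
    season_end: SeasonRule
    day_period: DayPeriod
    empty_pool_fallback: str = "season_proportions"
    rounding: str = "half_up"
    validation: ValidationPolicy = field(default_factory=ValidationPolicy)

    def __post_init__(self) -> None:
        if self.window_minutes["small"] > self.window_minutes["large"]:
            raise ValueError("small-species window must not exceed large")
        if not self.overlap_zones["small"] <= self.overlap_zones["large"]:
            raise ValueError("small overlap zones must be a subset of large")
        if self.empty_pool_fallback not in (
            "season_proportions", "skip", "equal_split"
        ):
            raise ValueError(
                f"unknown empty_pool_fallback: {self.empty_pool_fallback!r}"
            )

    def size_of(self, code: str) -> str:
        return self.size_class.get(code, "large")

    def window_for(self, code: str) -> int:
        return self.window_minutes[self.size_of(code)]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def _parse_time(text: str) -> dt.time:
    parts = [int(p) for p in str(text).split(":")]
    return dt.time(*parts)


def _zone_pairs(blocks: list[dict]) -> frozenset[ZonePair]:
    pairs: set[ZonePair] = set()
    for block in blocks:
        for z1 in block["station1"]:
            for z2 in block["station2"]:
                pairs.add((z1, z2))
    return frozenset(pairs)


def _build_hierarchy(tax: dict) -> Hierarchy:
    status = {}
    for level, codes in tax.get("status", {}).items():
        for code in codes:
            status[code] = level
    return Hierarchy(
        parent=dict(tax["parent"]),
        pools={g: tuple(p) for g, p in tax["pools"].items()},
        status=status,
        age_protocol=dict(tax.get("age_protocol", {})),
        extra_species=frozenset(tax.get("ungrouped_species", ())),
    )


def _build_config(proto: dict) -> ProtocolConfig:
    size_class = {code: "small" for code in proto["size_class"]["small"]}
    size_class.update(
        {code: "large" for code in proto["size_class"].get("large", ())}
    )
    rules = proto["season_rules"]
    day = proto["day_period"]
    val = proto.get("validation", {})
    return ProtocolConfig(
        size_class=size_class,
        window_minutes={k: int(v) for k, v in proto["window_minutes"].items()},
        overlap_zones={
            cls: _zone_pairs(blocks)
            for cls, blocks in proto["overlap_zones"].items()
        },
        season_start=SeasonRule(
            rules["start"]["species"],
            float(rules["start"]["quantile"]),
            int(rules["start"]["offset_days"]),
        ),
        season_end=SeasonRule(
            rules["end"]["species"],
            float(rules["end"]["quantile"]),
            int(rules["end"]["offset_days"]),
        ),
        day_period=DayPeriod(
            _parse_time(day["start"]),
            _parse_time(day["end"]),
            _parse_time(day["early_morning_start"]),
        ),
        empty_pool_fallback=proto.get(
            "empty_pool_fallback", "season_proportions"
        ),
        rounding=proto.get("rounding", "half_up"),
        validation=ValidationPolicy(
            degrade_lesser_spotted_without_age=bool(
                val.get("degrade_lesser_spotted_without_age", False)
            ),
            rare_flock_threshold=int(val.get("rare_flock_threshold", 5)),
            morph_protocol={
                sp: tuple(vals)
                for sp, vals in val.get("morph_protocol", {}).items()
            },
        ),
    )


def load_protocol(
    path: Optional[Union[str, Path]] = None,
) -> tuple[Hierarchy, ProtocolConfig]:
    """Load taxonomy + protocol config, merging ``path`` over the default."""
    raw = (
        resources.files("raptorcount")
        .joinpath("data/default_protocol.yml")
        .read_text()
    )
    data = yaml.safe_load(raw)
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        data = _deep_merge(data, override)
    return _build_hierarchy(data["taxonomy"]), _build_config(data["protocol"])
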