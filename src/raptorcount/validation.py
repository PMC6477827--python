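"""Protocol-integrity rules and degradation of under-specified records.

Some identifications are only trusted when they come with supporting
detail: ringtail harriers (Montagu's/Pallid) must carry age information,
and the confusable large eagles cannot be told apart without ageing.
Records that fail such a rule are *degraded* — reclassified to the
designated morphological group (``MonPalHen``, ``LargeEAGLE``) with every
other field kept.  Softer anomalies (a morph on a species without a morph
protocol, a sexed juvenile ringtail, an implausibly large flock of a rare
species) are warnings and never modify data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import ValidationPolicy
from .records import CountRecord
from .taxonomy import Hierarchy

#: registry of rule ids -> human description
RULES = {
    "ringtail-age": "Montagu's/Pallid Harrier record without age information",
    "hen-harrier-age": "Hen Harrier record without age information",
    "large-eagle-age": "confusable large eagle record without age information",
    "large-eagle-age-value": "large eagle with age outside {ad, imm, juv}",
    "morph-protocol": "morph recorded for a species without a morph protocol",
    "juv-male-sex": "sexed juvenile of a species whose juveniles are not sexed",
    "rare-flock": "large flock of a rare (secondary) species",
    "sampling-species-imm": "imm age on a species aged juv/nonjuv only",
}

_RINGTAIL_DEGRADE = {"Mon": "MonPalHen", "Pal": "MonPalHen"}
_EAGLE_DEGRADE = {
    "GreaterSE": "LargeEAGLE",
    "SteppeE": "LargeEAGLE",
    "ImperialE": "LargeEAGLE",
}
_RINGTAILS = ("Mon", "Pal", "Hen", "MonPalHen")
_SAMPLING_SPECIES = ("HB", "BlackKite", "StepBuz")


@dataclass(frozen=True)
class Violation:
    record_id: int
    rule: str
    severity: str  # degrade | warn | reject
    message: str

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unregistered rule id: {self.rule!r}")


@dataclass
class ValidationReport:
    n_in: int = 0
    n_out: int = 0
    n_degraded: int = 0
    n_rejected: int = 0
    violations: list[Violation] = field(default_factory=list)


def _degrade_target(
    r: CountRecord, policy: ValidationPolicy
) -> Optional[str]:
    """Fallback group for a record that fails a degrade rule, else None."""
    if r.age is not None:
        return None
    if r.species in _RINGTAIL_DEGRADE:
        return _RINGTAIL_DEGRADE[r.species]
    if r.species in _EAGLE_DEGRADE:
        return _EAGLE_DEGRADE[r.species]
    if r.species == "LesserSE" and policy.degrade_lesser_spotted_without_age:
        return "LargeEAGLE"
    return None


def check_record(
    r: CountRecord,
    hierarchy: Hierarchy,
    policy: Optional[ValidationPolicy] = None,
) -> list[Violation]:
    """All rule violations triggered by one record."""
    policy = policy or ValidationPolicy()
    out: list[Violation] = []

    def hit(rule: str, severity: str, msg: str) -> None:
        out.append(Violation(r.id, rule, severity, msg))

    if r.age is None and r.species in _RINGTAIL_DEGRADE:
        hit("ringtail-age", "degrade", RULES["ringtail-age"])
    if r.age is None and r.species == "Hen":
        hit("hen-harrier-age", "warn", RULES["hen-harrier-age"])
    if r.age is None and r.species in _EAGLE_DEGRADE:
        hit("large-eagle-age", "degrade", RULES["large-eagle-age"])
    if (
        r.age is None
        and r.species == "LesserSE"
        and policy.degrade_lesser_spotted_without_age
    ):
        hit("large-eagle-age", "degrade", RULES["large-eagle-age"])
    if (
        r.species in ("LesserSE", *_EAGLE_DEGRADE)
        and r.age == "nonjuv"
    ):
        # subadults (5th calendar year) are always recorded as adult, so the
        # juv/nonjuv sampling convention never applies to large eagles
        hit("large-eagle-age-value", "warn", RULES["large-eagle-age-value"])
    if r.morph is not None:
        allowed = policy.morph_protocol.get(r.species, ())
        if r.morph not in allowed:
            hit(
                "morph-protocol",
                "warn",
                f"{RULES['morph-protocol']}: {r.species} morph={r.morph}",
            )
    if r.sex == "m" and r.age == "juv" and r.species in _RINGTAILS:
        hit("juv-male-sex", "warn", RULES["juv-male-sex"])
    if (
        hierarchy.status.get(r.species) == "secondary"
        and r.number > policy.rare_flock_threshold
    ):
        hit(
            "rare-flock",
            "warn",
            f"{RULES['rare-flock']}: {r.species} number={r.number}",
        )
    if r.age == "imm" and r.species in _SAMPLING_SPECIES:
        hit("sampling-species-imm", "warn", RULES["sampling-species-imm"])
    return out


def degrade_record(
    r: CountRecord,
    hierarchy: Hierarchy,
    policy: Optional[ValidationPolicy] = None,
) -> CountRecord:
    """Reclassify an under-specified record to its fallback group.

    Idempotent: records already at group level (or with age present) are
    returned unchanged.  Only the species code changes.
    """
    policy = policy or ValidationPolicy()
    target = _degrade_target(r, policy)
    if target is None:
        return r
    return r.copy(species=hierarchy.resolve(target))


def integrity_pass(
    records: Iterable[CountRecord],
    hierarchy: Hierarchy,
    policy: Optional[ValidationPolicy] = None,
) -> tuple[list[CountRecord], ValidationReport]:
    """Check and degrade every record; warnings never modify data."""
    policy = policy or ValidationPolicy()
    report = ValidationReport()
    out: list[CountRecord] = []
    for r in records:
        report.n_in += 1
        violations = check_record(r, hierarchy, policy)
        report.violations.extend(violations)
        if any(v.severity == "reject" for v in violations):
            report.n_rejected += 1
            continue
        if any(v.severity == "degrade" for v in violations):
            degraded = degrade_record(r, hierarchy, policy)
            if degraded.species != r.species:
                report.n_degraded += 1
            r = degraded
        out.append(r)
    report.n_out = len(out)
    return out, report
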