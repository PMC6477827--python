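"""Protocol-local species codes and the identification hierarchy.

A migration watch records birds under short species abbreviations (``HB``,
``Pal``, ``Mar``, ...) and, when species identification fails, under
morphological-group codes (``MonPalHen``, ``Buzzard_SPEC``,
``Raptor_SPEC``, ...).  Groups nest: a Pallid Harrier sits inside
``MonPalHen``, which sits inside ``Harrier_SPEC``, which sits inside the
root group ``Raptor_SPEC``.  Each group carries an allocation *pool* — the
set of species whose identified daily totals define the proportions used
when the group's count is reallocated to species level.

Separate-age-protocol codes (``HB_JUV``, ``BK_NONJUV``, ...) denote sampled
age subsets of the three most numerous species; for taxonomic queries they
resolve to their parent species but they are never mixed into regular-count
totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping


class UnknownCodeError(KeyError):
    """Raised when a text value is not a known species or group code."""


@dataclass(frozen=True)
class Hierarchy:
    """Immutable identification hierarchy (species, groups, pools, status).

    Parameters
    ----------
    parent
        Child code -> parent group code.  Codes without an entry are roots.
    pools
        Group code -> species-level codes defining its allocation pool.
    status
        Species code -> ``"priority"`` / ``"secondary"``.  Codes missing
        from the map have no monitoring status.
    age_protocol
        Separate-age-protocol code -> the species it samples.
    extra_species
        Species that appear in no group (non-raptor singletons).
    """

    parent: Mapping[str, str]
    pools: Mapping[str, tuple[str, ...]]
    status: Mapping[str, str]
    age_protocol: Mapping[str, str]
    extra_species: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        groups = self.groups
        for g, pool in self.pools.items():
            if not pool:
                raise ValueError(f"group {g!r} has an empty allocation pool")
            for s in pool:
                if s in groups:
                    raise ValueError(
                        f"pool of {g!r} contains group-level code {s!r}"
                    )
        for child, par in self.parent.items():
            if par not in groups:
                raise ValueError(f"parent of {child!r} is unknown group {par!r}")
        for code in self.nodes:
            if code in self.age_protocol:
                continue
            self.ancestors(code)  # raises on a cycle

    # -- membership ------------------------------------------------------

    @property
    def groups(self) -> frozenset[str]:
        """All morphological-group codes (everything that owns a pool)."""
        return frozenset(self.pools)

    @property
    def species(self) -> frozenset[str]:
        """All species-level codes."""
        out = set(self.extra_species)
        for pool in self.pools.values():
            out.update(pool)
        out.update(c for c in self.parent if c not in self.pools)
        return frozenset(out)

    @property
    def nodes(self) -> frozenset[str]:
        return self.species | self.groups | frozenset(self.age_protocol)

    def is_group(self, code: str) -> bool:
        return code in self.pools

    def base_species(self, code: str) -> str:
        """Map an age-protocol code to its parent species; identity otherwise."""
        return self.age_protocol.get(code, code)

    def resolve(self, text: str) -> str:
        """Return the code matching ``text`` (case-sensitive) or raise."""
        if text in self.nodes:
            return text
        raise UnknownCodeError(f"unknown species or group code: {text!r}")

    def pool(self, group: str) -> tuple[str, ...]:
        return self.pools[group]

    # -- structure -------------------------------------------------------

    def ancestors(self, code: str) -> tuple[str, ...]:
        """Group codes above ``code``, most specific first; ``code`` excluded."""
        code = self.base_species(self.resolve(code))
        chain: list[str] = []
        seen = {code}
        cur = code
        while cur in self.parent:
            cur = self.parent[cur]
            if cur in seen:
                raise ValueError(f"cycle in hierarchy at {cur!r}")
            seen.add(cur)
            chain.append(cur)
        return tuple(chain)

    def compatible(self, a: str, b: str) -> bool:
        """True iff ``a`` and ``b`` can denote the same bird.

        Equal codes, a species and one of its ancestor groups, or two nested
        groups are compatible; codes on disjoint branches are not.
        """
        a = self.base_species(self.resolve(a))
        b = self.base_species(self.resolve(b))
        return a == b or a in self.ancestors(b) or b in self.ancestors(a)

    def more_general(self, a: str, b: str) -> str:
        """Of two compatible codes, the one higher in the hierarchy."""
        a = self.base_species(a)
        b = self.base_species(b)
        if a == b:
            return a
        if a in self.ancestors(b):
            return a
        if b in self.ancestors(a):
            return b
        raise ValueError(f"codes {a!r} and {b!r} are not compatible")

    def group_depth(self, group: str) -> int:
        """Number of group ancestors above ``group`` (root groups -> 0)."""
        return len(self.ancestors(group))

    def group_order(self) -> tuple[str, ...]:
        """Groups sorted most specific first (children before their parents)."""
        return tuple(
            sorted(self.groups, key=lambda g: (-self.group_depth(g), g))
        )


# Spec-level operation aliases -------------------------------------------

def resolve_code(text: str, hierarchy: Hierarchy) -> str:
    return hierarchy.resolve(text)


def ancestors(code: str, hierarchy: Hierarchy) -> tuple[str, ...]:
    return hierarchy.ancestors(code)


def taxon_compatible(a: str, b: str, hierarchy: Hierarchy) -> bool:
    return hierarchy.compatible(a, b)
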