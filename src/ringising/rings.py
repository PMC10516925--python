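"""Ring combinatorics for six-subunit oligomers.

A hexamer ring carries one binary label per subunit: a conformational
state (exposed ``+1`` / buried ``-1``) or a phosphorylation label
(AA ``0`` / EE ``1``).  The 2^6 = 64 labelled rings collapse into
symmetry classes once the absolute orientation of the ring is
discarded.  Conformational patterns are reduced under the full
dihedral symmetry of the ring (rotations and reflections), which
yields 13 classes; phosphorylation arrangements are reduced under
rotations only, which yields 14 classes.  Both groups are exposed so
either reduction can be applied to either labelling.

Class counts are independently checkable with Burnside's lemma
(:func:`burnside_count`), which this module's tests use as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import pandas as pd

N_SITES = 6

Config = tuple[int, ...]


def _rotations(n: int) -> list[tuple[int, ...]]:
    return [tuple((i + r) % n for i in range(n)) for r in range(n)]


def _reflections(n: int) -> list[tuple[int, ...]]:
    return [tuple((r - i) % n for i in range(n)) for r in range(n)]


@dataclass(frozen=True)
class SymmetryGroup:
    """A permutation group acting on the ring sites.

    ``elements`` are site permutations ``p``; a permutation acts on a
    configuration ``c`` by ``(p . c)[j] = c[p[j]]``.
    """

    name: str
    elements: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.elements)


ROTATION_GROUP = SymmetryGroup("rotation", tuple(_rotations(N_SITES)))
DIHEDRAL_GROUP = SymmetryGroup(
    "dihedral", tuple(_rotations(N_SITES) + _reflections(N_SITES))
)

_GROUPS = {"rotation": ROTATION_GROUP, "dihedral": DIHEDRAL_GROUP}


def symmetry_group(name: str) -> SymmetryGroup:
    """Look up a group by name (``rotation`` or ``dihedral``)."""
    try:
        return _GROUPS[name]
    except KeyError:
        raise ValueError(
            f"unknown symmetry group {name!r}; expected one of {sorted(_GROUPS)}"
        ) from None


@dataclass(frozen=True)
class ConformationalPattern:
    """A symmetry class of exposed/buried ring configurations.

    Attributes
    ----------
    pattern_id : int
        1-based index; classes are ordered by decreasing number of
        exposed subunits, ties broken by canonical form.
    canonical_form : tuple of int
        Lexicographically minimal member (entries +1/-1).
    omega : int
        Degeneracy: number of raw configurations in the class.
    n_exposed : int
        Number of +1 entries (identical across members).
    members : tuple of configurations
        All ``omega`` configurations in the class.
    """

    pattern_id: int
    canonical_form: Config
    omega: int
    n_exposed: int
    members: tuple[Config, ...]

    @property
    def label(self) -> str:
        return "".join("E" if s == 1 else "B" for s in self.canonical_form)


@dataclass(frozen=True)
class PhosphoArrangement:
    """A rotation class of AA/EE labels around the ring (0 = AA, 1 = EE)."""

    arrangement_id: int
    sigma: tuple[int, ...]
    multiplicity: int
    ee_count: int
    members: tuple[tuple[int, ...], ...]

    @property
    def label(self) -> str:
        return "".join("E" if s == 1 else "A" for s in self.sigma)


def enumerate_configurations(values: Sequence[int] = (-1, 1)) -> list[Config]:
    """All 64 ordered rings over a binary alphabet, in counting order.

    With the default spin alphabet the first element is the all-buried
    ring ``(-1,)*6`` and site 0 is the most significant digit.
    """
    lo, hi = values
    return [
        tuple(hi if (m >> (N_SITES - 1 - i)) & 1 else lo for i in range(N_SITES))
        for m in range(2**N_SITES)
    ]


def _validate_config(config: Sequence[int]) -> Config:
    c = tuple(config)
    if len(c) != N_SITES:
        raise ValueError(f"ring configuration must have {N_SITES} sites, got {len(c)}")
    return c


def canonicalize(config: Sequence[int], group: SymmetryGroup = DIHEDRAL_GROUP) -> Config:
    """Lexicographically minimal image of ``config`` under the group."""
    c = _validate_config(config)
    return min(tuple(c[p[j]] for j in range(N_SITES)) for p in group.elements)


def orbit(config: Sequence[int], group: SymmetryGroup) -> set[Config]:
    """All distinct images of ``config`` under the group."""
    c = _validate_config(config)
    return {tuple(c[p[j]] for j in range(N_SITES)) for p in group.elements}


def _partition(
    configs: Iterable[Config], group: SymmetryGroup
) -> list[tuple[Config, tuple[Config, ...]]]:
    classes: dict[Config, list[Config]] = {}
    for c in configs:
        classes.setdefault(canonicalize(c, group), []).append(c)
    return [(k, tuple(v)) for k, v in classes.items()]


@lru_cache(maxsize=None)
def build_patterns(group: SymmetryGroup = DIHEDRAL_GROUP) -> tuple[ConformationalPattern, ...]:
    """Partition the 64 spin configurations into conformational patterns.

    Under the dihedral group this gives the 13 patterns with
    degeneracies summing to 64; under rotations only it gives 14.
    Ordering: decreasing exposed count, then lexicographic canonical
    form — which pins the four-exposed classes to EEEEBB before
    EEEBEB before the diametric EEBEEB arrangement.
    """
    parts = _partition(enumerate_configurations(), group)
    parts.sort(key=lambda kv: (-sum(s == 1 for s in kv[0]), kv[0]))
    return tuple(
        ConformationalPattern(
            pattern_id=i + 1,
            canonical_form=canon,
            omega=len(members),
            n_exposed=sum(s == 1 for s in canon),
            members=members,
        )
        for i, (canon, members) in enumerate(parts)
    )


@lru_cache(maxsize=None)
def build_arrangements() -> tuple[PhosphoArrangement, ...]:
    """Partition the 64 AA/EE labelings into the 14 rotation classes.

    Ordered by increasing EE count (all-AA first, all-EE last), ties
    broken lexicographically.
    """
    parts = _partition(enumerate_configurations(values=(0, 1)), ROTATION_GROUP)
    parts.sort(key=lambda kv: (sum(kv[0]), kv[0]))
    return tuple(
        PhosphoArrangement(
            arrangement_id=i + 1,
            sigma=canon,
            multiplicity=len(members),
            ee_count=sum(canon),
            members=members,
        )
        for i, (canon, members) in enumerate(parts)
    )


def _cycle_count(perm: tuple[int, ...]) -> int:
    seen = [False] * len(perm)
    cycles = 0
    for i in range(len(perm)):
        if not seen[i]:
            cycles += 1
            j = i
            while not seen[j]:
                seen[j] = True
                j = perm[j]
    return cycles


def burnside_count(n_states: int, group: SymmetryGroup) -> int:
    """Number of orbits of ``n_states``-ary rings under the group.

    Burnside's lemma: ``(1/|G|) * sum_g n_states**cycles(g)``.  Serves
    as an independent oracle for the class counts produced by orbit
    enumeration.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    total = sum(n_states ** _cycle_count(p) for p in group.elements)
    assert total % len(group) == 0
    return total // len(group)


def patterns_to_frame(patterns: Sequence[ConformationalPattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern_id": [p.pattern_id for p in patterns],
            "canonical_form": [p.label for p in patterns],
            "omega": [p.omega for p in patterns],
            "n_exposed": [p.n_exposed for p in patterns],
        }
    )


def arrangements_to_frame(arrangements: Sequence[PhosphoArrangement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "arrangement_id": [a.arrangement_id for a in arrangements],
            "sigma": [a.label for a in arrangements],
            "multiplicity": [a.multiplicity for a in arrangements],
            "n_EE": [a.ee_count for a in arrangements],
        }
    )
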