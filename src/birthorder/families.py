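"""Core containers for family disease data.

The unit of analysis is the *sibship*: the ordered offspring of one
nuclear family, each carrying a binary affection status. A
:class:`FamilyCollection` bundles many sibships; every statistic in
:mod:`birthorder.stats` aggregates over a collection, and the permutation
null is obtained by shuffling affection status *within* each sibship,
which preserves sibship sizes and per-family affected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class Offspring:
    """One child in a sibship.

    Parameters
    ----------
    individual_id
        Opaque identifier, unique within the family.
    birth_rank
        Position in the birth order, 1 = first-born.
    affected
        Binary disease status.
    sex
        ``"male"``, ``"female"`` or ``"unknown"``.
    birth_year
        Calendar year of birth, if known. Used to derive birth ranks and
        to detect twins (identical years).
    paternal_age_at_birth, maternal_age_at_birth
        Parental age in years at this child's birth, if known.
    twin_group
        Label shared by members of an explicitly flagged twin set.
    """

    individual_id: str
    birth_rank: int
    affected: bool
    sex: str = "unknown"
    birth_year: Optional[int] = None
    paternal_age_at_birth: Optional[float] = None
    maternal_age_at_birth: Optional[float] = None
    twin_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.birth_rank < 1:
            raise ValueError(f"birth_rank must be >= 1, got {self.birth_rank}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class Sibship:
    """The ordered offspring of one nuclear family.

    Offspring are stored sorted by ``birth_rank``; ranks must be unique
    within the sibship. After study filtering
    (:func:`birthorder.pedigree_io.filter_collection`) ranks are exactly
    ``1..N`` with no gaps and ``N >= 2``.
    """

    family_id: str
    offspring: tuple[Offspring, ...]
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    def __post_init__(self) -> None:
        kids = tuple(sorted(self.offspring, key=lambda o: o.birth_rank))
        object.__setattr__(self, "offspring", kids)
        ranks = [o.birth_rank for o in kids]
        if len(set(ranks)) != len(ranks):
            raise ValueError(
                f"family {self.family_id}: duplicate birth ranks {ranks}"
            )
        if not kids:
            raise ValueError(f"family {self.family_id}: empty sibship")

    @property
    def size(self) -> int:
        return len(self.offspring)

    @property
    def n_affected(self) -> int:
        return sum(o.affected for o in self.offspring)

    @property
    def ranks(self) -> np.ndarray:
        return np.array([o.birth_rank for o in self.offspring], dtype=np.int64)

    @property
    def affected_vector(self) -> np.ndarray:
        return np.array([o.affected for o in self.offspring], dtype=bool)

    @property
    def has_canonical_ranks(self) -> bool:
        """True when ranks are exactly 1..N (the post-filter invariant)."""
        return [o.birth_rank for o in self.offspring] == list(
            range(1, self.size + 1)
        )

    def with_affected(self, affected: Sequence[bool]) -> "Sibship":
        """Copy of this sibship with a new affection vector (same order)."""
        if len(affected) != self.size:
            raise ValueError("affection vector length mismatch")
        kids = tuple(
            replace(o, affected=bool(a)) for o, a in zip(self.offspring, affected)
        )
        return replace(self, offspring=kids)


@dataclass(frozen=True)
class FamilyCollection:
    """A set of sibships analysed together, with a free-text label."""

    sibships: tuple[Sibship, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sibships", tuple(self.sibships))

    def __len__(self) -> int:
        return len(self.sibships)

    def __iter__(self) -> Iterator[Sibship]:
        return iter(self.sibships)

    @property
    def n_families(self) -> int:
        return len(self.sibships)

    @property
    def n_children(self) -> int:
        return sum(s.size for s in self.sibships)

    @property
    def n_affected(self) -> int:
        return sum(s.n_affected for s in self.sibships)

    @property
    def max_sibship_size(self) -> int:
        return max((s.size for s in self.sibships), default=0)

    def with_sibships(self, sibships: Sequence[Sibship]) -> "FamilyCollection":
        return replace(self, sibships=tuple(sibships))
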