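"""Designs, treatment orderings, loop inconsistency models and their unions.

A *design* is the set of treatments compared within one study.  A *loop
inconsistency model* is derived from a treatment ordering: designs are grouped
by the earliest-ordered treatment they contain, and designs within a group are
assumed to estimate the same relative treatment effects.  The *union* of two
such models is the common refinement of their design partitions.  The union of
the loop models over all orderings is the discrete partition (every design in
its own group), i.e. the design-by-treatment interaction model; this module
verifies that computationally for arbitrary design sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import (
    IncompatiblePartitionsError,
    InvalidNetworkError,
    InvalidOrderingError,
    NotSeparableError,
)

__all__ = [
    "Design",
    "DesignSet",
    "ConsistencyPartition",
    "Ordering",
    "MAX_EXHAUSTIVE_TREATMENTS",
    "enumerate_designs",
    "loop_model",
    "partition_union",
    "union_over_orderings",
    "distinct_orderings",
    "separation_witness",
    "verify_lemma",
    "verify_theorem",
    "discrete_partition",
    "single_group_partition",
    "format_ordering",
    "parse_ordering",
]

#: Refuse exhaustive ordering enumeration above this many treatments unless
#: explicitly overridden (n!/2 grows factorially; 8!/2 = 20160 partitions).
MAX_EXHAUSTIVE_TREATMENTS = 8

#: A treatment ordering: a permutation of the network's treatment labels.
Ordering = tuple[str, ...]


def _validate_treatments(treatments: Iterable[str]) -> frozenset[str]:
    ts = frozenset(treatments)
    if not all(isinstance(t, str) and t and " " not in t for t in ts):
        raise InvalidNetworkError("treatment labels must be nonempty tokens")
    return ts


def _join_labels(labels: Sequence[str]) -> str:
    # Single-letter labels concatenate ("ABD"); longer labels need a separator.
    if all(len(t) == 1 for t in labels):
        return "".join(labels)
    return "+".join(labels)


@dataclass(frozen=True)
class Design:
    """A set of at least two treatment labels identifying a study's arm set."""

    members: frozenset[str]

    def __init__(self, members: Iterable[str]) -> None:
        ms = _validate_treatments(members)
        if len(ms) < 2:
            raise InvalidNetworkError(
                f"a design needs at least 2 treatments, got {sorted(ms)}"
            )
        object.__setattr__(self, "members", ms)

    @classmethod
    def parse(cls, text: str) -> "Design":
        """Parse ``"ABD"``, ``"A+B+D"`` or ``"A,B,D"`` into a design."""
        text = text.strip()
        if "+" in text:
            return cls(text.split("+"))
        if "," in text:
            return cls(part.strip() for part in text.split(","))
        return cls(text)

    @property
    def label(self) -> str:
        """Canonical string form: sorted labels, e.g. ``"ABD"``."""
        return _join_labels(sorted(self.members))

    def __contains__(self, treatment: str) -> bool:
        return treatment in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __lt__(self, other: "Design") -> bool:
        return self.label < other.label

    def __repr__(self) -> str:
        return f"Design({self.label!r})"


@dataclass(frozen=True)
class DesignSet:
    """A set of designs together with the network's treatment set.

    The treatment set defaults to the union of the designs' members but may be
    a declared superset.
    """

    designs: frozenset[Design]
    treatments: frozenset[str]

    def __init__(
        self, designs: Iterable[Design], treatments: Iterable[str] | None = None
    ) -> None:
        ds = frozenset(designs)
        if not ds:
            raise InvalidNetworkError("a design set must be nonempty")
        covered: frozenset[str] = frozenset().union(*(d.members for d in ds))
        ts = covered if treatments is None else _validate_treatments(treatments)
        if not covered <= ts:
            raise InvalidNetworkError(
                f"designs use treatments {sorted(covered - ts)} "
                "outside the declared treatment set"
            )
        object.__setattr__(self, "designs", ds)
        object.__setattr__(self, "treatments", ts)

    def __iter__(self) -> Iterator[Design]:
        return iter(sorted(self.designs))

    def __len__(self) -> int:
        return len(self.designs)

    def __contains__(self, design: Design) -> bool:
        return design in self.designs

    def labels(self) -> list[str]:
        return [d.label for d in self]


def _canonical_groups(
    groups: Iterable[Iterable[Design]],
) -> tuple[tuple[Design, ...], ...]:
    canon = [tuple(sorted(set(g))) for g in groups]
    if any(not g for g in canon):
        raise InvalidNetworkError("partition groups must be nonempty")
    seen: set[Design] = set()
    for g in canon:
        for d in g:
            if d in seen:
                raise InvalidNetworkError(
                    f"design {d.label} appears in more than one group"
                )
            seen.add(d)
    return tuple(sorted(canon, key=lambda g: g[0].label))


@dataclass(frozen=True)
class ConsistencyPartition:
    """A partition of a design set into groups assumed mutually consistent.

    Canonical form: designs sorted within each group, groups sorted by their
    lexicographically smallest design.  Equality and hashing ignore ``source``.
    """

    groups: tuple[tuple[Design, ...], ...]
    source: str | None = field(default=None, compare=False)

    def __init__(
        self, groups: Iterable[Iterable[Design]], source: str | None = None
    ) -> None:
        object.__setattr__(self, "groups", _canonical_groups(groups))
        object.__setattr__(self, "source", source)

    @property
    def designs(self) -> frozenset[Design]:
        return frozenset(d for g in self.groups for d in g)

    @property
    def is_discrete(self) -> bool:
        return all(len(g) == 1 for g in self.groups)

    def group_of(self, design: Design) -> tuple[Design, ...]:
        for g in self.groups:
            if design in g:
                return g
        raise KeyError(design.label)

    def group_index(self, design: Design) -> int:
        for i, g in enumerate(self.groups):
            if design in g:
                return i
        raise KeyError(design.label)

    def refines(self, other: "ConsistencyPartition") -> bool:
        """True if every group here is a subset of some group of ``other``."""
        others = [set(g) for g in other.groups]
        return all(any(set(g) <= og for og in others) for g in self.groups)

    def group_labels(self) -> list[list[str]]:
        return [[d.label for d in g] for g in self.groups]

    def __len__(self) -> int:
        return len(self.groups)

    def __repr__(self) -> str:
        body = "; ".join("{" + ",".join(d.label for d in g) + "}" for g in self.groups)
        return f"ConsistencyPartition({body})"


def format_ordering(ordering: Ordering) -> str:
    return _join_labels(list(ordering))


def parse_ordering(text: str) -> Ordering:
    text = text.strip()
    if "," in text:
        return tuple(part.strip() for part in text.split(","))
    return tuple(text)


def enumerate_designs(treatments: Iterable[str]) -> DesignSet:
    """All subsets of the treatment set with at least two members.

    For ``n`` treatments this yields ``2**n - n - 1`` designs.
    """
    ts = _validate_treatments(treatments)
    if len(ts) < 2:
        raise InvalidNetworkError(
            f"a network needs at least 2 treatments, got {sorted(ts)}"
        )
    ordered = sorted(ts)
    designs = [
        Design(combo)
        for size in range(2, len(ordered) + 1)
        for combo in itertools.combinations(ordered, size)
    ]
    return DesignSet(designs, ts)


def _check_ordering(ordering: Ordering, designs: DesignSet) -> None:
    if len(set(ordering)) != len(ordering):
        raise InvalidOrderingError(f"ordering {ordering} repeats a treatment")
    missing = designs.treatments - set(ordering)
    if missing:
        raise InvalidOrderingError(
            f"ordering {ordering} is missing treatments {sorted(missing)}"
        )
    extra = set(ordering) - designs.treatments
    if extra:
        raise InvalidOrderingError(
            f"ordering {ordering} contains unknown treatments {sorted(extra)}"
        )


def loop_model(ordering: Ordering, designs: DesignSet) -> ConsistencyPartition:
    """The loop inconsistency model induced by a treatment ordering.

    Group *k* collects the designs that contain the *k*-th ordered treatment
    but none of the earlier ones; empty groups are dropped.
    """
    _check_ordering(ordering, designs)
    unassigned = set(designs.designs)
    groups: list[list[Design]] = []
    for treatment in ordering:
        group = [d for d in unassigned if treatment in d]
        if group:
            groups.append(group)
            unassigned -= set(group)
    assert not unassigned
    return ConsistencyPartition(groups, source=f"ordering:{format_ordering(ordering)}")


def partition_union(
    p: ConsistencyPartition, q: ConsistencyPartition
) -> ConsistencyPartition:
    """Common refinement: all nonempty pairwise intersections of groups.

    This is the smallest inconsistency model containing both arguments.
    """
    if p.designs != q.designs:
        raise IncompatiblePartitionsError(
            "partitions cover different design sets"
        )
    groups = []
    for gp in p.groups:
        sp = set(gp)
        for gq in q.groups:
            inter = sp & set(gq)
            if inter:
                groups.append(inter)
    return ConsistencyPartition(groups, source="union")


def union_over_orderings(
    designs: DesignSet, orderings: Sequence[Ordering]
) -> ConsistencyPartition:
    """Left-fold of :func:`partition_union` over the orderings' loop models."""
    if not orderings:
        raise InvalidNetworkError("at least one ordering is required")
    return reduce(partition_union, (loop_model(o, designs) for o in orderings))


def distinct_orderings(
    treatments: Iterable[str], allow_large: bool = False
) -> list[Ordering]:
    """One ordering per distinct loop model: n!/2 representatives.

    Swapping the final two treatments never changes the loop model, so only
    orderings whose last two treatments are in lexicographic order are kept.
    """
    ts = _validate_treatments(treatments)
    n = len(ts)
    if n < 2:
        raise InvalidNetworkError("need at least 2 treatments")
    if n > MAX_EXHAUSTIVE_TREATMENTS and not allow_large:
        raise InvalidNetworkError(
            f"refusing exhaustive enumeration for n={n} > "
            f"{MAX_EXHAUSTIVE_TREATMENTS} treatments (pass allow_large=True)"
        )
    return [
        perm for perm in itertools.permutations(sorted(ts)) if perm[-2] < perm[-1]
    ]


def separation_witness(
    p: Design, q: Design, treatments: Iterable[str]
) -> Ordering:
    """An ordering whose loop model puts ``p`` and ``q`` in different groups.

    Constructive: pick a treatment Z in exactly one of the two designs, order
    Z first and the remaining treatments alphabetically.  The design holding Z
    lands in the first group; the other one cannot.
    """
    ts = _validate_treatments(treatments)
    if not (p.members <= ts and q.members <= ts):
        raise InvalidNetworkError("designs are not subsets of the treatment set")
    if p == q:
        raise NotSeparableError(
            f"design {p.label} is always consistent with itself"
        )
    diff = sorted(p.members - q.members) or sorted(q.members - p.members)
    z = diff[0]
    return (z, *sorted(ts - {z}))


def verify_lemma(designs: DesignSet) -> dict[frozenset[Design], Ordering]:
    """Witness orderings separating every pair of distinct designs.

    Each witness is re-verified by recomputing its loop model; failure would
    indicate an implementation bug and raises.
    """
    if len(designs) < 2:
        raise InvalidNetworkError("need at least 2 designs to form pairs")
    witnesses: dict[frozenset[Design], Ordering] = {}
    for p, q in itertools.combinations(sorted(designs.designs), 2):
        ordering = separation_witness(p, q, designs.treatments)
        model = loop_model(ordering, designs)
        if model.group_index(p) == model.group_index(q):  # pragma: no cover
            raise AssertionError(
                f"witness {ordering} fails to separate {p.label} and {q.label}"
            )
        witnesses[frozenset((p, q))] = ordering
    return witnesses


def verify_theorem(designs: DesignSet, allow_large: bool = False) -> bool:
    """True iff the union of all loop models is the discrete partition."""
    if len(designs) == 1:
        return True
    orderings = distinct_orderings(designs.treatments, allow_large=allow_large)
    union = union_over_orderings(designs, orderings)
    return union.is_discrete


def discrete_partition(designs: DesignSet) -> ConsistencyPartition:
    """Every design in its own group (the design-by-treatment model)."""
    return ConsistencyPartition([[d] for d in designs], source="discrete")


def single_group_partition(designs: DesignSet) -> ConsistencyPartition:
    """All designs in one group (the consistency model)."""
    return ConsistencyPartition([list(designs)], source="consistency")
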