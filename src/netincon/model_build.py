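"""Contrast-level design matrices for consistency and inconsistency models.

Each observed contrast (study x non-baseline treatment) is expressed in terms
of basic effects versus a reference treatment plus group-level inconsistency
offsets shared by all designs in the contrast's partition group.  The offsets
are reduced to an identifiable subset by rank-revealing elimination with a
deterministic column order, which is equivalent in column space to any valid
constraint choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import IncompatibleLayoutError, StructuralError
from .partitions import (
    ConsistencyPartition,
    Design,
    DesignSet,
    _join_labels,
    single_group_partition,
)

__all__ = [
    "StudyLayout",
    "ModelSpec",
    "DesignMatrix",
    "one_study_per_design",
    "build_matrix",
    "inconsistency_df",
    "model_contains",
]


@dataclass(frozen=True)
class StudyLayout:
    """One study's contribution to the contrast layout.

    ``contrasts`` lists the non-baseline treatments; together with the
    baseline they must equal the design's arm set (a study's design is defined
    by the arms actually present).
    """

    study: str
    design: Design
    baseline: str
    contrasts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.baseline not in self.design:
            raise StructuralError(
                f"study {self.study}: baseline {self.baseline} "
                f"not in design {self.design.label}"
            )
        arms = {self.baseline, *self.contrasts}
        if arms != self.design.members:
            raise StructuralError(
                f"study {self.study}: arms {sorted(arms)} do not match "
                f"design {self.design.label}"
            )
        if len(set(self.contrasts)) != len(self.contrasts):
            raise StructuralError(f"study {self.study}: repeated contrast arm")


@dataclass(frozen=True)
class ModelSpec:
    """Identifiable parameterization of an inconsistency model.

    ``basic_effects`` holds the n-1 reference contrasts (reference, J);
    ``inconsistency_params`` holds (group label, (reference, J)) entries, one
    per identifiable inconsistency offset.
    """

    reference: str
    basic_effects: tuple[tuple[str, str], ...]
    inconsistency_params: tuple[tuple[str, tuple[str, str]], ...]
    partition: ConsistencyPartition

    @property
    def n_params(self) -> int:
        return len(self.basic_effects) + len(self.inconsistency_params)

    def parameter_names(self) -> list[str]:
        names = [f"d_{_join_labels([a, j])}" for a, j in self.basic_effects]
        names += [
            f"w_{g}_{_join_labels([a, j])}" for g, (a, j) in self.inconsistency_params
        ]
        return names

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "basic_effects": [list(pair) for pair in self.basic_effects],
            "inconsistency_params": [
                {"group": g, "pair": list(pair)}
                for g, pair in self.inconsistency_params
            ],
            "groups": self.partition.group_labels(),
        }


@dataclass(frozen=True)
class DesignMatrix:
    """Contrast-level design matrix with named columns and rows.

    Rows are (study, baseline, treatment) triples; entries are contrast
    coefficients in {-1, 0, 1}.  The first ``n_basic`` columns form the
    classical network (consistency) design matrix.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    rows: tuple[tuple[str, str, str], ...]
    n_basic: int

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def basic_block(self) -> np.ndarray:
        return self.values[:, : self.n_basic]

    @property
    def omega_block(self) -> np.ndarray:
        return self.values[:, self.n_basic :]

    def to_frame(self):
        import pandas as pd

        index = [f"{s}:{_join_labels([i, j])}" for s, i, j in self.rows]
        return pd.DataFrame(self.values, columns=list(self.columns), index=index)


def one_study_per_design(
    designs: DesignSet, baseline: str | None = None
) -> list[StudyLayout]:
    """Canonical layout with a single study per design.

    The baseline is each design's lexicographically first treatment unless a
    common baseline present in every design is given.
    """
    layout = []
    for k, d in enumerate(designs, start=1):
        b = baseline if baseline is not None and baseline in d else min(d.members)
        rest = tuple(t for t in sorted(d.members) if t != b)
        layout.append(StudyLayout(study=f"s{k}", design=d, baseline=b, contrasts=rest))
    return layout


def _group_label(group: tuple[Design, ...]) -> str:
    return group[0].label


def _rank(matrix: np.ndarray) -> int:
    if matrix.size == 0:
        return 0
    return int(np.linalg.matrix_rank(matrix))


def build_matrix(
    layout: Sequence[StudyLayout],
    partition: ConsistencyPartition,
    reference: str | None = None,
    omega_order: Sequence[int] | None = None,
) -> tuple[ModelSpec, DesignMatrix]:
    """Build the design matrix of the inconsistency model given by a partition.

    Every contrast row expresses the study effect of J versus baseline I as
    (d_AJ - d_AI) + (w_gJ - w_gI), where g is the study design's partition
    group and offsets for the reference treatment are zero.  Candidate
    inconsistency columns are generated per (group, treatment) and greedily
    reduced to an identifiable subset; ``omega_order`` permutes the candidate
    order (any order spans the same column space).

    The single-group partition yields the consistency model; the discrete
    partition yields the full design-by-treatment interaction model.
    """
    if not layout:
        raise StructuralError("empty layout")
    part_designs = partition.designs
    treatments = sorted(frozenset().union(*(d.members for d in part_designs)))
    if reference is None:
        reference = treatments[0]
    if reference not in treatments:
        raise StructuralError(f"reference {reference} not in the network")
    for entry in layout:
        if entry.design not in part_designs:
            raise StructuralError(
                f"study {entry.study}: design {entry.design.label} "
                "absent from the partition"
            )

    basic = tuple((reference, t) for t in treatments if t != reference)
    basic_index = {t: k for k, (_, t) in enumerate(basic)}

    # Candidate inconsistency offsets: one per (group, non-reference treatment
    # occurring in the group), in canonical deterministic order.
    candidates: list[tuple[str, tuple[str, str]]] = []
    for group in partition.groups:
        label = _group_label(group)
        group_treatments = sorted(frozenset().union(*(d.members for d in group)))
        for t in group_treatments:
            if t != reference:
                candidates.append((label, (reference, t)))
    cand_index = {key: k for k, key in enumerate(candidates)}

    rows: list[tuple[str, str, str]] = []
    X_basic = np.zeros((0, len(basic)))
    X_cand = np.zeros((0, len(candidates)))
    basic_rows = []
    cand_rows = []
    group_of_design = {d: _group_label(g) for g in partition.groups for d in g}
    for entry in layout:
        glabel = group_of_design[entry.design]
        for j in entry.contrasts:
            rows.append((entry.study, entry.baseline, j))
            brow = np.zeros(len(basic))
            crow = np.zeros(len(candidates))
            if j != reference:
                brow[basic_index[j]] = 1.0
                crow[cand_index[(glabel, (reference, j))]] = 1.0
            if entry.baseline != reference:
                brow[basic_index[entry.baseline]] = -1.0
                crow[cand_index[(glabel, (reference, entry.baseline))]] = -1.0
            basic_rows.append(brow)
            cand_rows.append(crow)
    X_basic = np.array(basic_rows)
    X_cand = np.array(cand_rows)

    order = list(range(len(candidates))) if omega_order is None else list(omega_order)
    if sorted(order) != list(range(len(candidates))):
        raise StructuralError(
            f"omega_order must be a permutation of range({len(candidates)})"
        )

    kept: list[int] = []
    current = X_basic
    rank = _rank(current)
    for k in order:
        trial = np.column_stack([current, X_cand[:, k]])
        trial_rank = _rank(trial)
        if trial_rank > rank:
            kept.append(k)
            current = trial
            rank = trial_rank
    kept.sort()

    spec = ModelSpec(
        reference=reference,
        basic_effects=basic,
        inconsistency_params=tuple(candidates[k] for k in kept),
        partition=partition,
    )
    values = np.column_stack([X_basic, X_cand[:, kept]]) if kept else X_basic
    matrix = DesignMatrix(
        values=values,
        columns=tuple(spec.parameter_names()),
        rows=tuple(rows),
        n_basic=len(basic),
    )
    return spec, matrix


def inconsistency_df(
    designs: DesignSet,
    partition: ConsistencyPartition,
    layout: Sequence[StudyLayout] | None = None,
) -> int:
    """Inconsistency degrees of freedom: rank(full) - rank(consistency).

    Computed on a one-study-per-design layout unless one is supplied.  Zero
    for the single-group partition, maximal for the discrete partition.
    """
    if partition.designs != designs.designs:
        raise StructuralError("partition does not cover the design set")
    if layout is None:
        layout = one_study_per_design(designs)
    _, full = build_matrix(layout, partition)
    _, cons = build_matrix(layout, single_group_partition(designs))
    return _rank(full.values) - _rank(cons.values)


def model_contains(outer: DesignMatrix, inner: DesignMatrix) -> bool:
    """True iff every column of ``inner`` lies in the column space of ``outer``."""
    if outer.rows != inner.rows:
        raise IncompatibleLayoutError(
            "matrices were built on different contrast layouts"
        )
    stacked = np.column_stack([outer.values, inner.values])
    return _rank(stacked) == _rank(outer.values)
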