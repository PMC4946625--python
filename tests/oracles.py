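"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths wherever the quantity
being checked has a simpler, slower definition.
"""

from __future__ import annotations

import itertools

import numpy as np

from netincon.partitions import ConsistencyPartition, Design, DesignSet


def all_loop_models_brute(designs: DesignSet) -> list[dict[Design, int]]:
    """Group index per design for every one of the n! orderings.

    Reimplements grouping directly from the ordering definition (first listed
    treatment a design contains), independent of ``loop_model``.
    """
    models = []
    for perm in itertools.permutations(sorted(designs.treatments)):
        pos = {t: i for i, t in enumerate(perm)}
        models.append({d: min(pos[t] for t in d.members) for d in designs.designs})
    return models


def separable_brute(p: Design, q: Design, models: list[dict[Design, int]]) -> bool:
    """True iff some loop model puts p and q in different groups."""
    return any(m[p] != m[q] for m in models)


def union_partition_brute(designs: DesignSet) -> list[frozenset[Design]]:
    """Partition by 'same group in every loop model' equivalence."""
    models = all_loop_models_brute(designs)
    ds = sorted(designs.designs)
    groups: list[list[Design]] = []
    for d in ds:
        for g in groups:
            if all(m[d] == m[g[0]] for m in models):
                g.append(d)
                break
        else:
            groups.append([d])
    return [frozenset(g) for g in groups]


def arm_difference_matrix(rows, treatments: list[str]) -> np.ndarray:
    """Rows of (study, baseline, treatment): +1 at treatment, -1 at baseline.

    Uses one column per treatment (no reference reduction); its rank equals
    the rank of any reduced consistency parameterization on a connected
    network component containing the reference.
    """
    index = {t: k for k, t in enumerate(treatments)}
    X = np.zeros((len(rows), len(treatments)))
    for r, (_, baseline, treatment) in enumerate(rows):
        X[r, index[treatment]] += 1.0
        X[r, index[baseline]] -= 1.0
    return X


def partition_model_rank(layout, partition: ConsistencyPartition) -> int:
    """Rank of the partition model: each group fits its own network matrix."""
    treatments = sorted(
        frozenset().union(*(d.members for d in partition.designs))
    )
    total = 0
    for group in partition.groups:
        rows = [
            (entry.study, entry.baseline, t)
            for entry in layout
            if entry.design in group
            for t in entry.contrasts
        ]
        if rows:
            total += int(np.linalg.matrix_rank(arm_difference_matrix(rows, treatments)))
    return total


def inconsistency_df_oracle(layout, partition: ConsistencyPartition) -> int:
    """Rank(partition model) - rank(single consistent network)."""
    treatments = sorted(
        frozenset().union(*(d.members for d in partition.designs))
    )
    rows = [
        (entry.study, entry.baseline, t)
        for entry in layout
        for t in entry.contrasts
    ]
    consistency_rank = int(
        np.linalg.matrix_rank(arm_difference_matrix(rows, treatments))
    )
    return partition_model_rank(layout, partition) - consistency_rank


def colspace_equal(a: np.ndarray, b: np.ndarray) -> bool:
    ra = np.linalg.matrix_rank(a)
    rb = np.linalg.matrix_rank(b)
    return ra == rb == np.linalg.matrix_rank(np.column_stack([a, b]))


def random_design_subset(rng: np.random.Generator, n: int, k: int) -> DesignSet:
    """k random distinct designs over the first n letters."""
    letters = [chr(ord("A") + i) for i in range(n)]
    full = [
        frozenset(combo)
        for size in range(2, n + 1)
        for combo in itertools.combinations(letters, size)
    ]
    picks = rng.choice(len(full), size=min(k, len(full)), replace=False)
    return DesignSet([Design(full[int(i)]) for i in picks])


def random_partition(
    rng: np.random.Generator, designs: DesignSet, n_groups: int
) -> ConsistencyPartition:
    ds = sorted(designs.designs)
    labels = rng.integers(0, n_groups, size=len(ds))
    groups: dict[int, list[Design]] = {}
    for d, g in zip(ds, labels):
        groups.setdefault(int(g), []).append(d)
    return ConsistencyPartition(list(groups.values()))
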