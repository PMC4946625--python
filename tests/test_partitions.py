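import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netincon.errors import (
    IncompatiblePartitionsError,
    InvalidNetworkError,
    InvalidOrderingError,
    NotSeparableError,
)
from netincon.partitions import (
    ConsistencyPartition,
    Design,
    DesignSet,
    discrete_partition,
    distinct_orderings,
    enumerate_designs,
    loop_model,
    partition_union,
    separation_witness,
    single_group_partition,
    union_over_orderings,
    verify_lemma,
    verify_theorem,
)
from conftest import designs
from oracles import (
    all_loop_models_brute,
    separable_brute,
    union_partition_brute,
)


def groups_of(partition: ConsistencyPartition) -> set[frozenset[str]]:
    return {frozenset(d.label for d in g) for g in partition.groups}


class TestDesign:
    def test_canonical_label_sorts_members(self):
        assert Design("DBA").label == "ABD"
        assert Design.parse("B,A").label == "AB"

    def test_rejects_singletons(self):
        with pytest.raises(InvalidNetworkError):
            Design("A")

    def test_equality_is_set_equality(self):
        assert Design("AB") == Design("BA")
        assert len({Design("AB"), Design("BA")}) == 1


class TestEnumerateDesigns:
    def test_full_t_n4_matches_listing(self, full_t4):
        expected = {"AB", "AC", "AD", "BC", "BD", "CD",
                    "ABC", "ABD", "ACD", "BCD", "ABCD"}
        assert set(full_t4.labels()) == expected

    def test_two_treatments(self):
        assert enumerate_designs("AB").labels() == ["AB"]

    def test_n5_count(self):
        assert len(enumerate_designs("ABCDE")) == 2**5 - 5 - 1 == 26

    @pytest.mark.parametrize("n", range(2, 8))
    def test_count_formula(self, n):
        labels = [chr(ord("A") + i) for i in range(n)]
        assert len(enumerate_designs(labels)) == 2**n - n - 1

    def test_single_treatment_rejected(self):
        with pytest.raises(InvalidNetworkError):
            enumerate_designs("A")


class TestLoopModel:
    def test_cbda_reproduces_three_groups(self, full_t4):
        p = loop_model(tuple("CBDA"), full_t4)
        assert groups_of(p) == {
            frozenset({"AC", "BC", "CD", "ABC", "ACD", "BCD", "ABCD"}),
            frozenset({"AB", "BD", "ABD"}),
            frozenset({"AD"}),
        }
        assert p.source == "ordering:CBDA"

    def test_abcd_reproduces_three_groups(self, full_t4):
        p = loop_model(tuple("ABCD"), full_t4)
        assert groups_of(p) == {
            frozenset({"AB", "AC", "AD", "ABC", "ABD", "ACD", "ABCD"}),
            frozenset({"BC", "BD", "BCD"}),
            frozenset({"CD"}),
        }

    def test_single_design(self):
        p = loop_model(("A", "B"), designs("AB"))
        assert groups_of(p) == {frozenset({"AB"})}

    def test_missing_treatment_rejected(self, full_t4):
        with pytest.raises(InvalidOrderingError):
            loop_model(("A", "B", "C"), full_t4)

    def test_repeated_treatment_rejected(self, full_t4):
        with pytest.raises(InvalidOrderingError):
            loop_model(("A", "B", "C", "C"), full_t4)

    def test_at_most_n_minus_1_groups_on_full_t(self):
        for n in range(2, 6):
            labels = [chr(ord("A") + i) for i in range(n)]
            ds = enumerate_designs(labels)
            for ordering in distinct_orderings(labels):
                assert len(loop_model(ordering, ds)) <= n - 1

    def test_group_count_equals_earliest_member_count(self, full_t4):
        ordering = tuple("DCBA")
        p = loop_model(ordering, full_t4)
        pos = {t: i for i, t in enumerate(ordering)}
        earliest = {min(d.members, key=pos.__getitem__) for d in full_t4.designs}
        assert len(p) == len(earliest)


class TestPartitionUnion:
    def test_l1_union_l2_reproduces_six_groups(self, full_t4):
        l1 = loop_model(tuple("CBDA"), full_t4)
        l2 = loop_model(tuple("ABCD"), full_t4)
        u = partition_union(l1, l2)
        assert groups_of(u) == {
            frozenset({"AC", "ABC", "ACD", "ABCD"}),
            frozenset({"BC", "BCD"}),
            frozenset({"CD"}),
            frozenset({"AB", "ABD"}),
            frozenset({"BD"}),
            frozenset({"AD"}),
        }

    def test_idempotent(self, full_t4):
        p = loop_model(tuple("BDCA"), full_t4)
        assert partition_union(p, p) == p

    def test_coarsest_partition_is_identity(self, full_t4):
        p = loop_model(tuple("CBDA"), full_t4)
        top = single_group_partition(full_t4)
        assert partition_union(p, top) == p
        assert partition_union(top, p) == p

    def test_mismatched_design_sets_rejected(self, full_t4, triangle):
        with pytest.raises(IncompatiblePartitionsError):
            partition_union(
                discrete_partition(full_t4), discrete_partition(triangle)
            )


class TestUnionOverOrderings:
    def test_all_orderings_n4_gives_singletons(self, full_t4):
        u = union_over_orderings(full_t4, distinct_orderings("ABCD"))
        assert u.is_discrete and len(u) == 11

    def test_matches_brute_force_equivalence(self, full_t4):
        u = union_over_orderings(full_t4, distinct_orderings("ABCD"))
        brute = {
            frozenset(d.label for d in g) for g in union_partition_brute(full_t4)
        }
        assert groups_of(u) == brute

    def test_observed_n3_subset(self):
        ds = designs("AB", "AC", "BC", "ABC")
        u = union_over_orderings(ds, distinct_orderings("ABC"))
        assert u.is_discrete and len(u) == 4

    def test_single_design(self):
        ds = designs("AB")
        u = union_over_orderings(ds, [("A", "B"), ("B", "A")])
        assert groups_of(u) == {frozenset({"AB"})}

    def test_empty_ordering_list_rejected(self, full_t4):
        with pytest.raises(InvalidNetworkError):
            union_over_orderings(full_t4, [])

    def test_fold_order_does_not_matter(self, full_t4):
        orderings = distinct_orderings("ABCD")
        forward = union_over_orderings(full_t4, orderings)
        backward = union_over_orderings(full_t4, orderings[::-1])
        assert forward == backward


class TestDistinctOrderings:
    @pytest.mark.parametrize(
        "labels,count", [("ABCD", 12), ("AB", 1), ("ABC", 3)]
    )
    def test_counts(self, labels, count):
        orderings = distinct_orderings(labels)
        assert len(orderings) == count
        assert len(set(orderings)) == count

    def test_omitted_orderings_duplicate_partitions(self, full_t4):
        kept = {
            loop_model(o, full_t4) for o in distinct_orderings("ABCD")
        }
        assert len(kept) == 12
        everything = {
            loop_model(o, full_t4) for o in itertools.permutations("ABCD")
        }
        assert everything == kept

    def test_n3_partitions_all_distinct_on_full_t(self):
        ds = enumerate_designs("ABC")
        models = {loop_model(o, ds) for o in distinct_orderings("ABC")}
        assert len(models) == 3

    def test_refuses_large_n_without_override(self):
        labels = [chr(ord("A") + i) for i in range(9)]
        with pytest.raises(InvalidNetworkError):
            distinct_orderings(labels)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_last_two_swap_invariance_exhaustive(self, n):
        labels = [chr(ord("A") + i) for i in range(n)]
        ds = enumerate_designs(labels)
        for perm in itertools.permutations(labels):
            swapped = perm[:-2] + (perm[-1], perm[-2])
            assert loop_model(perm, ds) == loop_model(swapped, ds)


class TestSeparationWitness:
    def test_abd_vs_bc(self):
        w = separation_witness(Design("ABD"), Design("BC"), "ABCD")
        assert w == ("A", "B", "C", "D")
        ds = enumerate_designs("ABCD")
        m = loop_model(w, ds)
        assert m.group_index(Design("ABD")) != m.group_index(Design("BC"))

    def test_subset_case_cd_vs_bcd(self):
        w = separation_witness(Design("CD"), Design("BCD"), "ABCD")
        assert w == ("B", "A", "C", "D")
        m = loop_model(w, enumerate_designs("ABCD"))
        assert m.group_index(Design("CD")) != m.group_index(Design("BCD"))

    def test_identical_designs_rejected(self):
        with pytest.raises(NotSeparableError):
            separation_witness(Design("AB"), Design("AB"), "ABCD")


class TestVerifyLemma:
    def test_n3_exhaustive(self):
        witnesses = verify_lemma(enumerate_designs("ABC"))
        assert len(witnesses) == 4 * 3 // 2 == 6

    def test_n4_exhaustive(self, full_t4):
        witnesses = verify_lemma(full_t4)
        assert len(witnesses) == 11 * 10 // 2 == 55

    def test_disjoint_pair(self):
        ds = designs("AB", "CD")
        witnesses = verify_lemma(ds)
        (ordering,) = witnesses.values()
        m = loop_model(ordering, ds)
        assert len(m) == 2

    def test_witness_agrees_with_brute_force_n3(self):
        ds = enumerate_designs("ABC")
        models = all_loop_models_brute(ds)
        for pair in verify_lemma(ds):
            p, q = sorted(pair)
            assert separable_brute(p, q, models)


class TestVerifyTheorem:
    def test_full_t_n4(self, full_t4):
        assert verify_theorem(full_t4)

    def test_single_design(self):
        assert verify_theorem(designs("ABC"))

    def test_random_observed_subsets_n5(self):
        rng = np.random.default_rng(20)
        from oracles import random_design_subset

        for _ in range(20):
            ds = random_design_subset(rng, 5, int(rng.integers(2, 12)))
            assert verify_theorem(ds)


# --- property tests -------------------------------------------------------

letters = st.sampled_from("ABCDE")


@st.composite
def design_sets(draw):
    n = draw(st.integers(3, 5))
    labels = [chr(ord("A") + i) for i in range(n)]
    universe = [
        frozenset(c)
        for size in range(2, n + 1)
        for c in itertools.combinations(labels, size)
    ]
    picked = draw(
        st.lists(st.sampled_from(universe), min_size=1, max_size=8, unique=True)
    )
    return DesignSet([Design(m) for m in picked])


@st.composite
def orderings_of(draw, ds):
    return tuple(draw(st.permutations(sorted(ds.treatments))))


@st.composite
def design_set_with_orderings(draw, k=2):
    ds = draw(design_sets())
    orderings = [draw(orderings_of(ds)) for _ in range(k)]
    return ds, orderings


@st.composite
def random_partitions_pair(draw):
    ds = draw(design_sets())
    items = sorted(ds.designs)

    def one():
        labels = [draw(st.integers(0, len(items) - 1)) for _ in items]
        groups: dict[int, list[Design]] = {}
        for d, g in zip(items, labels):
            groups.setdefault(g, []).append(d)
        return ConsistencyPartition(list(groups.values()))

    return one(), one(), one()


@settings(max_examples=60, deadline=None)
@given(design_set_with_orderings())
def test_partition_laws_hold_on_loop_models(ds_orderings):
    ds, orderings = ds_orderings
    for ordering in orderings:
        p = loop_model(ordering, ds)
        all_designs = [d for g in p.groups for d in g]
        assert len(all_designs) == len(set(all_designs)) == len(ds)
        assert set(all_designs) == set(ds.designs)
        assert all(g for g in p.groups)


@settings(max_examples=60, deadline=None)
@given(design_set_with_orderings())
def test_union_refines_both_arguments(ds_orderings):
    ds, (o1, o2) = ds_orderings
    p, q = loop_model(o1, ds), loop_model(o2, ds)
    u = partition_union(p, q)
    assert u.refines(p) and u.refines(q)


@settings(max_examples=40, deadline=None)
@given(random_partitions_pair())
def test_union_algebra_on_random_partitions(triple):
    p, q, r = triple
    assert partition_union(p, p) == p
    assert partition_union(p, q) == partition_union(q, p)
    assert partition_union(partition_union(p, q), r) == partition_union(
        p, partition_union(q, r)
    )


@settings(max_examples=25, deadline=None)
@given(design_sets())
def test_theorem_on_random_design_sets(ds):
    assert verify_theorem(ds)


@settings(max_examples=25, deadline=None)
@given(design_sets())
def test_lemma_on_random_design_sets(ds):
    if len(ds) < 2:
        return
    models = all_loop_models_brute(ds)
    for pair, ordering in verify_lemma(ds).items():
        p, q = sorted(pair)
        assert separable_brute(p, q, models)
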