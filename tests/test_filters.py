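import random
from itertools import combinations

import pytest

from kmerphylo.filters import (
    FilterConfig,
    apply_filter,
    compatible,
    filter_2tree,
    filter_strict,
    filter_topx,
    filter_weakly,
    two_tree_bins,
    weakly_compatible_triple,
)
from kmerphylo.splits import Split, canonical_side
from conftest import make_system, random_compatible_sides, taxa_for
from oracles import (
    audit_pairwise_compatible,
    audit_weakly_compatible,
    oracle_compatible,
    oracle_weak_triple,
    sides_as_sets,
)


def split(side: int, n: int) -> Split:
    return Split(side=canonical_side(side, n), n=n)


def mask(indices, n):
    m = 0
    for i in indices:
        m |= 1 << i
    return m


def all_splits_system(n: int, rng: random.Random):
    """Every bipartition of n taxa with distinct random weights."""
    sides = {canonical_side(p, n) for p in range(1, (1 << n) - 1)}
    weights = rng.sample(range(1, 10 * len(sides)), len(sides))
    return make_system(taxa_for(n), {s: float(w) for s, w in zip(sorted(sides), weights)})


class TestCompatible:
    def test_trivial_always_compatible(self):
        n = 4
        assert compatible(split(mask([0], n), n), split(mask([1], n), n))

    def test_crossing_quartet_incompatible(self):
        n = 4
        assert not compatible(split(mask([0, 1], n), n), split(mask([0, 2], n), n))

    def test_nested_compatible(self):
        n = 5
        assert compatible(split(mask([0, 1], n), n), split(mask([0, 1, 2], n), n))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_set_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 8)
        s1 = split(rng.randint(1, (1 << n) - 2), n)
        s2 = split(rng.randint(1, (1 << n) - 2), n)
        expected = oracle_compatible(
            frozenset(s1.indices()), frozenset(s2.indices()), n
        )
        assert compatible(s1, s2) == expected
        assert compatible(s2, s1) == expected  # symmetric


class TestWeaklyCompatibleTriple:
    def test_pairwise_compatible_triple_is_weak(self):
        n = 5
        s = [split(mask([0, 1], n), n), split(mask([0, 1, 2], n), n), split(mask([4], n), n)]
        assert weakly_compatible_triple(*s)

    def test_d_split_configuration(self):
        n = 6
        s1 = split(mask([0, 1], n), n)
        s2 = split(mask([1, 2], n), n)
        s3 = split(mask([0, 2], n), n)
        expected = oracle_weak_triple(
            frozenset(s1.indices()), frozenset(s2.indices()), frozenset(s3.indices()), n
        )
        assert weakly_compatible_triple(s1, s2, s3) == expected

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_orientation_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        triple = [split(rng.randint(1, (1 << n) - 2), n) for _ in range(3)]
        expected = oracle_weak_triple(
            *[frozenset(s.indices()) for s in triple], n
        )
        for perm in [(0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            assert (
                weakly_compatible_triple(*(triple[i] for i in perm)) == expected
            )


class TestFilterTopx:
    def test_zero(self):
        system = all_splits_system(4, random.Random(0))
        assert len(filter_topx(system, 0)) == 0

    def test_exceeding_size_is_identity(self):
        system = all_splits_system(4, random.Random(0))
        assert filter_topx(system, 1000).splits == system.splits

    def test_takes_highest_weighting(self):
        system = all_splits_system(5, random.Random(1))
        top = filter_topx(system, 3)
        assert top.splits == system.splits[:3]


class TestFilterStrict:
    def test_compatible_input_identity(self):
        system = make_system(taxa_for(5), random_compatible_sides(random.Random(2), 5))
        assert filter_strict(system).splits == system.splits

    def test_four_taxon_all_splits(self):
        n = 4
        rng = random.Random(3)
        sides = {canonical_side(p, n) for p in range(1, (1 << n) - 1)}
        weights = {s: 1.0 for s in sides}
        best = canonical_side(mask([0, 1], n), n)
        weights[best] = 10.0
        system = make_system(taxa_for(n), weights)
        out = filter_strict(system)
        out_sides = out.sides()
        assert best in out_sides
        assert canonical_side(mask([0, 2], n), n) not in out_sides
        assert canonical_side(mask([0, 3], n), n) not in out_sides

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_output_pairwise_compatible_and_tree_sized(self, n):
        system = all_splits_system(n, random.Random(n))
        out = filter_strict(system)
        assert audit_pairwise_compatible(sides_as_sets(out), n)
        assert len(out) <= 2 * n - 3


class TestFilter2Tree:
    def test_compatible_input_second_bin_empty(self):
        system = make_system(taxa_for(6), random_compatible_sides(random.Random(4), 6))
        out = filter_2tree(system)
        assert out.splits == filter_strict(system).splits
        _, bin2 = two_tree_bins(system)
        assert bin2 == []

    def test_retains_best_incompatible_split(self):
        system = all_splits_system(4, random.Random(5))
        strict_sides = filter_strict(system).sides()
        out_sides = filter_2tree(system).sides()
        assert strict_sides < out_sides

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_partitions_into_two_compatible_bins(self, n):
        system = all_splits_system(n, random.Random(10 + n))
        out = filter_2tree(system)
        bin1, bin2 = two_tree_bins(system)
        assert sorted(ws.split.side for ws in out) == sorted(
            ws.split.side for ws in bin1 + bin2
        )
        for bin_ in (bin1, bin2):
            sides = [frozenset(ws.split.indices()) for ws in bin_]
            assert audit_pairwise_compatible(sides, n)

    def test_superset_of_strict(self):
        system = all_splits_system(5, random.Random(6))
        assert filter_strict(system).sides() <= filter_2tree(system).sides()


class TestFilterWeakly:
    def test_compatible_input_identity(self):
        system = make_system(taxa_for(6), random_compatible_sides(random.Random(7), 6))
        assert filter_weakly(system).splits == system.splits

    def test_strict_output_unchanged_by_weakly(self):
        system = all_splits_system(6, random.Random(8))
        strict = filter_strict(system)
        assert filter_weakly(strict).splits == strict.splits

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_all_triples_audit_and_size_bound(self, n):
        system = all_splits_system(n, random.Random(20 + n))
        out = filter_weakly(system)
        assert audit_weakly_compatible(sides_as_sets(out), n)
        assert len(out) <= n * (n - 1) // 2

    def test_can_retain_incompatible_pair(self):
        # 4-taxon all-splits: weakly keeps a box that strict would reject
        system = all_splits_system(4, random.Random(9))
        out = filter_weakly(system)
        sides = sides_as_sets(out)
        assert not audit_pairwise_compatible(sides, 4) or len(out) == len(
            filter_strict(system)
        )


def test_filters_deterministic():
    system = all_splits_system(6, random.Random(11))
    for filt in (filter_strict, filter_2tree, filter_weakly):
        assert filt(system).splits == filt(system).splits


def test_apply_filter_dispatch():
    system = all_splits_system(4, random.Random(12))
    assert apply_filter(system, FilterConfig(mode="none")).splits == system.splits
    assert apply_filter(system, FilterConfig(mode="topx", x=2)).splits == system.splits[:2]
    assert apply_filter(system, FilterConfig(mode="strict")).splits == filter_strict(system).splits
    with pytest.raises(ValueError):
        FilterConfig(mode="topx")
    with pytest.raises(ValueError):
        FilterConfig(mode="strict", x=3)
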