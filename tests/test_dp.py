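import random

import pytest

import rfsolve as rf
from rfsolve.bipartition import Bipartition
from rfsolve.errors import InfeasibleConstraintsError

from conftest import all_bipartitions, random_instance, random_tree


def mask(index, labels):
    return index.mask_of(labels)


class TestAssignedToPair:
    def test_matching_side_with_other_clade_touching(self, e1_sources, e1_index):
        bip = next(iter(rf.tree_bipartitions(e1_sources[0], e1_index)))  # ab|cd
        assert rf.assigned_to_pair(bip, mask(e1_index, "ab"), mask(e1_index, "c"))

    def test_partial_overlap_is_not_assignment(self, e1_sources, e1_index):
        bip = next(iter(rf.tree_bipartitions(e1_sources[2], e1_index)))  # bc|de
        assert not rf.assigned_to_pair(bip, mask(e1_index, "ab"), mask(e1_index, "c"))

    def test_restriction_to_full_side_matches(self, e1_sources, e1_index):
        bip = next(iter(rf.tree_bipartitions(e1_sources[2], e1_index)))  # bc|de
        assert rf.assigned_to_pair(bip, mask(e1_index, "abc"), mask(e1_index, "d"))

    def test_overlapping_clades_rejected(self, e1_sources, e1_index):
        bip = next(iter(rf.tree_bipartitions(e1_sources[0], e1_index)))
        with pytest.raises(ValueError):
            rf.assigned_to_pair(bip, mask(e1_index, "ab"), mask(e1_index, "bc"))


class TestSupport:
    def test_worked_values(self, e1_sources, e1_index):
        table = rf.SupportTable(e1_sources, e1_index)
        assert table.support(mask(e1_index, "ab"), mask(e1_index, "c")) == 2
        assert table.support(mask(e1_index, "abc"), mask(e1_index, "d")) == 1
        assert table.support(mask(e1_index, "a"), mask(e1_index, "b")) == 0
        assert table.support(mask(e1_index, "abcd"), mask(e1_index, "e")) == 0

    def test_symmetric_and_bounded(self, e1_sources, e1_index):
        table = rf.SupportTable(e1_sources, e1_index)
        a1, a2 = mask(e1_index, "ab"), mask(e1_index, "c")
        assert table.support(a1, a2) == table.support(a2, a1)
        assert 0 <= table.support(a1, a2) <= table.total_source_bipartitions

    def test_exhaustive_against_predicate(self, e1_sources, e1_index):
        """The memoized count equals a direct predicate sweep for every
        disjoint clade pair on 5 taxa."""
        table = rf.SupportTable(e1_sources, e1_index)
        bips_by_source = [
            list(rf.tree_bipartitions(t, e1_index)) for t in e1_sources
        ]
        full = e1_index.full_mask
        for a1 in range(1, full + 1):
            for a2 in range(1, full + 1):
                if a1 & a2:
                    continue
                direct = sum(
                    rf.assigned_to_pair(b, a1, a2)
                    for bips in bips_by_source
                    for b in bips
                )
                assert table.support(a1, a2) == direct


class TestRunDP:
    def test_e1_total_support(self, e1_sources, e1_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e1_index), e1_index)
        dp = rf.run_dp(cs, e1_sources)
        assert dp.total == 3

    def test_singletons_are_zero(self, e1_sources, e1_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e1_index), e1_index)
        dp = rf.run_dp(cs, e1_sources)
        for i in range(len(e1_index)):
            assert dp.bps[1 << i] == 0

    def test_e2_total_support(self, e2_sources, e2_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e2_index), e2_index)
        dp = rf.run_dp(cs, e2_sources)
        assert dp.total == 1

    def test_recorded_values_dominate_admissible_splits(self, e1_sources, e1_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e1_index), e1_index)
        dp = rf.run_dp(cs, e1_sources)
        table = rf.SupportTable(e1_sources, e1_index)
        clade_set = set(cs.clades)
        for a, value in dp.bps.items():
            if a.bit_count() < 2:
                continue
            for a1 in clade_set:
                a2 = a ^ a1
                if a1 & a != a1 or a2 not in clade_set or a1 >= a or a2 >= a:
                    continue
                if a1 in dp.bps and a2 in dp.bps:
                    assert value >= dp.bps[a1] + dp.bps[a2] + table.support(a1, a2)

    def test_infeasible_constraints_raise(self, e1_sources, e1_index):
        # two crossing bipartitions cannot jointly resolve S, and alone
        # neither yields n-3 = 2 compatible bipartitions
        x = [
            Bipartition.from_string("a,b|c,d,e", e1_index),
            Bipartition.from_string("a,c|b,d,e", e1_index),
        ]
        cs = rf.ConstraintSet.from_bipartitions(x, e1_index)
        with pytest.raises(InfeasibleConstraintsError):
            rf.run_dp(cs, e1_sources)


class TestBacktrack:
    def test_e1_unique_optimum_recovered(self, e1_sources, e1_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e1_index), e1_index)
        tree, bps, score = rf.solve_constrained_rfs(e1_sources, cs)
        assert (bps, score) == (3, 0)
        got = {b.to_string(e1_index) for b in rf.tree_bipartitions(tree, e1_index)}
        assert got == {"a,b|c,d,e", "a,b,c|d,e"}

    def test_e2_tie_breaks_deterministically(self, e2_sources, e2_index):
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(e2_index), e2_index)
        outputs = set()
        for _ in range(3):
            tree, bps, score = rf.solve_constrained_rfs(e2_sources, cs)
            outputs.add(rf.write_newick(tree))
            assert (bps, score) == (1, 4)
        assert len(outputs) == 1
        tree = rf.parse_newick(outputs.pop())
        assert Bipartition.from_string("a,b|c,d", e2_index) in rf.tree_bipartitions(tree, e2_index)

    def test_output_is_fully_resolved_within_x(self, e1_sources, e1_index):
        cs = rf.build_constraint_set(e1_sources, index=e1_index, seed=0)
        tree, _, _ = rf.solve_constrained_rfs(e1_sources, cs)
        bips = rf.tree_bipartitions(tree, e1_index)
        assert len(bips) == len(e1_index) - 3
        assert bips <= cs.bipartitions
        assert rf.is_binary(tree)

    def test_compatible_sources_reach_zero(self):
        model = random_tree(7, 77)
        index = rf.TaxonIndex(model.leaf_labels())
        rng = random.Random(77)
        sources = [
            rf.restrict_tree(model, set(rng.sample(model.leaf_labels(), 5)))
            for _ in range(4)
        ]
        cs = rf.build_constraint_set(sources, [model], index, seed=0)
        _, _, score = rf.solve_constrained_rfs(sources, cs)
        assert score == 0


class TestConversion:
    def test_worked_values(self, e1_sources, e2_sources):
        assert rf.bps_to_rfs(3, e1_sources) == 0
        assert rf.bps_to_rfs(1, e2_sources) == 4

    def test_zero_support_is_maximum_score(self, e1_sources):
        # binary quartet sources: each contributes 2(l-3) = 2
        assert rf.bps_to_rfs(0, e1_sources) == 6

    def test_matches_direct_scoring_of_backtracked_tree(self):
        for seed in range(10):
            _, sources, index = random_instance(seed)
            cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(index), index)
            tree, bps, score = rf.solve_constrained_rfs(sources, cs)
            assert score == rf.rfs_criterion_score(tree, sources).rfs_total

    def test_impossible_support_rejected(self, e1_sources):
        with pytest.raises(InfeasibleConstraintsError):
            rf.bps_to_rfs(100, e1_sources)


class TestStructuralProperties:
    def test_assignment_unique_per_rooted_tree(self, e1_sources, e1_index):
        """Every source bipartition is charged to at most one node, over all
        rootings of all 15 five-taxon topologies."""
        source_bips = [
            b for t in e1_sources for b in rf.tree_bipartitions(t, e1_index)
        ]
        for topo in rf.enumerate_binary_trees(e1_index):
            for rooted in rf.all_rootings(topo):
                node_masks = []

                def collect(node):
                    if node.is_leaf:
                        return e1_index.bit(node.label)
                    ms = [collect(c) for c in node.children]
                    node_masks.append(tuple(ms))
                    return ms[0] | ms[1]

                collect(rooted.root)
                for bip in source_bips:
                    hits = sum(
                        rf.assigned_to_pair(bip, m1, m2) for m1, m2 in node_masks
                    )
                    assert hits <= 1

    def test_decomposition_over_tripartitions(self):
        """Node-wise support sums equal the directly counted bipartition
        support for random binary supertrees."""
        rng = random.Random(0)
        for rep in range(30):
            n = rng.randint(5, 12)
            supertree = random_tree(n, 9000 + rep)
            index = rf.TaxonIndex(supertree.leaf_labels())
            sources = [
                rf.restrict_tree(
                    random_tree(n, 9500 + rep * 7 + j),
                    set(rng.sample(supertree.leaf_labels(), rng.randint(4, n))),
                )
                for j in range(3)
            ]
            table = rf.SupportTable(sources, index)
            rooted = rf.all_rootings(supertree)[0]
            total = 0

            def walk(node):
                nonlocal total
                if node.is_leaf:
                    return index.bit(node.label)
                ms = [walk(c) for c in node.children]
                total += table.support(ms[0], ms[1])
                return ms[0] | ms[1]

            walk(rooted.root)
            assert total == rf.bipartition_support_of_tree(supertree, sources)

    @pytest.mark.parametrize("seed", range(12))
    def test_exactness_against_brute_force(self, seed):
        _, sources, index = random_instance(seed)
        cs = rf.ConstraintSet.from_bipartitions(all_bipartitions(index), index)
        _, _, score = rf.solve_constrained_rfs(sources, cs)
        _, best, _ = rf.exact_rfs_search(sources, index)
        assert score == best

    @pytest.mark.parametrize("seed", range(8))
    def test_exactness_with_proper_x(self, seed):
        _, sources, index = random_instance(seed)
        rng = random.Random(seed + 4000)
        x = set()
        for _ in range(3):
            x |= rf.tree_bipartitions(rf.random_binary_tree(list(index.labels), rng), index)
        cs = rf.ConstraintSet.from_bipartitions(x, index)
        _, _, score = rf.solve_constrained_rfs(sources, cs)
        _, best = rf.exact_constrained_search(sources, x, index)
        assert score == best

    @pytest.mark.parametrize("seed", range(6))
    def test_enhanced_mode_dominates_candidates(self, seed):
        _, sources, index = random_instance(seed)
        rng = random.Random(seed + 8000)
        candidates = [
            rf.random_binary_tree(list(index.labels), rng) for _ in range(3)
        ]
        cs = rf.build_constraint_set(sources, candidates, index, seed=seed)
        _, _, score = rf.solve_constrained_rfs(sources, cs)
        for cand in candidates:
            assert score <= rf.rfs_criterion_score(cand, sources).rfs_total

    @pytest.mark.parametrize("seed", range(6))
    def test_enlarging_x_never_hurts(self, seed):
        _, sources, index = random_instance(seed)
        rng = random.Random(seed + 12000)
        x_small = set(
            rf.tree_bipartitions(rf.random_binary_tree(list(index.labels), rng), index)
        )
        x_big = x_small | set(
            rf.tree_bipartitions(rf.random_binary_tree(list(index.labels), rng), index)
        )
        _, _, s_small = rf.solve_constrained_rfs(
            sources, rf.ConstraintSet.from_bipartitions(x_small, index)
        )
        _, _, s_big = rf.solve_constrained_rfs(
            sources, rf.ConstraintSet.from_bipartitions(x_big, index)
        )
        assert s_big <= s_small
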