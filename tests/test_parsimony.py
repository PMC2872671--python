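"""Fitch scoring, heuristic search, bootstrap, ILD and constrained search."""

import numpy as np
import pytest

from conftest import all_tuple_topologies, random_alignment, sankoff_length
from mycopop.alignment_io import AlignedLocus
from mycopop.errors import TreeError
from mycopop.parsimony import (
    bootstrap_support,
    constrained_search,
    encode_characters,
    exhaustive_search_masks,
    fitch_length,
    ild_test,
    mp_search,
    read_newick,
    tree_from_groups,
)
from mycopop.simulate import LocusSpec, SimulationConfig, simulate_dataset


class TestFitch:
    def test_congruent_character_one_step(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["A", "A", "T", "T"])
        s = fitch_length(tree_from_groups((("t1", "t2"), ("t3", "t4"))), locus)
        assert (s.length, s.ci, s.ri) == (1, 1.0, 1.0)
        assert s.minima.tolist() == [1] and s.maxima.tolist() == [2]

    def test_conflicting_character_two_steps(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["A", "A", "T", "T"])
        s = fitch_length(tree_from_groups((("t1", "t3"), ("t2", "t4"))), locus)
        assert s.length == 2
        assert s.ci == 0.5
        assert s.ri == 0.0

    def test_invariant_character_costs_nothing(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["A", "A", "A", "A"])
        for topo in [(("t1", "t2"), ("t3", "t4")), (("t1", "t3"), ("t2", "t4"))]:
            assert fitch_length(tree_from_groups(topo), locus).length == 0

    def test_leaf_mismatch_is_error(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["A", "A", "T", "T"])
        tree = tree_from_groups((("t1", "t2"), ("t3", "x9")))
        with pytest.raises(TreeError):
            fitch_length(tree, locus)

    def test_ci_one_exactly_when_no_homoplasy(self, rng):
        for _ in range(30):
            locus = random_alignment(rng, int(rng.integers(4, 7)), int(rng.integers(2, 8)))
            res = mp_search(locus, n_random_addition=4, seed=int(rng.integers(2**31)))
            s = fitch_length(res.best, locus)
            if s.length == 0:
                continue
            assert (s.ci == 1.0) == bool(np.all(s.steps == s.minima))

    def test_agrees_with_dendropy_fitch(self, rng):
        """Independent library cross-check on random trees and data."""
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        for _ in range(20):
            n = int(rng.integers(4, 8))
            locus = random_alignment(rng, n, int(rng.integers(1, 12)))
            res = mp_search(locus, n_random_addition=2, seed=int(rng.integers(2**31)))
            tree = res.best
            ours = fitch_length(tree, locus).length

            taxa = dendropy.TaxonNamespace()
            fasta = "".join(
                f">{s}\n{r}\n" for s, r in zip(locus.strain_ids, locus.rows)
            )
            data = dendropy.DnaCharacterMatrix.get(
                data=fasta, schema="fasta", taxon_namespace=taxa
            )
            dtree = dendropy.Tree.get(
                data=tree.newick(), schema="newick", taxon_namespace=taxa
            )
            theirs = fitch_down_pass(
                dtree.postorder_node_iter(),
                taxon_state_sets_map=data.taxon_state_sets_map(gaps_as_missing=True),
            )
            assert ours == theirs


class TestSearch:
    def test_single_informative_character_groups_the_pair(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["A", "A", "T", "T"])
        res = mp_search(locus, n_random_addition=3, seed=0)
        assert res.length == 1
        assert frozenset({"t3", "t4"}) in res.best.splits() or frozenset(
            {"t1", "t2"}
        ) in res.best.splits()

    def test_identical_sequences_zero_length(self):
        locus = AlignedLocus("x", ["t1", "t2", "t3", "t4"], ["ACG"] * 4)
        assert mp_search(locus, n_random_addition=2, seed=0).length == 0

    def test_two_clade_truth_recovered(self):
        ids = [f"t{i}" for i in range(6)]
        rows = ["AAAAA" if i < 3 else "TTTTT" for i in range(6)]
        locus = AlignedLocus("x", ids, rows)
        res = mp_search(locus, n_random_addition=4, seed=1)
        assert res.length == 5
        assert frozenset(ids[3:]) in res.best.splits() or frozenset(ids[:3]) in res.best.splits()

    def test_below_four_taxa_is_error(self):
        locus = AlignedLocus("x", ["a", "b", "c"], ["A", "A", "T"])
        with pytest.raises(TreeError):
            mp_search(locus)

    def test_deterministic_given_seed(self, rng):
        locus = random_alignment(rng, 7, 12)
        a = mp_search(locus, n_random_addition=5, seed=42)
        b = mp_search(locus, n_random_addition=5, seed=42)
        assert a.length == b.length
        assert [t.canonical_key() for t in a.trees] == [t.canonical_key() for t in b.trees]

    def test_matches_sankoff_oracle_over_all_topologies(self, rng):
        """Heuristic and exhaustive-module search equal an independent
        exhaustive Sankoff enumeration on tuple trees."""
        for _ in range(40):
            n = int(rng.integers(4, 7))
            locus = random_alignment(rng, n, int(rng.integers(1, 9)))
            cols = dict(zip(locus.strain_ids, locus.rows))
            oracle = min(
                sankoff_length(t, cols)
                for t in all_tuple_topologies(list(locus.strain_ids))
            )
            got = mp_search(locus, n_random_addition=6, seed=int(rng.integers(2**31)))
            assert got.length == oracle
            taxa, masks = encode_characters(locus)
            assert exhaustive_search_masks(masks, taxa).length == oracle


class TestNewick:
    def test_newick_round_trip_preserves_topology(self, rng):
        locus = random_alignment(rng, 6, 10)
        tree = mp_search(locus, n_random_addition=3, seed=3).best
        back = read_newick(tree.newick())
        assert back.splits() == tree.splits()


class TestBootstrap:
    def test_clean_two_clade_split_is_strongly_supported(self):
        ids = [f"t{i}" for i in range(6)]
        rows = ["A" * 12 if i < 3 else "T" * 12 for i in range(6)]
        locus = AlignedLocus("x", ids, rows)
        bs = bootstrap_support(locus, n_reps=100, seed=5)
        main_split = frozenset(ids[3:])
        if main_split not in bs.support:
            main_split = frozenset(ids[:3])
        assert bs.support[main_split] >= 90.0

    def test_no_variable_sites_no_supports(self):
        locus = AlignedLocus("x", ["a", "b", "c", "d"], ["ACG"] * 4)
        bs = bootstrap_support(locus, n_reps=10, seed=1)
        assert bs.support == {}
        assert bs.n_variable_sites == 0

    def test_strain_order_does_not_change_supports(self):
        ids = [f"t{i}" for i in range(6)]
        rows = ["AATTAGAC" if i < 3 else "TTAACTGA" for i in range(6)]
        locus = AlignedLocus("x", ids, rows)
        shuffled = AlignedLocus("x", ids[::-1], rows[::-1])
        b1 = bootstrap_support(locus, n_reps=30, seed=9)
        b2 = bootstrap_support(shuffled, n_reps=30, seed=9)
        assert b1.support == b2.support


class TestILD:
    def test_copied_locus_is_maximally_congruent(self, rng):
        locus = random_alignment(rng, 6, 12)
        copy = AlignedLocus("copy", locus.strain_ids, locus.rows)
        res = ild_test([locus, copy], n_reps=49, seed=2)
        assert res.p_value > 0.5

    def test_planted_conflict_is_detected(self):
        ids = [f"t{i}" for i in range(8)]
        rows_a = ["A" * 6 if i < 4 else "T" * 6 for i in range(8)]
        rows_b = ["A" * 6 if i % 2 == 0 else "T" * 6 for i in range(8)]
        res = ild_test(
            [AlignedLocus("a", ids, rows_a), AlignedLocus("b", ids, rows_b)],
            n_reps=99,
            seed=2,
        )
        assert res.p_value < 0.05

    def test_single_locus_is_error(self, rng):
        locus = random_alignment(rng, 5, 8)
        with pytest.raises(TreeError):
            ild_test([locus], n_reps=9, seed=0)

    def test_mismatched_strain_sets_is_error(self, rng):
        l1 = random_alignment(rng, 5, 8)
        l2 = AlignedLocus("z", [f"z{i}" for i in range(5)], l1.rows)
        with pytest.raises(TreeError):
            ild_test([l1, l2], n_reps=9, seed=0)


class TestConstrainedSearch:
    @pytest.fixture
    def three_lineage_locus(self):
        cfg = SimulationConfig(
            lineages=["L1", "L2", "L3"],
            populations={"L1": {"A": 3}, "L2": {"B": 3}, "L3": {"C": 3}},
            loci=[
                LocusSpec(
                    "loc",
                    length=120,
                    fixed_differences={
                        frozenset({"L1", "L2"}): 6,
                        frozenset({"L1", "L3"}): 8,
                        frozenset({"L2", "L3"}): 6,
                    },
                    within_segregating={"L1": 2, "L2": 1, "L3": 1},
                )
            ],
            seed=17,
        )
        loci, part, _ = simulate_dataset(cfg)
        groups = [frozenset(part.strains_in_lineage(l)) for l in part.lineages]
        return loci["loc"], groups

    def test_true_lineage_constraint_costs_nothing(self, three_lineage_locus):
        locus, groups = three_lineage_locus
        res = constrained_search(locus, groups, seed=4, n_random_addition=4)
        assert res.delta == 0

    def test_cross_lineage_constraint_costs_steps(self, three_lineage_locus):
        locus, groups = three_lineage_locus
        mixed = [frozenset(list(groups[0])[:2] + list(groups[1])[:2])]
        res = constrained_search(locus, mixed, seed=4, n_random_addition=4)
        assert res.delta > 0

    def test_permutation_p_large_for_costless_constraint(self, three_lineage_locus):
        locus, groups = three_lineage_locus
        res = constrained_search(
            locus, groups, seed=4, n_random_addition=2, n_permutations=9
        )
        assert res.p_value == 1.0  # delta 0 can never be exceeded

    def test_overlapping_groups_rejected(self, three_lineage_locus):
        locus, groups = three_lineage_locus
        with pytest.raises(TreeError):
            constrained_search(locus, [groups[0], groups[0]], seed=0)

    def test_constrained_never_shorter_than_unconstrained(self, rng):
        for _ in range(5):
            locus = random_alignment(rng, 6, 10)
            ids = locus.strain_ids
            res = constrained_search(
                locus, [frozenset(ids[:3])], seed=int(rng.integers(2**31)),
                n_random_addition=3,
            )
            assert res.delta >= 0
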