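"""Index of association and cross-locus phylogenetic compatibility."""

import itertools

import numpy as np
import pytest

from mycopop.clonality import (
    MultilocusGenotypeMatrix,
    from_phased,
    index_of_association,
    pairwise_distance,
    phylogenetic_compatibility,
)
from mycopop.errors import ClonalityError
from mycopop.phasing import em_phase, snpify
from mycopop.simulate import simulate_multilocus_panel, simulate_phasing_panel


def matrix_from(rows, loci=None):
    """rows: {strain: {locus: (a, b)}}"""
    strains = list(rows)
    loci = loci or sorted(next(iter(rows.values())))
    return MultilocusGenotypeMatrix(strains, list(loci), {s: dict(g) for s, g in rows.items()})


class TestDistance:
    def test_identical_genotypes_distance_zero(self):
        d, total = pairwise_distance([("A", "A"), ("B", "B")], [("A", "A"), ("B", "B")])
        assert d == [0.0, 0.0] and total == 0.0

    def test_one_shared_allele_is_half(self):
        d, _ = pairwise_distance([("A", "a")], [("A", "A")])
        assert d == [0.5]

    def test_disjoint_pairs_are_one_each(self):
        d, total = pairwise_distance(
            [("A", "a"), ("B", "b")], [("c", "d"), ("e", "f")]
        )
        assert d == [1.0, 1.0] and total == 2.0

    def test_locus_list_mismatch_is_error(self):
        with pytest.raises(ClonalityError):
            pairwise_distance([("A", "A")], [("A", "A"), ("B", "B")])


def brute_force_ia(matrix):
    """Independent recomputation of I_A from scratch (pure python)."""
    n = len(matrix.strain_ids)
    pairs = list(itertools.combinations(range(n), 2))
    per_locus = {l: [] for l in matrix.loci}
    totals = []
    for i, j in pairs:
        g1 = [matrix.pair(matrix.strain_ids[i], l) for l in matrix.loci]
        g2 = [matrix.pair(matrix.strain_ids[j], l) for l in matrix.loci]
        deltas, total = pairwise_distance(g1, g2)
        totals.append(total)
        for l, d in zip(matrix.loci, deltas):
            per_locus[l].append(d)

    def var(xs):
        m = sum(xs) / len(xs)
        return sum((x - m) ** 2 for x in xs) / len(xs)

    return var(totals) / sum(var(per_locus[l]) for l in matrix.loci) - 1.0


class TestIndexOfAssociation:
    def test_single_variable_locus_is_exactly_zero(self):
        m, _ = simulate_multilocus_panel(10, n_loci=1, mode="sexual", seed=3)
        res = index_of_association(m, n_permutations=19, seed=1)
        assert res.ia == 0.0

    def test_duplicated_locus_is_exactly_one(self):
        m, _ = simulate_multilocus_panel(10, n_loci=1, mode="sexual", seed=3)
        rows = {
            s: {
                "LOC1": m.pair(s, "LOC1"),
                "LOC2": tuple(a.replace("LOC1", "LOC2") for a in m.pair(s, "LOC1")),
            }
            for s in m.strain_ids
        }
        res = index_of_association(matrix_from(rows), n_permutations=19, seed=1)
        assert res.ia == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_recomputation(self):
        m, _ = simulate_multilocus_panel(12, n_loci=3, mode="clonal", seed=8)
        res = index_of_association(m, n_permutations=9, seed=1)
        assert res.ia == pytest.approx(brute_force_ia(m), abs=1e-12)

    def test_invariant_under_allele_relabeling_and_strain_order(self):
        m, _ = simulate_multilocus_panel(10, n_loci=2, mode="clonal", seed=4)
        res = index_of_association(m, n_permutations=9, seed=1)
        relabeled = {
            s: {l: tuple(sorted(f"x{a}" for a in m.pair(s, l))) for l in m.loci}
            for s in m.strain_ids
        }
        m2 = MultilocusGenotypeMatrix(m.strain_ids[::-1], m.loci, relabeled)
        res2 = index_of_association(m2, n_permutations=9, seed=1)
        assert res2.ia == pytest.approx(res.ia, abs=1e-12)

    def test_exhaustive_p_at_n5_matches_independent_enumeration(self):
        m, _ = simulate_multilocus_panel(5, n_loci=2, n_alleles=3, mode="clonal", seed=2)
        res = index_of_association(m, seed=0, exhaustive=True)
        assert res.n_permutations == (120) ** 2

        # independent enumeration: rebuild the matrix for every pair of
        # per-locus strain relabelings and recompute I_A from scratch
        strains = m.strain_ids
        null = []
        for p1 in itertools.permutations(range(5)):
            g1 = [m.pair(strains[i], "LOC1") for i in p1]
            for p2 in itertools.permutations(range(5)):
                g2 = [m.pair(strains[i], "LOC2") for i in p2]
                rows = {
                    s: {"LOC1": g1[k], "LOC2": g2[k]} for k, s in enumerate(strains)
                }
                null.append(brute_force_ia(matrix_from(rows)))
        observed = brute_force_ia(m)
        expected_p = np.mean(np.array(null) >= observed - 1e-12)
        assert res.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_monomorphic_locus_excluded_with_note(self):
        m, _ = simulate_multilocus_panel(8, n_loci=2, mode="sexual", seed=5)
        rows = {
            s: {"LOC1": m.pair(s, "LOC1"), "LOC2": ("LOC2.1", "LOC2.1")}
            for s in m.strain_ids
        }
        res = index_of_association(matrix_from(rows), n_permutations=9, seed=1)
        assert res.excluded_loci == ["LOC2"]
        assert res.ia == 0.0  # single informative locus left

    def test_all_monomorphic_is_error(self):
        rows = {
            f"s{i}": {"L1": ("a", "a"), "L2": ("b", "b")} for i in range(5)
        }
        with pytest.raises(ClonalityError):
            index_of_association(matrix_from(rows), n_permutations=9, seed=1)

    def test_null_distribution_centred_near_zero(self):
        m, _ = simulate_multilocus_panel(20, n_loci=2, mode="clonal", seed=9)
        res = index_of_association(m, n_permutations=499, seed=3)
        se = res.null.std() / np.sqrt(len(res.null))
        assert abs(res.null.mean()) < 3 * max(se, 1e-12)

    def test_clone_correction_collapses_repeated_genotypes(self):
        m, _ = simulate_multilocus_panel(20, n_loci=2, mode="clonal",
                                         mutation_rate=0.0, seed=11)
        res = index_of_association(m, n_permutations=9, seed=1, clone_correct=True)
        assert res.n_strains < 20


class TestDiscrimination:
    def test_sexual_populations_not_flagged_clonal_on_average(self):
        ps = []
        for seed in range(25):
            m, _ = simulate_multilocus_panel(30, 2, 5, mode="sexual", seed=seed)
            ps.append(index_of_association(m, n_permutations=99, seed=seed + 1).p_value)
        assert np.median(ps) > 0.2

    def test_clonal_populations_strongly_flagged(self):
        ps = []
        for seed in range(25):
            m, _ = simulate_multilocus_panel(30, 2, 5, mode="clonal", seed=seed)
            ps.append(index_of_association(m, n_permutations=99, seed=seed + 1).p_value)
        assert np.mean(np.array(ps) < 0.05) >= 0.9


class TestCompatibility:
    def test_four_homozygous_combinations_flag_quartet(self):
        rows = {
            "s1": {"A": ("A.1", "A.1"), "B": ("B.1", "B.1")},
            "s2": {"A": ("A.1", "A.1"), "B": ("B.2", "B.2")},
            "s3": {"A": ("A.2", "A.2"), "B": ("B.1", "B.1")},
            "s4": {"A": ("A.2", "A.2"), "B": ("B.2", "B.2")},
        }
        rep = phylogenetic_compatibility(matrix_from(rows), "A", "B")
        assert len(rep.quartets) == 1
        q = rep.quartets[0]
        assert all(len(w) == 1 for w in q.witnesses.values())

    def test_two_combinations_do_not_flag(self):
        rows = {
            "s1": {"A": ("A.1", "A.1"), "B": ("B.1", "B.1")},
            "s2": {"A": ("A.2", "A.2"), "B": ("B.2", "B.2")},
            "s3": {"A": ("A.1", "A.1"), "B": ("B.1", "B.1")},
            "s4": {"A": ("A.2", "A.2"), "B": ("B.2", "B.2")},
        }
        rep = phylogenetic_compatibility(matrix_from(rows), "A", "B")
        assert not rep.incompatible

    def test_double_heterozygotes_alone_cannot_witness(self):
        # every strain doubly heterozygous: cross-locus phase is ambiguous,
        # so nothing is evidenced and no quartet may be flagged
        rows = {
            f"s{i}": {"A": ("A.1", "A.2"), "B": ("B.1", "B.2")} for i in range(6)
        }
        rep = phylogenetic_compatibility(matrix_from(rows), "A", "B")
        assert not rep.incompatible

    def test_recombining_vs_clonal_simulations(self):
        flagged_sexual = 0
        for seed in range(10):
            m, _ = simulate_multilocus_panel(50, 2, 3, mode="sexual", seed=seed)
            rep = phylogenetic_compatibility(m, "LOC1", "LOC2")
            flagged_sexual += rep.incompatible
        assert flagged_sexual >= 9  # all-four-combinations nearly certain at n=50

        for seed in range(10):
            m, _ = simulate_multilocus_panel(
                50, 2, 3, mode="clonal", n_founders=3, mutation_rate=0.0, seed=seed
            )
            rep = phylogenetic_compatibility(m, "LOC1", "LOC2")
            assert not rep.incompatible  # three founders cannot span a quartet


class TestFromPhased:
    def test_alleles_are_locus_scoped_and_consistent(self):
        phased = {}
        for locus_seed, name in [(3, "ITS"), (4, "RPB2")]:
            locus, _, _ = simulate_phasing_panel(15, 5, 3, seed=locus_seed)
            locus.locus_name = name
            phased[name] = em_phase(snpify(locus), seed=1)
        m = from_phased(phased)
        assert m.loci == ["ITS", "RPB2"]
        assert len(m.strain_ids) == 15
        for s in m.strain_ids:
            for l in m.loci:
                a, b = m.pair(s, l)
                assert a.startswith(f"{l}.") and b.startswith(f"{l}.")
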