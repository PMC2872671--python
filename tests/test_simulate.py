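"""Synthetic-data generator: determinism, planted truth, genetic structure."""

import numpy as np
import pytest

from mycopop.alignment_io import classify_sites
from mycopop.divergence_stats import pairwise_divergence
from mycopop.errors import ConfigError
from mycopop.genotype_diversity import collapse_genotypes
from mycopop.simulate import (
    IndelTrackSpec,
    LocusSpec,
    SimulationConfig,
    _solve_fixed_decomposition,
    default_config,
    expected_fixed_differences,
    simulate_dataset,
    simulate_lineage_pool,
    simulate_multilocus_panel,
    simulate_phasing_panel,
)


class TestFixedDecomposition:
    def test_two_lineages_is_direct(self):
        d, t = _solve_fixed_decomposition(["A", "B"], {frozenset({"A", "B"}): 21})
        assert d["A"] + d["B"] == 21 and t == 0

    @pytest.mark.parametrize("k12,k13,k23", [(21, 47, 37), (18, 29, 16), (5, 8, 7), (0, 0, 0)])
    def test_three_lineage_counts_reconstruct(self, k12, k13, k23):
        lins = ["L1", "L2", "L3"]
        k = {
            frozenset({"L1", "L2"}): k12,
            frozenset({"L1", "L3"}): k13,
            frozenset({"L2", "L3"}): k23,
        }
        d, t = _solve_fixed_decomposition(lins, k)
        assert d["L1"] + d["L2"] + t == k12
        assert d["L1"] + d["L3"] + t == k13
        assert d["L2"] + d["L3"] + t == k23
        assert all(v >= 0 for v in d.values()) and t >= 0

    def test_infeasible_counts_rejected(self):
        # triangle violation: k12 + k13 < k23 admits no solution
        k = {
            frozenset({"L1", "L2"}): 1,
            frozenset({"L1", "L3"}): 1,
            frozenset({"L2", "L3"}): 10,
        }
        with pytest.raises(ConfigError):
            _solve_fixed_decomposition(["L1", "L2", "L3"], k)


class TestDeterminism:
    def test_same_seed_same_bytes(self):
        a = simulate_dataset(default_config(42))
        b = simulate_dataset(default_config(42))
        assert {n: l.rows for n, l in a[0].items()} == {n: l.rows for n, l in b[0].items()}
        assert a[1].assignments == b[1].assignments
        assert a[2].to_json() == b[2].to_json()

    def test_different_seed_different_data(self):
        a = simulate_dataset(default_config(1))
        b = simulate_dataset(default_config(2))
        assert a[0]["ITS"].rows != b[0]["ITS"].rows


class TestPlantedStructure:
    def test_default_dataset_shape(self):
        loci, part, truth = simulate_dataset(default_config(5))
        assert sorted(loci) == ["ITS", "RPB2", "mtSSU", "nucLSU"]
        assert loci["ITS"].n_sites == 683
        assert loci["ITS"].n_strains == 33
        assert classify_sites(loci["nucLSU"]).n_variable == 0
        assert classify_sites(loci["mtSSU"]).n_variable == 0

    def test_indel_tracks_emitted_at_configured_positions(self):
        cfg = default_config(5)
        loci, _, _ = simulate_dataset(cfg)
        sc = classify_sites(loci["ITS"])
        assert (450, 452, 3) in sc.indel_tracks
        assert (520, 537, 18) in sc.indel_tracks

    def test_pairwise_fixed_differences_match_expectation(self):
        cfg = default_config(5)
        loci, part, _ = simulate_dataset(cfg)
        exp = expected_fixed_differences(cfg, cfg.loci[0])
        for l1, l2 in [("L1", "L2"), ("L1", "L3"), ("L2", "L3")]:
            d = pairwise_divergence(loci["ITS"], part, l1, l2)
            assert d.n_fixed == exp[frozenset({l1, l2})]

    def test_genotypes_trace_back_to_planted_haplotype_pairs(self):
        """With no mutation, each strain's sequence is the IUPAC union of
        its recorded haplotype pair."""
        cfg = default_config(6)
        loci, part, truth = simulate_dataset(cfg)
        from mycopop.alignment_io import expand_char

        for sid in loci["ITS"].strain_ids:
            i, j = truth.haplotype_pairs[sid]["ITS"]
            pool = truth.pools[truth.lineage[sid]]["ITS"]
            h1, h2 = pool[i], pool[j]
            row = loci["ITS"].row(sid)
            for a, b, c in zip(h1, h2, row):
                assert expand_char(c) == frozenset({a, b})

    def test_site_budget_overflow_rejected(self):
        cfg = SimulationConfig(
            lineages=["L1", "L2"],
            populations={"L1": {"A": 2}, "L2": {"B": 2}},
            loci=[
                LocusSpec(
                    "tiny", length=10,
                    fixed_differences={frozenset({"L1", "L2"}): 20},
                )
            ],
            seed=1,
        )
        with pytest.raises(ConfigError, match="exceed"):
            simulate_lineage_pool(cfg)

    def test_indel_track_beyond_locus_rejected(self):
        cfg = SimulationConfig(
            lineages=["L1"],
            populations={"L1": {"A": 2}},
            loci=[
                LocusSpec(
                    "tiny", length=10,
                    indel_tracks=[IndelTrackSpec(start=8, length=5, gap_lineages=("L1",))],
                )
            ],
            seed=1,
        )
        with pytest.raises(ConfigError, match="range"):
            simulate_lineage_pool(cfg)


class TestReproductionModes:
    def test_sexual_heterozygote_fraction_near_hardy_weinberg(self):
        """Two equifrequent haplotypes differing at one site: expected
        heterozygote fraction 1/2."""
        cfg = SimulationConfig(
            lineages=["L1"],
            populations={"L1": {"A": 400}},
            loci=[LocusSpec("loc", length=40, within_segregating={"L1": 1})],
            pool_size=2,
            seed=12,
        )
        loci, _, truth = simulate_dataset(cfg)
        pool = truth.pools["L1"]["loc"]
        assert len(set(pool)) == 2
        het = sum(
            1 for sid in loci["loc"].strain_ids
            if len(set(truth.haplotype_pairs[sid]["loc"])) == 2
        )
        frac = het / 400
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 400)

    def test_clonal_without_mutation_copies_founders(self):
        cfg = default_config(9, mode="clonal")
        cfg.mutation_rate = 0.0
        loci, part, truth = simulate_dataset(cfg)
        table = collapse_genotypes(loci["ITS"], part)
        founders = {
            (truth.lineage[s], truth.pedigree[s]) for s in loci["ITS"].strain_ids
        }
        # number of distinct sequences cannot exceed number of founders used
        assert table.n_genotypes <= len(founders)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                lineages=["L1"], populations={"L1": {"A": 2}},
                loci=[LocusSpec("x", 10)], mode="budding", seed=0,
            )


class TestPanels:
    def test_phasing_panel_site_count_and_biallelism(self):
        locus, truth, pool = simulate_phasing_panel(20, 6, 4, seed=2)
        assert locus.n_strains == 20
        assert len(pool) == 4
        assert len(truth) == 20
        sc = classify_sites(locus)
        assert sc.n_indel_sites == 0

    def test_multilocus_panel_modes_and_determinism(self):
        m1, ped1 = simulate_multilocus_panel(15, 2, 5, mode="clonal", seed=7)
        m2, ped2 = simulate_multilocus_panel(15, 2, 5, mode="clonal", seed=7)
        assert m1.data == m2.data and ped1 == ped2
        assert all(v is not None for v in ped1.values())
        ms, peds = simulate_multilocus_panel(15, 2, 5, mode="sexual", seed=7)
        assert all(v is None for v in peds.values())
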