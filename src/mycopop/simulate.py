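"""Synthetic multilocus dikaryotic sequence datasets.

Generates aligned FASTA datasets with the statistical structure the
analysis pipeline assumes: a small number of deeply divergent lineages with
planted fixed differences, within-lineage polymorphism, lineage-diagnostic
indel tracks, invariant loci, and dikaryotic (IUPAC-coded) heterozygosity
produced by either sexual (random union of gametes) or clonal (founder
copying with rare mutation) reproduction.  Every dataset is a pure function
of its configuration, seed included.

Planting exact pairwise fixed-difference counts among three lineages needs
care: at any single site, if two lineages differ, the third must match one
of them or differ from both, so a site is always a fixed difference for at
least two of the three pairs.  The generator therefore decomposes the
requested pairwise counts k_ij into per-lineage private derived-site counts
d_i plus a number t of triallelic sites, with k_ij = d_i + d_j + t, and
raises a configuration error when no non-negative integer solution exists.

Default scales mirror a realistic single-mountain fungal collection:
33 strains, two variable loci (an ITS-like and an RPB2-like fragment, with
between-lineage fixed differences at the tens scale and single-digit
within-lineage polymorphism) plus two invariant rDNA-like loci.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import GAP, AlignedLocus, encode_base_pair, write_fasta_alignment
from .clonality import AllelePair, MultilocusGenotypeMatrix
from .errors import ConfigError
from .partition import LineagePartition, write_partition

_BASES = "ACGT"


@dataclass
class IndelTrackSpec:
    """A run of alignment columns gapped in all strains of some lineages."""

    start: int  # 1-based first column of the track
    length: int
    gap_lineages: tuple[str, ...]  # lineages whose strains carry the gap


@dataclass
class LocusSpec:
    name: str
    length: int
    #: symmetric pairwise fixed-difference counts, keyed by frozenset({l1,l2})
    fixed_differences: dict[frozenset, int] = field(default_factory=dict)
    #: within-lineage segregating substitution sites
    within_segregating: dict[str, int] = field(default_factory=dict)
    indel_tracks: list[IndelTrackSpec] = field(default_factory=list)


@dataclass
class SimulationConfig:
    lineages: list[str]
    #: lineage -> population -> number of strains
    populations: dict[str, dict[str, int]]
    loci: list[LocusSpec]
    mode: str = "sexual"  # or "clonal"
    pool_size: int = 4  # haplotypes per lineage pool per locus
    n_founders: int = 5  # clonal mode: founder dikaryons per lineage
    mutation_rate: float = 0.0  # clonal mode: per-site per-haplotype
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sexual", "clonal"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for spec in self.loci:
            for pair, k in spec.fixed_differences.items():
                if k < 0:
                    raise ConfigError(f"negative fixed-difference count for {sorted(pair)}")
                if not pair <= set(self.lineages):
                    raise ConfigError(f"fixed-difference pair {sorted(pair)} not in lineages")

    @property
    def strains(self) -> list[tuple[str, str, str]]:
        """(strain_id, population, lineage) triples, deterministic order."""
        out = []
        for lin in self.lineages:
            for pop in sorted(self.populations.get(lin, {})):
                for i in range(self.populations[lin][pop]):
                    out.append((f"{pop}{i + 1:02d}", pop, lin))
        return out


def default_config(seed: int, mode: str = "sexual") -> SimulationConfig:
    """Study-scale default: 3 lineages, 33 strains, 2 variable + 2 invariant loci.

    The ITS-like locus carries between-lineage substitution fixed
    differences of 18/29/16 plus two diagnostic indel tracks — a 3 bp
    poly-T-like insertion private to lineage L2 (so L1 and L3 are gapped
    there) and an 18 bp deletion private to lineage L3 — giving total
    pairwise fixed differences of 21, 47 and 37.  The RPB2-like locus
    diverges more modestly and carries most of the within-lineage
    polymorphism of the largest lineage.
    """
    its = LocusSpec(
        name="ITS",
        length=683,
        fixed_differences={
            frozenset({"L1", "L2"}): 18,
            frozenset({"L1", "L3"}): 29,
            frozenset({"L2", "L3"}): 16,
        },
        within_segregating={"L1": 6, "L2": 4, "L3": 2},
        indel_tracks=[
            IndelTrackSpec(start=450, length=3, gap_lineages=("L1", "L3")),
            IndelTrackSpec(start=520, length=18, gap_lineages=("L3",)),
        ],
    )
    rpb2 = LocusSpec(
        name="RPB2",
        length=422,
        fixed_differences={
            frozenset({"L1", "L2"}): 5,
            frozenset({"L1", "L3"}): 8,
            frozenset({"L2", "L3"}): 7,
        },
        within_segregating={"L1": 13, "L2": 2, "L3": 1},
    )
    lsu = LocusSpec(name="nucLSU", length=902)
    mtssu = LocusSpec(name="mtSSU", length=429)
    return SimulationConfig(
        lineages=["L1", "L2", "L3"],
        populations={"L1": {"AL": 23}, "L2": {"ML": 5}, "L3": {"DDG": 5}},
        loci=[its, rpb2, lsu, mtssu],
        mode=mode,
        seed=seed,
    )


def _solve_fixed_decomposition(
    lineages: Sequence[str], k: dict[frozenset, int]
) -> tuple[dict[str, int], int]:
    """Solve k_ij = d_i + d_j + t for non-negative integers (see module docs)."""
    if not k:
        return {l: 0 for l in lineages}, 0
    lins = [l for l in lineages]
    if len(lins) == 2:
        pair = frozenset(lins)
        return {lins[0]: 0, lins[1]: k.get(pair, 0)}, 0
    if len(lins) != 3:
        raise ConfigError("pairwise fixed differences supported for 2 or 3 lineages")
    a, b, c = lins
    kab = k.get(frozenset({a, b}), 0)
    kac = k.get(frozenset({a, c}), 0)
    kbc = k.get(frozenset({b, c}), 0)
    total = kab + kac + kbc
    t = total % 2  # parity of the sum fixes the parity of t; use the minimum
    while t <= min(kab, kac, kbc):
        da2 = kab + kac - kbc - t
        db2 = kab + kbc - kac - t
        dc2 = kac + kbc - kab - t
        if da2 >= 0 and db2 >= 0 and dc2 >= 0 and da2 % 2 == db2 % 2 == dc2 % 2 == 0:
            return {a: da2 // 2, b: db2 // 2, c: dc2 // 2}, t
        t += 2
    raise ConfigError(
        f"pairwise fixed-difference counts ({kab}, {kac}, {kbc}) admit no "
        "non-negative decomposition into private derived sites and triallelic sites"
    )


def expected_fixed_differences(cfg: SimulationConfig, locus: LocusSpec) -> dict[frozenset, int]:
    """Planted pairwise fixed-difference counts, indel columns included.

    A gap is a full state downstream, so every column of an indel track
    adds one fixed difference to each lineage pair with exactly one gapped
    member.
    """
    _solve_fixed_decomposition(cfg.lineages, locus.fixed_differences)  # validate
    out: dict[frozenset, int] = {}
    for i, l1 in enumerate(cfg.lineages):
        for l2 in cfg.lineages[i + 1 :]:
            pair = frozenset({l1, l2})
            n = locus.fixed_differences.get(pair, 0)
            for tr in locus.indel_tracks:
                if (l1 in tr.gap_lineages) != (l2 in tr.gap_lineages):
                    n += tr.length
            out[pair] = n
    return out


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    lineage: dict[str, str]  # strain -> lineage
    population: dict[str, str]
    haplotype_pairs: dict[str, dict[str, tuple[int, int]]]  # strain -> locus -> pool indices
    pedigree: dict[str, str | None]  # strain -> founder strain id (clonal) or None
    pools: dict[str, dict[str, list[str]]]  # lineage -> locus -> haplotype strings

    def to_json(self) -> str:
        payload = {
            "lineage": self.lineage,
            "population": self.population,
            "haplotype_pairs": {
                s: {l: list(p) for l, p in per.items()}
                for s, per in self.haplotype_pairs.items()
            },
            "pedigree": self.pedigree,
            "pools": self.pools,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulate_lineage_pool(cfg: SimulationConfig) -> dict[str, dict[str, list[str]]]:
    """Per-lineage, per-locus haplotype pools.

    One ancestral sequence per locus; planted fixed differences at disjoint
    random non-indel sites; within-lineage polymorphism as derived alleles
    carried by a random proper subset of the pool; indel tracks gapped in
    all pool members of their carrier lineages.
    """
    rng = np.random.default_rng(cfg.seed)
    pools: dict[str, dict[str, list[str]]] = {l: {} for l in cfg.lineages}
    for locus in cfg.loci:
        d, t = _solve_fixed_decomposition(cfg.lineages, locus.fixed_differences)
        indel_cols: set[int] = set()
        for tr in locus.indel_tracks:
            if tr.start < 1 or tr.start + tr.length - 1 > locus.length:
                raise ConfigError(f"indel track out of range in locus {locus.name!r}")
            for unknown in tr.gap_lineages:
                if unknown not in cfg.lineages:
                    raise ConfigError(f"indel track names unknown lineage {unknown!r}")
            indel_cols.update(range(tr.start - 1, tr.start - 1 + tr.length))
        budget = sum(d.values()) + t + sum(locus.within_segregating.values())
        free_sites = [j for j in range(locus.length) if j not in indel_cols]
        if budget > len(free_sites):
            raise ConfigError(
                f"locus {locus.name!r}: {budget} planted variable sites exceed the "
                f"{len(free_sites)} non-indel columns available"
            )
        ancestral = rng.choice(list(_BASES), size=locus.length)
        chosen = rng.choice(len(free_sites), size=budget, replace=False)
        sites = [free_sites[i] for i in chosen]
        at = 0

        # lineage base sequences: start from the ancestor
        lineage_seq = {l: ancestral.copy() for l in cfg.lineages}
        for l in cfg.lineages:
            for _ in range(d.get(l, 0)):
                j = sites[at]
                at += 1
                lineage_seq[l][j] = rng.choice([b for b in _BASES if b != ancestral[j]])
        for _ in range(t):
            j = sites[at]
            at += 1
            others = [b for b in _BASES if b != ancestral[j]]
            picks = rng.choice(len(others), size=2, replace=False)
            # first lineage keeps the ancestral state; the other two diverge
            lineage_seq[cfg.lineages[1]][j] = others[picks[0]]
            lineage_seq[cfg.lineages[2]][j] = others[picks[1]]
        for tr in locus.indel_tracks:
            for l in tr.gap_lineages:
                lineage_seq[l][tr.start - 1 : tr.start - 1 + tr.length] = GAP

        for l in cfg.lineages:
            base = lineage_seq[l]
            pool = [base.copy() for _ in range(cfg.pool_size)]
            if locus.within_segregating.get(l, 0) and cfg.pool_size < 2:
                raise ConfigError("within-lineage polymorphism needs pool_size >= 2")
            for _ in range(locus.within_segregating.get(l, 0)):
                j = sites[at]
                at += 1
                derived = rng.choice([b for b in _BASES if b != base[j]])
                # a random nonempty proper subset of the pool carries the allele
                k = int(rng.integers(1, cfg.pool_size))
                carriers = rng.choice(cfg.pool_size, size=k, replace=False)
                for ci in carriers:
                    pool[ci][j] = derived
            pools[l][locus.name] = ["".join(h) for h in pool]
    return pools


def _union_sequence(h1: str, h2: str, locus: str) -> str:
    """IUPAC-coded composite sequence of a dikaryon's two haplotypes."""
    out = []
    for a, b in zip(h1, h2):
        if a == b:
            out.append(a)
        elif a == GAP or b == GAP:
            raise ConfigError(
                f"locus {locus!r}: haplotypes disagree at a gap column; indels "
                "must be fixed within lineages"
            )
        else:
            out.append(encode_base_pair((a, b)))
    return "".join(out)


def simulate_population(
    pools: dict[str, dict[str, list[str]]], cfg: SimulationConfig
) -> tuple[dict[str, AlignedLocus], LineagePartition, TruthRecord]:
    """Draw strains from the lineage pools under the configured mode.

    Sexual mode unites two independently drawn haplotypes per locus
    (independent across loci: free recombination between unlinked nuclear
    fragments).  Clonal mode copies a small founder set of dikaryons with
    per-site mutation on each haplotype.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # distinct stream from the pools
    strains = cfg.strains
    hap_pairs: dict[str, dict[str, tuple[int, int]]] = {}
    pedigree: dict[str, str | None] = {}
    sequences: dict[str, dict[str, str]] = {}  # locus -> strain -> seq

    def draw_pair(lineage: str, locus: str) -> tuple[int, int]:
        pool = pools[lineage][locus]
        i, j = int(rng.integers(len(pool))), int(rng.integers(len(pool)))
        return i, j

    if cfg.mode == "sexual":
        for sid, pop, lin in strains:
            hap_pairs[sid] = {}
            pedigree[sid] = None
            for locus in cfg.loci:
                hap_pairs[sid][locus.name] = draw_pair(lin, locus.name)
    else:  # clonal
        founders_by_lineage: dict[str, list[dict[str, tuple[int, int]]]] = {}
        for lin in cfg.lineages:
            founders_by_lineage[lin] = [
                {locus.name: draw_pair(lin, locus.name) for locus in cfg.loci}
                for _ in range(cfg.n_founders)
            ]
        for sid, pop, lin in strains:
            fi = int(rng.integers(cfg.n_founders))
            pedigree[sid] = f"{lin}:founder{fi + 1}"
            hap_pairs[sid] = dict(founders_by_lineage[lin][fi])

    for locus in cfg.loci:
        sequences[locus.name] = {}
        for sid, pop, lin in strains:
            i, j = hap_pairs[sid][locus.name]
            h1 = pools[lin][locus.name][i]
            h2 = pools[lin][locus.name][j]
            if cfg.mode == "clonal" and cfg.mutation_rate > 0:
                h1 = _mutate(h1, cfg.mutation_rate, rng)
                h2 = _mutate(h2, cfg.mutation_rate, rng)
            sequences[locus.name][sid] = _union_sequence(h1, h2, locus.name)

    loci_out = {
        locus.name: AlignedLocus(
            locus.name,
            [sid for sid, _, _ in strains],
            [sequences[locus.name][sid] for sid, _, _ in strains],
        )
        for locus in cfg.loci
    }
    partition = LineagePartition({sid: (pop, lin) for sid, pop, lin in strains})
    truth = TruthRecord(
        lineage={sid: lin for sid, _, lin in strains},
        population={sid: pop for sid, pop, _ in strains},
        haplotype_pairs=hap_pairs,
        pedigree=pedigree,
        pools=pools,
    )
    return loci_out, partition, truth


def _mutate(hap: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at non-gap positions; indels never mutate."""
    chars = list(hap)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for j in hits:
        if chars[j] == GAP:
            continue
        chars[j] = rng.choice([b for b in _BASES if b != chars[j]])
    return "".join(chars)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[dict[str, AlignedLocus], LineagePartition, TruthRecord]:
    """Pools + population in one call."""
    pools = simulate_lineage_pool(cfg)
    return simulate_population(pools, cfg)


def write_dataset(
    outdir: str | Path,
    loci: dict[str, AlignedLocus],
    partition: LineagePartition,
    truth: TruthRecord,
    cfg: SimulationConfig,
) -> dict:
    """Emit FASTA per locus, partition TSV, truth JSON and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in sorted(loci):
        p = outdir / f"{name}.fasta"
        write_fasta_alignment(loci[name], p)
        paths[name] = str(p)
    write_partition(partition, outdir / "partition.tsv")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "lineages": cfg.lineages,
        "loci": {name: paths[name] for name in sorted(loci)},
        "partition": str(outdir / "partition.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# small panels for phasing-recovery and clonality-power studies


def simulate_phasing_panel(
    n_strains: int = 30,
    n_sites: int = 6,
    n_haplotypes: int = 4,
    seed: int = 0,
) -> tuple[AlignedLocus, dict[str, tuple[str, str]], list[str]]:
    """Dikaryon panel from a known haplotype pool (random union of gametes).

    Returns the IUPAC-coded locus, the true unordered haplotype pair per
    strain, and the pool.  Each site is biallelic in the pool; pool
    haplotype frequencies are drawn once from a flat Dirichlet.
    """
    rng = np.random.default_rng(seed)
    while True:
        site_alleles = [rng.choice(list(_BASES), size=2, replace=False) for _ in range(n_sites)]
        pool = set()
        tries = 0
        while len(pool) < n_haplotypes and tries < 1000:
            pool.add("".join(site_alleles[j][rng.integers(2)] for j in range(n_sites)))
            tries += 1
        if len(pool) == n_haplotypes:
            break
    pool_list = sorted(pool)
    freqs = rng.dirichlet(np.ones(n_haplotypes))
    strain_ids = [f"S{i + 1:02d}" for i in range(n_strains)]
    truth: dict[str, tuple[str, str]] = {}
    rows = []
    for sid in strain_ids:
        i = int(rng.choice(n_haplotypes, p=freqs))
        j = int(rng.choice(n_haplotypes, p=freqs))
        h1, h2 = pool_list[i], pool_list[j]
        truth[sid] = tuple(sorted((h1, h2)))  # type: ignore[assignment]
        rows.append(_union_sequence(h1, h2, "panel"))
    return AlignedLocus("panel", strain_ids, rows), truth, pool_list


def simulate_multilocus_panel(
    n_strains: int = 30,
    n_loci: int = 2,
    n_alleles: int = 5,
    mode: str = "sexual",
    n_founders: int = 5,
    mutation_rate: float = 0.01,
    seed: int = 0,
) -> tuple[MultilocusGenotypeMatrix, dict[str, str | None]]:
    """Allele-level panel for the association tests.

    Sexual mode draws the two alleles per locus independently from
    equifrequent pools, independently across loci (the free-recombination
    null).  Clonal mode first builds a gamete pool by strictly clonal
    descent — each new multilocus gamete copies an earlier one and mutates
    exactly one locus to a previously unused allele, so the gamete
    genealogy is a tree and no four-gamete quartet can exist — then founds
    ``n_founders`` dikaryons as pairs of pool gametes and copies them to
    the sample with per-allele mutation to a fresh allele label at rate
    ``mutation_rate`` (infinite-alleles style).
    """
    if mode not in ("sexual", "clonal"):
        raise ConfigError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    loci = [f"LOC{k + 1}" for k in range(n_loci)]
    strain_ids = [f"S{i + 1:02d}" for i in range(n_strains)]

    data: dict[str, dict[str, AllelePair]] = {}
    pedigree: dict[str, str | None] = {}
    if mode == "sexual":
        for sid in strain_ids:
            g: dict[str, AllelePair] = {}
            for l in loci:
                a = f"{l}.{int(rng.integers(n_alleles)) + 1}"
                b = f"{l}.{int(rng.integers(n_alleles)) + 1}"
                g[l] = tuple(sorted((a, b)))  # type: ignore[assignment]
            data[sid] = g
            pedigree[sid] = None
    else:
        # gamete genealogy: a tree with one novel-allele mutation per branch,
        # sized so every locus ends up with n_alleles alleles
        gametes: list[dict[str, str]] = [{l: f"{l}.1" for l in loci}]
        for l in loci:
            for k in range(2, n_alleles + 1):
                parent = gametes[int(rng.integers(len(gametes)))]
                child = dict(parent)
                child[l] = f"{l}.{k}"
                gametes.append(child)
        founders = []
        for _ in range(n_founders):
            g1 = gametes[int(rng.integers(len(gametes)))]
            g2 = gametes[int(rng.integers(len(gametes)))]
            founders.append(
                {l: tuple(sorted((g1[l], g2[l]))) for l in loci}
            )
        novel = 0
        for sid in strain_ids:
            fi = int(rng.integers(n_founders))
            pedigree[sid] = f"founder{fi + 1}"
            g = {l: list(founders[fi][l]) for l in loci}
            for l in loci:
                for slot in range(2):
                    if rng.random() < mutation_rate:
                        novel += 1
                        g[l][slot] = f"{l}.m{novel}"
            data[sid] = {l: tuple(sorted(g[l])) for l in loci}  # type: ignore[misc]
    return MultilocusGenotypeMatrix(strain_ids, loci, data), pedigree
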