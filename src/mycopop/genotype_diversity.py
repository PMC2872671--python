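"""Sequence genotypes and genotypic diversity.

A *genotype* here is a unique full aligned sequence string: two strains
share a genotype iff their aligned rows are identical character-for-
character, gaps and ambiguity codes included.  This treats each dikaryon's
composite (IUPAC-coded) sequence as the genotyping unit, and lets indel
differences create distinct genotypes.

Genotypic diversity is the unbiased probability that two individuals drawn
at random (without replacement) carry different genotypes:

    D = (1 - sum_i p_i^2) * n / (n - 1),   p_i = c_i / n

which is algebraically identical to 1 - sum_i c_i (c_i - 1) / (n (n - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .alignment_io import AlignedLocus
from .errors import DiversityError, PartitionError
from .partition import LineagePartition

POOLED = "_pooled"


@dataclass
class GenotypeTable:
    """Unique sequence types at one locus, tabulated per population.

    Genotype indices follow first occurrence in the input strain order, so
    they are stable given identical input order.
    """

    locus_name: str
    genotype_seqs: list[str]
    assignments: dict[str, int]  # strain -> genotype index
    populations: dict[str, list[str]]  # population -> strains, input order

    def counts(self, population: str) -> list[int]:
        """Counts c_i of each genotype observed in ``population`` (nonzero only)."""
        tally: dict[int, int] = {}
        for sid in self.populations[population]:
            g = self.assignments[sid]
            tally[g] = tally.get(g, 0) + 1
        return [tally[g] for g in sorted(tally)]

    def pooled_counts(self) -> list[int]:
        tally: dict[int, int] = {}
        for g in self.assignments.values():
            tally[g] = tally.get(g, 0) + 1
        return [tally[g] for g in sorted(tally)]

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_seqs)


@dataclass
class DiversityResult:
    population: str
    n: int
    n_genotypes: int
    diversity: float | None  # None when undefined (n < 2)


def collapse_genotypes(locus: AlignedLocus, partition: LineagePartition) -> GenotypeTable:
    """Collapse aligned rows into unique genotypes, tabulated per population.

    Identity is literal string identity over the full aligned row; an
    ambiguity code is not equal to either of its constituent bases.
    """
    seq_to_idx: dict[str, int] = {}
    genotype_seqs: list[str] = []
    assignments: dict[str, int] = {}
    populations: dict[str, list[str]] = {}
    for sid, row in zip(locus.strain_ids, locus.rows):
        if sid not in partition.assignments:
            raise PartitionError(
                f"strain {sid!r} in locus {locus.locus_name!r} is absent from the partition"
            )
        if row not in seq_to_idx:
            seq_to_idx[row] = len(genotype_seqs)
            genotype_seqs.append(row)
        assignments[sid] = seq_to_idx[row]
        populations.setdefault(partition.population(sid), []).append(sid)
    return GenotypeTable(locus.locus_name, genotype_seqs, assignments, populations)


def genotypic_diversity(counts: Sequence[int]) -> float:
    """Unbiased genotypic diversity from genotype counts.

    Raises :class:`DiversityError` unless all counts are >= 1 and they sum
    to at least 2 (a single individual has no defined diversity).
    """
    if not counts:
        raise DiversityError("empty count vector")
    if any(c < 1 for c in counts):
        raise DiversityError(f"genotype counts must all be >= 1, got {list(counts)}")
    n = sum(counts)
    if n < 2:
        raise DiversityError(f"diversity undefined for sample size {n} (< 2)")
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (1.0 - sum_p2) * n / (n - 1)


def diversity_report(table: GenotypeTable) -> list[DiversityResult]:
    """One row per population (sorted by name) plus a pooled row.

    A population of a single strain gets ``diversity=None`` rather than 0 —
    a lone individual is undefined, not monomorphic.
    """
    results: list[DiversityResult] = []
    for pop in sorted(table.populations):
        counts = table.counts(pop)
        n = sum(counts)
        d = genotypic_diversity(counts) if n >= 2 else None
        results.append(DiversityResult(pop, n, len(counts), d))
    pooled = table.pooled_counts()
    n = sum(pooled)
    d = genotypic_diversity(pooled) if n >= 2 else None
    results.append(DiversityResult(POOLED, n, len(pooled), d))
    return results


def write_diversity_report(
    table: GenotypeTable, results: list[DiversityResult], path: str | Path
) -> None:
    """TSV mirroring a per-population genotype/diversity table.

    Diversity values are rounded to 3 decimals at report time only.
    """
    with open(path, "w") as fh:
        fh.write("population\tn\tgenotypes\tgenotype_counts\tdiversity\n")
        for r in results:
            if r.population == POOLED:
                counts = table.pooled_counts()
            else:
                counts = table.counts(r.population)
            counts_s = ";".join(str(c) for c in counts)
            d_s = "undefined" if r.diversity is None else f"{r.diversity:.3f}"
            fh.write(f"{r.population}\t{r.n}\t{r.n_genotypes}\t{counts_s}\t{d_s}\n")
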