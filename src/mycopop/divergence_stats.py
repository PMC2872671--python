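"""Partitioning polymorphism between lineage pairs.

For a pair of lineages, every aligned site falls into one of:

* not segregating — at most one state in the union of both groups;
* fixed difference — both groups monomorphic, for different states;
* private polymorphism — polymorphic in one group, monomorphic in the
  other (whether or not the monomorphic state is among the polymorphic
  group's states);
* shared polymorphism — polymorphic in both groups with >= 2 states in
  common;
* unshared double polymorphism — polymorphic in both groups with < 2
  shared states (rare; kept as its own category so that every segregating
  site receives exactly one label).

Heterozygous IUPAC codes are expanded to both constituent bases before
state sets are formed — a single R-carrying strain makes its group
polymorphic at that site, matching the treatment of each dikaryon as two
alleles.  Gap characters are full states here: indels were counted among
polymorphisms in genotyping and they count here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .alignment_io import AlignedLocus, expand_char
from .errors import PartitionError
from .partition import LineagePartition

CONVENTION_NOTE = (
    "heterozygous IUPAC codes expanded to both bases before forming state sets; "
    "gap '-' treated as a state"
)


@dataclass
class DivergenceSummary:
    """Site-category counts for one lineage pair (Table-2 semantics)."""

    locus_name: str
    lineage1: str
    lineage2: str
    n_segregating: int
    n_fixed: int
    n_polym1_monom2: int
    n_polym2_monom1: int
    n_shared_polymorphic: int
    n_both_polym_unshared: int
    #: 1-based positions per category, for site-level reporting
    sites: dict[str, list[int]]


def allele_sets_per_site(
    locus: AlignedLocus, group: Iterable[str]
) -> list[frozenset[str]]:
    """Per-site state sets for a strain group, ambiguity codes expanded."""
    ids = list(group)
    if not ids:
        raise PartitionError("empty strain group")
    rows = [locus.row(s) for s in ids]
    out: list[frozenset[str]] = []
    for j in range(locus.n_sites):
        states: set[str] = set()
        for row in rows:
            states |= expand_char(row[j])
        out.append(frozenset(states))
    return out


def pairwise_divergence(
    locus: AlignedLocus,
    partition: LineagePartition,
    lineage1: str,
    lineage2: str,
) -> DivergenceSummary:
    """Classify every site for one pair of lineages.

    Only strains present in the locus alignment participate; a lineage with
    no strains in the alignment is an error.
    """
    present = set(locus.strain_ids)
    g1 = [s for s in partition.strains_in_lineage(lineage1) if s in present]
    g2 = [s for s in partition.strains_in_lineage(lineage2) if s in present]
    if not g1 or not g2:
        missing = lineage1 if not g1 else lineage2
        raise PartitionError(
            f"lineage {missing!r} has no strains in locus {locus.locus_name!r}"
        )
    sets1 = allele_sets_per_site(locus, g1)
    sets2 = allele_sets_per_site(locus, g2)

    sites: dict[str, list[int]] = {
        "fixed": [],
        "polym1_monom2": [],
        "polym2_monom1": [],
        "shared_polymorphic": [],
        "both_polym_unshared": [],
    }
    n_seg = 0
    for j, (s1, s2) in enumerate(zip(sets1, sets2)):
        if len(s1 | s2) < 2:
            continue
        n_seg += 1
        pos = j + 1
        if len(s1) == 1 and len(s2) == 1:
            sites["fixed"].append(pos)  # union >= 2 and both singletons => disjoint
        elif len(s1) > 1 and len(s2) == 1:
            sites["polym1_monom2"].append(pos)
        elif len(s1) == 1 and len(s2) > 1:
            sites["polym2_monom1"].append(pos)
        elif len(s1 & s2) >= 2:
            sites["shared_polymorphic"].append(pos)
        else:
            sites["both_polym_unshared"].append(pos)

    return DivergenceSummary(
        locus_name=locus.locus_name,
        lineage1=lineage1,
        lineage2=lineage2,
        n_segregating=n_seg,
        n_fixed=len(sites["fixed"]),
        n_polym1_monom2=len(sites["polym1_monom2"]),
        n_polym2_monom1=len(sites["polym2_monom1"]),
        n_shared_polymorphic=len(sites["shared_polymorphic"]),
        n_both_polym_unshared=len(sites["both_polym_unshared"]),
        sites=sites,
    )


def divergence_report(
    locus: AlignedLocus, partition: LineagePartition
) -> list[DivergenceSummary]:
    """All lineage pairs, ordered lexicographically."""
    lineages = [
        l
        for l in partition.lineages
        if any(s in set(locus.strain_ids) for s in partition.strains_in_lineage(l))
    ]
    out = []
    for i, l1 in enumerate(lineages):
        for l2 in lineages[i + 1 :]:
            out.append(pairwise_divergence(locus, partition, l1, l2))
    return out


def write_divergence_report(summaries: list[DivergenceSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# convention: {CONVENTION_NOTE}\n")
        fh.write(
            "locus\tlineage1\tlineage2\tsegregating\tfixed\tpolym1_monom2\t"
            "polym2_monom1\tshared_polymorphic\tboth_polym_unshared\n"
        )
        for s in summaries:
            fh.write(
                f"{s.locus_name}\t{s.lineage1}\t{s.lineage2}\t{s.n_segregating}\t"
                f"{s.n_fixed}\t{s.n_polym1_monom2}\t{s.n_polym2_monom1}\t"
                f"{s.n_shared_polymorphic}\t{s.n_both_polym_unshared}\n"
            )
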