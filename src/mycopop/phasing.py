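"""EM haplotype phasing of dikaryotic (diploid) sequence genotypes.

A directly sequenced dikaryon yields one composite sequence per locus in
which heterozygous positions appear as two-base IUPAC codes.  This module
first reduces a locus to its biallelic substitution sites
(:func:`snpify`), then resolves each strain's unordered site-wise base
pairs into a pair of haplotypes by maximizing the sample's haplotype
frequencies with an expectation-maximization algorithm (the classic
haplotype-frequency maximum-likelihood approach of Excoffier & Slatkin).

A strain heterozygous at k sites has 2^(k-1) possible unordered haplotype
resolutions; the E-step weights each by the product of current haplotype
frequencies (times 2 for heterozygous pairs), and the M-step re-estimates
frequencies from the expected haplotype counts.  The observed-data
log-likelihood is non-decreasing across iterations.  At the heterozygosity
levels this pipeline targets (a handful of heterozygous sites per strain)
the enumeration is tiny and EM converges in a few iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import GAP, AlignedLocus, expand_char
from .errors import PhasingError

MAX_HET_SITES = 12  # 2^(k-1) resolutions; hard cap to keep enumeration sane

ITS_PARALOGY_WARNING = (
    "heterozygous sites at a multi-copy rDNA locus (ITS) may reflect variation "
    "among paralogous repeats rather than the two nuclei; interpret phased "
    "haplotypes with caution"
)


@dataclass
class DiploidGenotypeMatrix:
    """Unordered base pairs at the biallelic substitution sites of a locus."""

    locus_name: str
    strain_ids: list[str]
    positions: list[int]  # 1-based alignment coordinates of retained sites
    site_alleles: list[tuple[str, str]]  # the two bases segregating per site
    genotypes: dict[str, tuple[tuple[str, str], ...]]  # strain -> sorted pairs

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def n_het_sites(self, strain_id: str) -> int:
        return sum(a != b for a, b in self.genotypes[strain_id])


def snpify(locus: AlignedLocus, strains: Sequence[str] | None = None) -> DiploidGenotypeMatrix:
    """Reduce a locus to its biallelic substitution sites for a strain subset.

    Indel columns (any gap among the selected strains) are excluded; among
    the rest, a column is retained when exactly two bases segregate after
    expanding heterozygote codes.  A column with three or more bases is an
    error — the phasing model is strictly biallelic.
    """
    ids = list(strains) if strains is not None else list(locus.strain_ids)
    if not ids:
        raise PhasingError("empty strain subset")
    rows = {s: locus.row(s) for s in ids}
    positions: list[int] = []
    site_alleles: list[tuple[str, str]] = []
    per_site_pairs: list[dict[str, tuple[str, str]]] = []
    for j in range(locus.n_sites):
        col = {s: rows[s][j] for s in ids}
        if any(c == GAP for c in col.values()):
            continue
        states: set[str] = set()
        for c in col.values():
            states |= expand_char(c)
        if len(states) < 2:
            continue
        if len(states) > 2:
            raise PhasingError(
                f"site {j + 1} of locus {locus.locus_name!r} has {len(states)} states "
                f"({'/'.join(sorted(states))}); phasing requires biallelic sites"
            )
        positions.append(j + 1)
        site_alleles.append(tuple(sorted(states)))  # type: ignore[arg-type]
        pairs = {}
        for s, c in col.items():
            exp = sorted(expand_char(c))
            pairs[s] = (exp[0], exp[-1]) if len(exp) == 2 else (exp[0], exp[0])
        per_site_pairs.append(pairs)
    genotypes = {
        s: tuple(per_site_pairs[k][s] for k in range(len(positions))) for s in ids
    }
    return DiploidGenotypeMatrix(locus.locus_name, ids, positions, site_alleles, genotypes)


@dataclass
class PhasedStrain:
    strain_id: str
    haplotypes: tuple[str, str]  # unordered; stored sorted
    posterior: float
    tied: bool  # True when two resolutions are exactly equally likely


@dataclass
class PhasedHaplotypes:
    """EM phasing output: haplotype catalogue plus per-strain best pairs."""

    locus_name: str
    haplotypes: list[str]
    frequencies: dict[str, float]
    phases: dict[str, PhasedStrain]
    log_likelihoods: list[float] = field(repr=False)
    n_iterations: int = 0
    converged: bool = True
    warnings: list[str] = field(default_factory=list)
    method: str = "EM haplotype-frequency maximum likelihood"

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def _resolutions(genotype: tuple[tuple[str, str], ...]) -> list[tuple[str, str]]:
    """All unordered haplotype pairs consistent with a site-wise genotype."""
    het_idx = [i for i, (a, b) in enumerate(genotype) if a != b]
    if len(het_idx) > MAX_HET_SITES:
        raise PhasingError(
            f"{len(het_idx)} heterozygous sites exceeds the enumeration cap of {MAX_HET_SITES}"
        )
    base = [a for a, _ in genotype]
    out: list[tuple[str, str]] = []
    if not het_idx:
        h = "".join(base)
        return [(h, h)]
    # fix the first heterozygous site to avoid double-counting unordered pairs
    free = het_idx[1:]
    for bits in range(2 ** len(free)):
        h1 = list(base)
        h2 = [b for _, b in genotype]
        h1[het_idx[0]] = genotype[het_idx[0]][0]
        h2[het_idx[0]] = genotype[het_idx[0]][1]
        for k, i in enumerate(free):
            if (bits >> k) & 1:
                h1[i], h2[i] = genotype[i][1], genotype[i][0]
            else:
                h1[i], h2[i] = genotype[i][0], genotype[i][1]
        out.append((("".join(h1)), ("".join(h2))))
    return out


def em_phase(
    matrix: DiploidGenotypeMatrix,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    seed: int = 0,
) -> PhasedHaplotypes:
    """Phase all strains by EM over population haplotype frequencies.

    Initialization is uniform over every haplotype compatible with the
    sample, perturbed by a seeded jitter of order 1e-9 so that exactly
    symmetric likelihoods resolve deterministically; genuinely tied
    resolutions are still reported with posterior 0.5 and flagged rather
    than silently broken.
    """
    if not matrix.strain_ids:
        raise PhasingError("empty genotype matrix")
    res_by_strain = {s: _resolutions(matrix.genotypes[s]) for s in matrix.strain_ids}
    hap_set: set[str] = set()
    for pairs in res_by_strain.values():
        for h1, h2 in pairs:
            hap_set.add(h1)
            hap_set.add(h2)
    haps = sorted(hap_set)
    h_index = {h: i for i, h in enumerate(haps)}
    rng = np.random.default_rng(seed)
    freqs = np.full(len(haps), 1.0 / len(haps))
    freqs = freqs + rng.uniform(0, 1e-9, size=len(haps))
    freqs /= freqs.sum()

    n = len(matrix.strain_ids)
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(len(haps))
        ll = 0.0
        for s in matrix.strain_ids:
            pairs = res_by_strain[s]
            weights = np.array(
                [
                    (2.0 if h1 != h2 else 1.0) * freqs[h_index[h1]] * freqs[h_index[h2]]
                    for h1, h2 in pairs
                ]
            )
            tot = weights.sum()
            if tot <= 0:
                # all compatible haplotypes driven to zero frequency: restart
                # this strain's mass uniformly (cannot happen from uniform init)
                weights = np.ones(len(pairs))
                tot = weights.sum()
            ll += math.log(tot)
            w = weights / tot
            for wk, (h1, h2) in zip(w, pairs):
                counts[h_index[h1]] += wk
                counts[h_index[h2]] += wk
        logliks.append(ll)
        new_freqs = counts / (2 * n)
        delta = float(np.max(np.abs(new_freqs - freqs)))
        freqs = new_freqs
        if delta < tol:
            converged = True
            break

    phases: dict[str, PhasedStrain] = {}
    for s in matrix.strain_ids:
        pairs = res_by_strain[s]
        weights = np.array(
            [
                (2.0 if h1 != h2 else 1.0) * freqs[h_index[h1]] * freqs[h_index[h2]]
                for h1, h2 in pairs
            ]
        )
        tot = weights.sum()
        post = weights / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
        best_i = int(np.argmax(post))
        best_post = float(post[best_i])
        tied = False
        if len(pairs) > 1:
            ranked = sorted(range(len(pairs)), key=lambda i: (-post[i], pairs[i]))
            best_i = ranked[0]
            second = ranked[1]
            # tolerance well above the ~1e-9 initialization jitter, far below
            # any genuine posterior separation
            if abs(post[best_i] - post[second]) < 1e-6:
                tied = True
                best_post = 0.5
            else:
                best_post = float(post[best_i])
        pair = tuple(sorted(pairs[best_i]))
        phases[s] = PhasedStrain(s, pair, best_post, tied)  # type: ignore[arg-type]

    # a haplotype actually carried by anyone has frequency >= 1/(2n) >> tol,
    # so the EM tolerance is a safe cut for numerically-dead haplotypes
    freq_map = {h: float(f) for h, f in zip(haps, freqs) if f > tol}
    # renormalize the reported catalogue after dropping zero-frequency haps
    z = sum(freq_map.values())
    freq_map = {h: f / z for h, f in freq_map.items()}
    return PhasedHaplotypes(
        locus_name=matrix.locus_name,
        haplotypes=sorted(freq_map),
        frequencies=freq_map,
        phases=phases,
        log_likelihoods=logliks,
        n_iterations=it,
        converged=converged,
    )


@dataclass
class CatalogueRow:
    haplotype: str
    frequency: float
    carriers: list[str]  # "<strain>a" / "<strain>b" labels


def haplotype_catalogue(ph: PhasedHaplotypes) -> list[CatalogueRow]:
    """Haplotypes sorted by descending frequency (ties by string).

    Carriers are labelled ``<strain>a`` and ``<strain>b`` for the two
    alleles within an individual, ``a`` being the lexicographically first
    haplotype of the pair.
    """
    carriers: dict[str, list[str]] = {h: [] for h in ph.haplotypes}
    for s in ph.phases:
        h1, h2 = ph.phases[s].haplotypes
        carriers.setdefault(h1, []).append(f"{s}a")
        if h2 == h1:
            carriers[h1].append(f"{s}b")
        else:
            carriers.setdefault(h2, []).append(f"{s}b")
    rows = [
        CatalogueRow(h, ph.frequencies.get(h, 0.0), sorted(carriers[h]))
        for h in carriers
    ]
    rows.sort(key=lambda r: (-r.frequency, r.haplotype))
    return rows


def write_phased_tsv(ph: PhasedHaplotypes, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# method: {ph.method}\n")
        for w in ph.warnings:
            fh.write(f"# warning: {w}\n")
        fh.write("strain\tallele_a\tallele_b\tposterior\ttied\n")
        for s in ph.phases:
            p = ph.phases[s]
            fh.write(
                f"{s}\t{p.haplotypes[0]}\t{p.haplotypes[1]}\t{p.posterior:.6f}\t"
                f"{'yes' if p.tied else 'no'}\n"
            )


def write_haplotype_fasta(ph: PhasedHaplotypes, path: str | Path) -> None:
    """Per-strain phased alleles as FASTA, labelled <strain>a / <strain>b."""
    with open(path, "w") as fh:
        for s in ph.phases:
            h1, h2 = ph.phases[s].haplotypes
            fh.write(f">{s}a\n{h1}\n>{s}b\n{h2}\n")
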