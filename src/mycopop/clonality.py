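"""Multilocus association tests for clonality vs recombination.

Given per-strain unordered allele pairs at two or more loci (alleles are
haplotype identifiers produced by phasing), two classic signals of the mode
of reproduction are computed:

* the **index of association** I_A — a variance-ratio statistic over
  pairwise strain distances.  With per-locus distance δ = 0 / 0.5 / 1 for
  two / one / zero shared alleles and total distance d = Σ_l δ_l,
  I_A = V_O / V_E − 1, where V_O is the variance of d over all strain
  pairs and V_E = Σ_l V_l the summed per-locus variances.  Under free
  recombination loci are independent, V_O ≈ V_E, and I_A ≈ 0; clonality
  inflates V_O.  The standardized form
  rbarD = (V_O − V_E) / (2 Σ_{l<m} sqrt(V_l V_m)) lies in [−1, 1].
  Significance comes from a permutation null that shuffles single-locus
  genotypes among strains independently at each locus.

* **phylogenetic incompatibility** between locus pairs — for a pair of
  alleles at each locus, the presence of all four allelic combinations is
  impossible under strict clonality without recurrent mutation, so each
  fully evidenced quartet is direct evidence of recombination.  Because a
  doubly heterozygous strain has ambiguous cross-locus phase, a
  combination only counts as evidenced when it is present under every
  possible pairing of the strain's alleles (in practice: when at least one
  of the two loci is homozygous in the witness strain).

Variances use the population convention (denominator = number of pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ClonalityError
from .phasing import PhasedHaplotypes

DISTANCE_CONVENTION = (
    "per-locus distance 0 (identical unordered pairs) / 0.5 (one shared allele) "
    "/ 1 (no shared allele); variances over strain pairs with denominator = "
    "number of pairs; null permutes single-locus genotypes among strains "
    "independently at each locus"
)

AllelePair = tuple[str, str]


@dataclass
class MultilocusGenotypeMatrix:
    """Per-strain, per-locus unordered allele pairs (locus-scoped labels)."""

    strain_ids: list[str]
    loci: list[str]
    data: dict[str, dict[str, AllelePair]]  # strain -> locus -> sorted pair
    populations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.strain_ids:
            if s not in self.data:
                raise ClonalityError(f"strain {s!r} missing from genotype data")
            for l in self.loci:
                if l not in self.data[s]:
                    raise ClonalityError(f"strain {s!r} has no genotype at locus {l!r}")
                a, b = self.data[s][l]
                self.data[s][l] = tuple(sorted((a, b)))  # type: ignore[assignment]

    def pair(self, strain: str, locus: str) -> AllelePair:
        return self.data[strain][locus]

    def multilocus_genotype(self, strain: str) -> tuple[AllelePair, ...]:
        return tuple(self.data[strain][l] for l in self.loci)


def from_phased(phased: dict[str, PhasedHaplotypes]) -> MultilocusGenotypeMatrix:
    """Assemble a multilocus matrix from per-locus phasing results.

    Haplotype strings are relabelled to locus-scoped allele identifiers
    "<locus>.<k>" in catalogue order.
    """
    loci = sorted(phased)
    strain_sets = [set(phased[l].phases) for l in loci]
    strains = sorted(set.intersection(*strain_sets))
    if not strains:
        raise ClonalityError("no strain is phased at every locus")
    data: dict[str, dict[str, AllelePair]] = {s: {} for s in strains}
    for l in loci:
        labels = {h: f"{l}.{i + 1}" for i, h in enumerate(sorted(phased[l].haplotypes))}
        for s in strains:
            h1, h2 = phased[l].phases[s].haplotypes
            for h in (h1, h2):
                if h not in labels:  # best pair may use a haplotype dropped at freq ~0
                    labels[h] = f"{l}.{len(labels) + 1}"
            data[s][l] = tuple(sorted((labels[h1], labels[h2])))  # type: ignore[assignment]
    return MultilocusGenotypeMatrix(strains, loci, data)


def pairwise_distance(
    g1: Sequence[AllelePair], g2: Sequence[AllelePair]
) -> tuple[list[float], float]:
    """Per-locus 0/0.5/1 allele-sharing distances and their sum."""
    if len(g1) != len(g2):
        raise ClonalityError("genotypes cover different locus lists")
    deltas = [_delta(a, b) for a, b in zip(g1, g2)]
    return deltas, float(sum(deltas))


def _delta(p1: AllelePair, p2: AllelePair) -> float:
    shared = 0
    pool = list(p2)
    for a in p1:
        if a in pool:
            pool.remove(a)
            shared += 1
    return 1.0 - shared / 2.0


def _delta_matrix(matrix: MultilocusGenotypeMatrix, locus: str) -> np.ndarray:
    n = len(matrix.strain_ids)
    D = np.zeros((n, n))
    pairs = [matrix.pair(s, locus) for s in matrix.strain_ids]
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _delta(pairs[i], pairs[j])
    return D


def _pair_variance(D: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], k=1)
    vals = D[iu]
    return float(vals.var())  # population convention: denominator = n_pairs


@dataclass
class IAResult:
    ia: float
    rbar_d: float
    null: np.ndarray = field(repr=False)
    p_value: float
    n_permutations: int
    seed: int
    n_strains: int
    loci_used: list[str]
    excluded_loci: list[str]
    convention: str = DISTANCE_CONVENTION


def index_of_association(
    matrix: MultilocusGenotypeMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    clone_correct: bool = False,
    exhaustive: bool = False,
) -> IAResult:
    """I_A and rbarD with a per-locus permutation null.

    Loci at which every strain carries the identical unordered pair are
    uninformative (all δ = 0) and are excluded with a note; if no locus
    remains the test is an error.  The p-value counts the observed
    arrangement in both numerator and denominator, so it can never be 0.
    With ``exhaustive`` set, every combination of per-locus strain
    relabelings is enumerated instead of sampled (feasible only for ~5
    strains and 2 loci); ``n_permutations`` is then ignored.

    By default strains with identical multilocus genotypes are retained
    (no clone correction); ``clone_correct`` collapses them first.
    """
    strains = list(matrix.strain_ids)
    if clone_correct:
        seen: dict[tuple, str] = {}
        for s in strains:
            seen.setdefault(matrix.multilocus_genotype(s), s)
        strains = [s for s in strains if seen[matrix.multilocus_genotype(s)] == s]
        matrix = MultilocusGenotypeMatrix(
            strains, matrix.loci, {s: dict(matrix.data[s]) for s in strains}, matrix.populations
        )
    n = len(strains)
    if n < 4:
        raise ClonalityError(f"need >= 4 strains, got {n}")

    loci_used, excluded = [], []
    deltas: list[np.ndarray] = []
    for l in matrix.loci:
        D = _delta_matrix(matrix, l)
        if np.all(D == 0):
            excluded.append(l)
        else:
            loci_used.append(l)
            deltas.append(D)
    if not loci_used:
        raise ClonalityError("all loci are monomorphic across strains")

    def ia_of(ds: list[np.ndarray]) -> tuple[float, float]:
        total = sum(ds)
        v_o = _pair_variance(total)
        v_l = [_pair_variance(D) for D in ds]
        v_e = sum(v_l)
        ia = v_o / v_e - 1.0
        cross = sum(
            np.sqrt(v_l[i] * v_l[j])
            for i in range(len(v_l))
            for j in range(i + 1, len(v_l))
        )
        rbar = (v_o - v_e) / (2.0 * cross) if cross > 0 else float("nan")
        return ia, rbar

    ia_obs, rbar_obs = ia_of(deltas)

    # per-locus variances are label-permutation invariant, so only V_O moves
    rng = np.random.default_rng(seed)
    null_vals: list[float] = []
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        for combo in itertools.product(perms, repeat=len(deltas)):
            total = sum(
                D[np.ix_(p, p)] for D, p in zip(deltas, combo)
            )
            v_o = _pair_variance(total)
            null_vals.append(v_o / sum(_pair_variance(D) for D in deltas) - 1.0)
        null = np.array(null_vals)
        p = float(np.mean(null >= ia_obs - 1e-12))  # observed identity is in the enumeration
        return IAResult(
            ia_obs, rbar_obs, null, p, len(null), seed, n, loci_used, excluded
        )

    v_e = sum(_pair_variance(D) for D in deltas)
    for _ in range(n_permutations):
        total = np.zeros((n, n))
        for D in deltas:
            p = rng.permutation(n)
            total += D[np.ix_(p, p)]
        null_vals.append(_pair_variance(total) / v_e - 1.0)
    null = np.array(null_vals)
    p_value = (1 + int(np.sum(null >= ia_obs))) / (n_permutations + 1)
    return IAResult(
        ia_obs, rbar_obs, null, p_value, n_permutations, seed, n, loci_used, excluded
    )


@dataclass
class IncompatibleQuartet:
    locus1_alleles: tuple[str, str]
    locus2_alleles: tuple[str, str]
    witnesses: dict[tuple[str, str], list[str]]  # combo -> strains evidencing it


@dataclass
class CompatibilityReport:
    locus1: str
    locus2: str
    quartets: list[IncompatibleQuartet]

    @property
    def incompatible(self) -> bool:
        return bool(self.quartets)


def phylogenetic_compatibility(
    matrix: MultilocusGenotypeMatrix, locus1: str, locus2: str
) -> CompatibilityReport:
    """Four-gamete-style incompatibility between two loci.

    A cross-locus allele combination (a, b) is *evidenced* by a strain when
    it occurs under every possible pairing of the strain's alleles at the
    two loci — i.e. when the strain carries a and b and is homozygous at at
    least one of the loci.  A quartet {a1,a2} x {b1,b2} is flagged when all
    four combinations are evidenced.
    """
    for l in (locus1, locus2):
        if l not in matrix.loci:
            raise ClonalityError(f"locus {l!r} not in matrix")
    combo_witnesses: dict[tuple[str, str], list[str]] = {}
    for s in matrix.strain_ids:
        x1, x2 = matrix.pair(s, locus1)
        y1, y2 = matrix.pair(s, locus2)
        pairing_a = {(x1, y1), (x2, y2)}
        pairing_b = {(x1, y2), (x2, y1)}
        for combo in pairing_a & pairing_b:
            combo_witnesses.setdefault(combo, []).append(s)

    alleles1 = sorted({a for s in matrix.strain_ids for a in matrix.pair(s, locus1)})
    alleles2 = sorted({a for s in matrix.strain_ids for a in matrix.pair(s, locus2)})
    quartets: list[IncompatibleQuartet] = []
    for a1, a2 in itertools.combinations(alleles1, 2):
        for b1, b2 in itertools.combinations(alleles2, 2):
            combos = [(a1, b1), (a1, b2), (a2, b1), (a2, b2)]
            if all(c in combo_witnesses for c in combos):
                quartets.append(
                    IncompatibleQuartet(
                        (a1, a2), (b1, b2), {c: combo_witnesses[c] for c in combos}
                    )
                )
    return CompatibilityReport(locus1, locus2, quartets)


def write_ia_report(result: IAResult, path: str | Path) -> None:
    """JSON report of the association test."""
    import json

    payload = {
        "ia": result.ia,
        "rbar_d": None if np.isnan(result.rbar_d) else result.rbar_d,
        "p_value": result.p_value,
        "n_permutations": result.n_permutations,
        "null_min": float(result.null.min()) if result.null.size else None,
        "null_max": float(result.null.max()) if result.null.size else None,
        "seed": result.seed,
        "n_strains": result.n_strains,
        "loci_used": result.loci_used,
        "excluded_loci": result.excluded_loci,
        "convention": result.convention,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_compatibility_report(report: CompatibilityReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus1_alleles\tlocus2_alleles\tcombination\twitnesses\n")
        for q in report.quartets:
            for combo, strains in sorted(q.witnesses.items()):
                fh.write(
                    f"{'/'.join(q.locus1_alleles)}\t{'/'.join(q.locus2_alleles)}\t"
                    f"{combo[0]}+{combo[1]}\t{';'.join(sorted(strains))}\n"
                )
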