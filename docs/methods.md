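# Methods

`mycopop` analyses multilocus Sanger-style sequence data from dikaryotic
fungi — organisms that carry two haploid nuclei per cell, so that direct
sequencing of a specimen yields one composite sequence per locus in which
sites where the two nuclei differ appear as two-base IUPAC ambiguity codes
(T/C = Y, A/G = R, A/C = M, G/T = K, A/T = W, C/G = S). The pipeline takes
per-locus aligned FASTA plus a strain→(population, lineage) table and
produces: genotype and diversity tables, lineage divergence statistics,
maximum-parsimony genealogies with concordance tests, phased haplotypes,
and clonality/recombination tests. This note describes each model, its
assumptions, the tunable parameters, and the deliberate numerical choices.

## Alignment model and site classification

The canonical alignment stores upper-case A/C/G/T, the six two-base codes
above, and `-` as the only gap character (`.` is rejected loudly — one
dialect, no silent guessing). Three- and four-fold codes (B, D, H, V, N)
are rejected because the biallelic-heterozygote model is the only
within-strain polymorphism the pipeline represents; data containing them
should be resolved upstream.

Columns are classified into three exclusive classes: *invariant*,
*substitution* (no gaps, ≥ 2 base states after expanding heterozygote
codes into both constituent bases), and *indel* (any gap — gap takes
precedence; base variation inside a gapped column is preserved in a
per-column detail record). Maximal runs of consecutive indel columns form
*tracks*, each treated as one insertion/deletion event region. All site
coordinates in reports are 1-based inclusive.

## Genotypes and genotypic diversity

A genotype is a full aligned row compared by literal string identity —
gaps and ambiguity codes included, so an indel difference or a Y-vs-T
difference creates a distinct genotype. This treats each dikaryon's
composite sequence as the genotyping unit.

Genotypic diversity is the unbiased probability that two individuals drawn
without replacement differ in genotype:

    D = (1 − Σ p_i²) · n/(n − 1),   p_i = c_i/n,

identically 1 − Σ c_i(c_i − 1)/(n(n − 1)). Full precision is kept
internally; table output rounds to 3 decimals. A population of one strain
reports D as *undefined*, never 0 — a lone individual carries no
information about diversity.

## Lineage divergence (segregating-site partition)

For each pair of lineages, per-site state sets are formed per group after
expanding heterozygote codes (a single R-carrying strain makes its group
polymorphic — each dikaryon contributes two alleles); gaps are full
states here because indels count among polymorphisms. A site is
*segregating* when the union of the two groups' sets has ≥ 2 states, and
then receives exactly one label: *fixed* (both groups monomorphic,
different states), *private polymorphism* in one group (polymorphic there,
monomorphic in the other — whether or not the monomorphic state is among
the polymorphic group's states), *shared polymorphism* (both polymorphic,
≥ 2 common states), or the rare *both polymorphic, unshared* remainder,
kept as its own category so the partition is exhaustive and exclusive.
Each report prints the expansion/gap convention it used.

## Maximum parsimony

Characters are alignment columns encoded as 4-bit state masks over
{A, C, G, T}: heterozygote codes become the union of their bases, gaps are
missing data (all bits set) — indel signal lives in the genotyping and
divergence modules, not in tree length. Scoring is Fitch's state-set
algorithm, vectorized across characters, on unrooted binary trees rooted
arbitrarily along one edge (the score is rooting-invariant).

Per character, the minimum possible steps m on *any* topology equal (size
of the smallest state set intersecting every non-missing leaf mask) − 1,
and the maximum g is the star-tree score (n_eff minus the best
single-state count). These give the consistency index CI = Σm/Σs and
retention index RI = (Σg − Σs)/(Σg − Σm). Parsimony-uninformative
characters (g = m) inflate CI but cancel in RI, so CI is reported both
with and without them; both indices are NaN when their denominators vanish
(e.g. a zero-length tree).

Search is exact below 8 taxa — every unrooted topology is enumerated
(10 395 at 8 taxa), so small searches cannot stop at local optima — and
heuristic beyond: random-addition stepwise starting trees followed by
first-improvement NNI hill-climbing. All equally-short distinct topologies
found are returned, ordered by a lexicographic bipartition encoding; every
stochastic choice flows through one seeded generator, so results are
reproducible bit-for-bit. Characters that cost zero on every topology are
dropped before searching (no effect on any length).

Bootstrap support resamples columns with replacement, re-searches, and
reports the percentage of replicates containing each bipartition of the
original best tree; with no variable sites no supports are reported.
Resampling is indexed by column, so supports do not depend on strain input
order.

The partition homogeneity (ILD) test sums best lengths of each locus'
variable characters and compares against random repartitions of the pooled
characters into blocks of the original sizes; p is the fraction of
arrangements (observed included, so p > 0) with summed length ≤ observed.
Conflicting partitions put the observed sum in the low tail.

The concordance (constrained) search forces given disjoint groups to be
monophyletic — candidate insertions and NNI moves that break a group are
rejected, and the exact branch simply filters enumerated topologies. The
reported Δ = constrained − unconstrained length is ≥ 0 by construction
(the constrained optimum also enters the unconstrained comparison). The
optional significance level permutes each character's states among taxa
independently and recomputes Δ; this interprets a "topology-dependent
permutation test" whose published procedure is underspecified, and is
labelled as such.

## Haplotype phasing (EM)

Phasing reduces a locus to its biallelic substitution sites for the strain
set under study (indel columns excluded; a triallelic site is an error,
not a warning — the model is strictly biallelic) and resolves each
strain's unordered site-wise base pairs into a haplotype pair by
maximum-likelihood haplotype frequencies, i.e. the classic
Excoffier–Slatkin EM for multi-site genotypes. A strain with k
heterozygous sites has 2^(k−1) unordered resolutions (capped at k = 12;
real dikaryon data of this kind has single-digit k). The E-step weights
each resolution by 2^het·f(h₁)f(h₂); the M-step re-estimates frequencies
from expected counts. The observed-data log-likelihood is non-decreasing
and is recorded per iteration so tests can assert it.

Defaults: uniform initial frequencies over all sample-compatible
haplotypes with a seeded jitter of order 1e-9 (deterministic resolution of
exact symmetries), tolerance 1e-8 on the largest frequency change,
max 10 000 iterations. Genuinely tied resolutions are reported at
posterior 0.5 and flagged, never silently broken; the tie tolerance (1e-6)
sits far above the jitter and far below any real separation. Haplotypes
whose converged frequency falls below the tolerance are numerically dead
(anything actually carried has frequency ≥ 1/(2n)) and are pruned from the
catalogue. EM is a deterministic substitute for Bayesian phasing samplers;
the output records the method used. Phased output at a multi-copy rDNA
locus (ITS) carries a warning that heterozygous sites may reflect
paralogous repeats rather than the two nuclei.

## Clonality and recombination tests

The index of association works on per-strain unordered allele pairs
(alleles = phased haplotype identifiers, locus-scoped). Per-locus distance
between strains is 0 / 0.5 / 1 for two / one / zero shared alleles;
total distance is the sum over loci. I_A = V_O/V_E − 1 with V_O the
variance of total distance over all strain pairs and V_E the summed
per-locus variances; rbarD standardizes by 2 Σ_{l<m} √(V_l V_m).
Variances use the population convention (denominator = number of pairs),
printed in every report. The null shuffles single-locus genotypes among
strains independently at each locus — per-locus variances are invariant
under this, so only V_O moves, and the permutation is implemented as
simultaneous row/column permutation of precomputed per-locus distance
matrices. p counts the observed arrangement in numerator and denominator
(conservative, never 0); for ~5 strains an exact mode enumerates all
per-locus relabelings. Loci where every strain carries the identical pair
are uninformative and are excluded with a note. Strains with identical
multilocus genotypes are retained by default (no clone correction; a flag
collapses them).

Phylogenetic incompatibility flags an allele quartet {a₁,a₂}×{b₁,b₂} when
all four cross-locus combinations are *evidenced*. A combination is
evidenced by a strain only when it occurs under every possible pairing of
that strain's alleles across the two loci — in practice, when at least one
locus is homozygous in the witness; a doubly heterozygous strain has
ambiguous cross-locus phase and evidences nothing. All four combinations
cannot coexist on a mutation tree without recurrent mutation, so each
flagged quartet (with its witness strains) is direct evidence of
recombination.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular organism's sequence content: a few deeply divergent
lineages with planted fixed differences, within-lineage polymorphism,
lineage-diagnostic indel tracks, invariant loci, and dikaryotic
heterozygosity arising from the reproduction model. Everything is a pure
function of the configuration (seed mandatory).

Planting exact pairwise fixed-difference counts among three lineages is
not possible site-by-site: at any site where two lineages differ, the
third matches one of them or differs from both, so each such site is a
fixed difference for at least two pairs. Requested counts k_ij are
therefore decomposed as k_ij = d_i + d_j + t (d_i = sites with a private
derived allele in lineage i; t = triallelic sites, chosen minimal with the
right parity); infeasible requests raise a configuration error. Planted
sites are drawn without replacement from non-indel columns; overflow of
the site budget is an error. Indel tracks are fixed within their carrier
lineages, so a track with exactly one gapped member per pair adds its
length to that pair's fixed differences (gaps are states downstream);
`expected_fixed_differences` returns these totals for truth-checking.

Within-lineage polymorphism scatters one derived allele per configured
site across a random nonempty proper subset of the lineage's haplotype
pool (default pool size 4). Sexual mode unites two independent draws from
the pool per locus, independently across loci — free recombination between
unlinked fragments; intra-locus recombination is not modelled because the
tests operate at the locus level. Clonal mode copies founder dikaryons
with per-site substitution on each haplotype; indels never mutate.

The default configuration mirrors a realistic single-collection study:
33 strains in 3 lineages (23/5/5 across three named populations), an
ITS-like locus of 683 columns with substitution fixed differences 18/29/16
plus a 3 bp and an 18 bp diagnostic indel track (pairwise totals 21/47/37
— the tens scale typical of congeneric fungal lineages), an RPB2-like
locus of 422 columns carrying most within-lineage polymorphism (13
segregating sites in the large lineage), and two invariant rDNA-like loci
(902 and 429 columns). Heterozygosity then emerges at a handful of sites
per strain, as in real dikaryon panels.

Two desk-scale panels drive the statistical validation. The phasing panel
draws dikaryons by random union from a known haplotype pool (frequencies
from a flat Dirichlet; each site biallelic). The allele-level multilocus
panel has a sexual mode (equifrequent alleles, independent across loci —
the exact null of the association test) and a strictly clonal mode whose
gamete pool is generated on a tree genealogy with one novel-allele
mutation per branch: a pool built that way provably cannot span a
four-gamete quartet, which is precisely the null the incompatibility test
assumes. (Founders built by random union would legitimately contain all
four gamete types — recombination in the founding history — and would
make a "clonal" population look recombining to the test; this is a
modelling requirement, not a tuning choice.) Sample-level mutation in
clonal mode creates fresh (infinite-alleles) labels.

What passing tests on these panels do *not* show about real data: the
generator has no rate heterogeneity, no intra-locus recombination, no
homoplasy in indels, no paralogous gene copies (the very caveat attached
to ITS phasing), and lineage sizes/polymorphism levels are configured, not
emergent. Power and calibration results transfer to real data only to the
extent those assumptions hold.

## Pipeline determinism and degenerate inputs

Each pipeline stage is a pure function of (inputs, parameters, seed);
reruns are byte-identical, which the tests assert. All randomness in a
stage flows through one generator seeded from the run seed, recorded in
the manifest together with inputs, parameters, warnings (e.g. the ITS
paralogy caveat) and output names. Phasing and the association tests run
on one focal population (the largest by default, configurable): the
within-population design keeps sites biallelic, whereas between-lineage
sites may legitimately carry three states. Degenerate inputs are handled
explicitly rather than silently: loci with < 4 strains skip tree building,
invariant loci report one haplotype and are excluded from the association
test, zero-variable-site bootstraps report no support values, and any
stage failure aborts the run with the stage name, leaving completed
outputs plus a FAILED marker.

## Problem sizes used in validation

The shipped test suite validates at desk scale: exhaustive diversity
checks to n = 12; a 200-case parsimony fuzz suite at ≤ 6 taxa against an
independent exhaustive Sankoff oracle; exact I_A permutation enumeration
at 5 strains; 200 seeds per reproduction mode for calibration (KS
uniformity of p under the sexual null at α = 0.01) and power (p < 0.05 in
≥ 90% of clonal replicates at 30 strains, 2 loci, 5 alleles); phasing
recovery over 10 seeded 30-strain panels (≥ 95% of strains correct); and
full-pipeline truth recovery on the default 33-strain three-lineage
dataset. These sizes were chosen so the whole suite runs in about a
minute and a half on one core while still pinning every statistic to an
independent oracle or a known truth.
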