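"""Aligned FASTA input/output and alignment-column classification.

Sequences here are direct (Sanger-style) reads of dikaryotic fungal
specimens: each strain carries two haploid nuclei, so a position where the
two nuclei differ appears in the chromatogram as a two-base IUPAC ambiguity
code (T/C = Y, A/G = R, A/C = M, G/T = K, A/T = W, C/G = S).  This module
keeps those codes intact in the canonical matrix — downstream modules decide
whether to expand them into allele pairs.

Columns of an alignment are classified into three mutually exclusive
classes:

* ``invariant``    — one state after expanding ambiguity codes, no gaps;
* ``substitution`` — no gaps, two or more base states;
* ``indel``        — at least one gap character.

Maximal runs of consecutive indel columns are grouped into *tracks*, each
track representing a single insertion/deletion event region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AmbiguityCodeError

GAP = "-"
BASES = frozenset("ACGT")

#: Two-base IUPAC ambiguity codes and their constituent bases.
AMBIGUITY_TO_BASES: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "M": frozenset("AC"),
    "K": frozenset("GT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
}

#: Inverse map: unordered base pair -> ambiguity code.
BASES_TO_AMBIGUITY: dict[frozenset[str], str] = {
    v: k for k, v in AMBIGUITY_TO_BASES.items()
}

#: Codes denoting three- or four-fold degeneracy; deliberately unsupported.
UNSUPPORTED_CODES = frozenset("BDHVN")

VALID_CHARS = BASES | set(AMBIGUITY_TO_BASES) | {GAP}


def decode_ambiguity(code: str) -> frozenset[str]:
    """Return the unordered base pair encoded by ``code``.

    A plain base maps to a singleton set (a homozygous site); a two-base
    ambiguity code maps to its two constituent bases.  Three- and four-fold
    codes (B, D, H, V, N) are rejected: biallelic heterozygosity is the only
    within-strain polymorphism this pipeline models.
    """
    c = code.upper()
    if c in BASES:
        return frozenset((c,))
    if c in AMBIGUITY_TO_BASES:
        return AMBIGUITY_TO_BASES[c]
    if c in UNSUPPORTED_CODES:
        raise AmbiguityCodeError(
            f"ambiguity code {code!r} denotes more than two bases and is not supported"
        )
    raise AmbiguityCodeError(f"{code!r} is not a base or two-base IUPAC code")


def encode_base_pair(bases: Iterable[str]) -> str:
    """Inverse of :func:`decode_ambiguity`: unordered base pair -> character."""
    s = frozenset(b.upper() for b in bases)
    if len(s) == 1:
        (b,) = s
        if b in BASES or b == GAP:
            return b
        raise AmbiguityCodeError(f"cannot encode {s!r}")
    if s in BASES_TO_AMBIGUITY:
        return BASES_TO_AMBIGUITY[s]
    raise AmbiguityCodeError(f"cannot encode base set {sorted(s)!r} as a single character")


def expand_char(c: str) -> frozenset[str]:
    """State set of one matrix character: gap is its own state, codes expand."""
    if c == GAP:
        return frozenset((GAP,))
    return decode_ambiguity(c)


@dataclass
class AlignedLocus:
    """One locus's aligned sequence matrix.

    rows are strains, columns aligned sites; characters are upper-case
    A/C/G/T, two-base IUPAC codes, or the gap character '-'.
    """

    locus_name: str
    strain_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.strain_ids) != len(self.rows):
            raise AlignmentError("strain_ids and rows differ in length")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = {s for s in self.strain_ids if self.strain_ids.count(s) > 1}
            raise AlignmentError(f"duplicate strain ids: {sorted(dupes)}")
        if not self.rows:
            raise AlignmentError("empty alignment")
        n = len(self.rows[0])
        self.rows = [r.upper() for r in self.rows]
        for sid, row in zip(self.strain_ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, expected {n}"
                )
            for j, c in enumerate(row):
                if c not in VALID_CHARS:
                    raise AlignmentError(
                        f"illegal character {c!r} in record {sid!r} at position {j + 1}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def row(self, strain_id: str) -> str:
        try:
            return self.rows[self.strain_ids.index(strain_id)]
        except ValueError:
            raise AlignmentError(f"strain {strain_id!r} not in locus {self.locus_name!r}")

    def column(self, j: int) -> list[str]:
        """Characters of 0-based column ``j``, in strain order."""
        return [r[j] for r in self.rows]

    def subset(self, strain_ids: Iterable[str]) -> "AlignedLocus":
        ids = list(strain_ids)
        return AlignedLocus(self.locus_name, ids, [self.row(s) for s in ids])


def read_fasta_alignment(path: str | Path, locus_name: str) -> AlignedLocus:
    """Read one aligned FASTA file into a validated :class:`AlignedLocus`.

    Record order is preserved and characters are upper-cased.  Raises
    :class:`AlignmentError` on ragged rows or illegal characters.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 FASTA records, got {len(records)}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return AlignedLocus(locus_name, ids, rows)


def write_fasta_alignment(locus: AlignedLocus, path: str | Path) -> None:
    """Write the locus back to aligned FASTA (round-trips with the reader)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(locus.strain_ids, locus.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


@dataclass
class SiteDetail:
    """Per-column record: 1-based position, class, observed states."""

    position: int
    site_class: str  # invariant | substitution | indel
    states: frozenset[str]
    #: for indel columns only: do the non-gap characters also vary?
    substitution_within_gapped: bool = False


@dataclass
class SiteClassification:
    """Column classes for one locus, with indel-track grouping.

    ``indel_tracks`` are maximal runs of consecutive indel columns, recorded
    as (start, end, length) with 1-based inclusive coordinates.
    """

    locus_name: str
    site_classes: list[str]
    indel_tracks: list[tuple[int, int, int]]
    details: list[SiteDetail] = field(repr=False, default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_classes)

    @property
    def n_substitution(self) -> int:
        return sum(c == "substitution" for c in self.site_classes)

    @property
    def n_indel_sites(self) -> int:
        return sum(c == "indel" for c in self.site_classes)

    @property
    def n_variable(self) -> int:
        return self.n_substitution + self.n_indel_sites

    @property
    def n_indel_tracks(self) -> int:
        return len(self.indel_tracks)


def classify_sites(locus: AlignedLocus) -> SiteClassification:
    """Classify every column as invariant, substitution, or indel.

    Ambiguity codes are expanded to their two bases before judging
    variability, so a column that is all-A except for one R (= A/G) counts
    as a substitution column.  Any gap makes a column an indel column (gap
    takes precedence); base variation inside a gapped column is still
    recorded in the per-column detail.
    """
    classes: list[str] = []
    details: list[SiteDetail] = []
    for j in range(locus.n_sites):
        col = locus.column(j)
        states: set[str] = set()
        base_states: set[str] = set()
        has_gap = False
        for c in col:
            s = expand_char(c)
            states |= s
            if c == GAP:
                has_gap = True
            else:
                base_states |= s
        if has_gap:
            cls = "indel"
            sub_within = len(base_states) >= 2
        else:
            cls = "substitution" if len(states) >= 2 else "invariant"
            sub_within = False
        classes.append(cls)
        details.append(SiteDetail(j + 1, cls, frozenset(states), sub_within))

    tracks: list[tuple[int, int, int]] = []
    start = None
    for j, cls in enumerate(classes + ["invariant"]):  # sentinel flushes last run
        if cls == "indel" and start is None:
            start = j
        elif cls != "indel" and start is not None:
            tracks.append((start + 1, j, j - start))
            start = None
    return SiteClassification(locus.locus_name, classes, tracks, details)


def write_site_report(sc: SiteClassification, path: str | Path) -> None:
    """TSV site report, 1-based positions: position, class, states."""
    with open(path, "w") as fh:
        fh.write("position\tclass\tstates\n")
        for d in sc.details:
            fh.write(f"{d.position}\t{d.site_class}\t{'/'.join(sorted(d.states))}\n")


def fasta_string(locus: AlignedLocus) -> str:
    """The locus as FASTA text (used for byte-identical manifests)."""
    buf = io.StringIO()
    SeqIO.write(
        [SeqRecord(Seq(r), id=s, description="") for s, r in zip(locus.strain_ids, locus.rows)],
        buf,
        "fasta",
    )
    return buf.getvalue()
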