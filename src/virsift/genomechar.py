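"""Viral genome characterization.

Given a (candidate) viral genome sequence this module finds open reading
frames on both strands, selects a non-overlapping cistron set, partitions the
genome into 5'UTR / ORFs / intergenic regions / 3'UTR, computes base
composition and coding coverage, and classifies coding completeness.

Conventions
-----------
* Coordinates are 1-based inclusive on the forward strand of the input
  sequence, regardless of the strand an ORF lies on.
* An ORF span runs from the A of the start codon through the last base of the
  stop codon, so a span of ``L`` nucleotides encodes ``L/3 - 1`` amino acids.
* Composition is reported over non-N bases with RNA (U) lettering, because
  the genomes of interest are ssRNA viruses even though sequencing data are
  in the DNA alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import CompositionError, CoordinateError, InputError, StructureError
from .seqio import SeqRecord

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class Orf:
    """An open reading frame; span includes both the start and stop codons."""

    start: int
    end: int
    strand: str
    peptide: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise CoordinateError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise CoordinateError(f"bad ORF span ({self.start}, {self.end})")
        if (self.end - self.start + 1) % 3:
            raise CoordinateError(
                f"ORF span ({self.start}, {self.end}) is not a whole number of codons"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def aa_len(self) -> int:
        return self.span // 3 - 1


class BaseComposition(NamedTuple):
    frac_a: float
    frac_u: float
    frac_c: float
    frac_g: float
    gc_pct: float


@dataclass
class GenomeAnnotation:
    """A characterized viral genome, mirroring a genome-table row."""

    genome_id: str
    length_bp: int
    sense: str  # positive / negative / unknown
    orfs: list[Orf]
    utr5: tuple[int, int] | None
    utr3: tuple[int, int] | None
    igrs: list[tuple[int, int]]
    composition: BaseComposition
    coding_coverage_pct: float  # rounded to 1 decimal
    coding_complete: bool
    completeness_reasons: list[str] = field(default_factory=list)

    @property
    def gc_pct(self) -> float:
        return self.composition.gc_pct

    @property
    def n_cistrons(self) -> int:
        return len(self.orfs)

    @property
    def coding_coverage_int(self) -> int:
        """Coverage rounded to the nearest whole percent, for prose-style reporting."""
        return int(np.floor(self.coding_coverage_pct + 0.5))


def _seq_of(seq: SeqRecord | str) -> str:
    if isinstance(seq, SeqRecord):
        if seq.alphabet != "nt":
            raise InputError("nucleotide sequence required")
        return seq.seq
    return seq.upper().replace("U", "T")


def base_composition(seq: SeqRecord | str) -> BaseComposition:
    """Mononucleotide fractions (A, U, C, G) and G+C percent over non-N bases."""
    s = _seq_of(seq)
    counts = {b: s.count(b) for b in "ATCG"}
    total = sum(counts.values())
    if total == 0:
        raise CompositionError("composition undefined: sequence has no unambiguous bases")
    frac = {b: counts[b] / total for b in "ATCG"}
    return BaseComposition(
        frac_a=frac["A"],
        frac_u=frac["T"],
        frac_c=frac["C"],
        frac_g=frac["G"],
        gc_pct=100.0 * (counts["C"] + counts["G"]) / total,
    )


def orf_peptide_len(start: int, end: int) -> int:
    """Amino-acid count encoded by an inclusive ORF span (stop codon included).

    ``(end - start + 1) / 3 - 1``: e.g. a 5817-nt span encodes 1938 residues.
    """
    span = end - start + 1
    if span <= 0 or span % 3:
        raise CoordinateError(f"span ({start}, {end}) is not a positive multiple of 3")
    return span // 3 - 1


def _scan_strand(seq: str, min_aa: int) -> list[tuple[int, int]]:
    """Maximal ATG..stop spans (0-based start, exclusive end) on one strand.

    Per stop codon only the longest ORF (5'-most ATG since the previous
    in-frame stop) is reported.
    """
    n = len(seq)
    spans = []
    for frame in range(3):
        first_atg = -1
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if first_atg >= 0:
                    span = i + 3 - first_atg
                    if span // 3 - 1 >= min_aa:
                        spans.append((first_atg, i + 3))
                first_atg = -1
            elif codon == "ATG" and first_atg < 0:
                first_atg = i
    return spans


def find_orfs(
    seq: SeqRecord | str, min_aa: int = 50, senses: Iterable[str] = ("+", "-")
) -> list[Orf]:
    """Find every maximal ORF with at least ``min_aa`` encoded residues.

    ORFs nested inside a longer ORF ending at the same stop are suppressed.
    Coordinates are always reported on the forward strand of the input;
    minus-strand ORFs are found on the reverse complement and mapped back.
    """
    s = _seq_of(seq)
    n = len(s)
    orfs: list[Orf] = []
    if "+" in senses:
        for a, b in _scan_strand(s, min_aa):
            pep = str(Seq(s[a : b - 3]).translate())
            orfs.append(Orf(start=a + 1, end=b, strand="+", peptide=pep))
    if "-" in senses:
        rc = str(Seq(s).reverse_complement())
        for a, b in _scan_strand(rc, min_aa):
            pep = str(Seq(rc[a : b - 3]).translate())
            orfs.append(Orf(start=n - b + 1, end=n - a, strand="-", peptide=pep))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def select_cistrons(orfs: Sequence[Orf]) -> list[Orf]:
    """Greedy non-overlapping ORF selection, longest peptide first.

    Ties in length are broken in favour of the smaller start coordinate.
    The result is sorted by start coordinate.
    """
    kept: list[Orf] = []
    for orf in sorted(orfs, key=lambda o: (-o.aa_len, o.start, o.end, o.strand)):
        if all(orf.end < k.start or orf.start > k.end for k in kept):
            kept.append(orf)
    kept.sort(key=lambda o: o.start)
    return kept


def completeness(
    contigs: Sequence[SeqRecord], orfs: Sequence[Orf], genome_seq: str | None = None
) -> tuple[bool, list[str]]:
    """Coding-completeness verdict: single contig, no gaps, complete ORFs.

    An ORF is complete when its span starts with ATG and ends with a stop
    codon inside the sequence (checked on the ORF's own strand).
    """
    reasons: list[str] = []
    if len(contigs) != 1:
        reasons.append("multiple contigs")
        return False, reasons
    seq = genome_seq if genome_seq is not None else contigs[0].seq
    if "N" in seq:
        reasons.append("gaps")
    for i, orf in enumerate(orfs, 1):
        sub = seq[orf.start - 1 : orf.end]
        if orf.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        if not sub.startswith("ATG") or sub[-3:] not in STOP_CODONS:
            reasons.append(f"incomplete ORF{i}")
    return (not reasons), reasons


def organize(genome: SeqRecord, orfs: Sequence[Orf]) -> GenomeAnnotation:
    """Partition a genome into UTRs, cistrons and IGRs and summarize it.

    The ORFs must be non-overlapping (use :func:`select_cistrons` first).
    Sense is negative iff every cistron is on the minus strand, positive iff
    every cistron is on the plus strand, otherwise unknown.
    """
    n = len(genome.seq)
    ordered = sorted(orfs, key=lambda o: o.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise StructureError(
                f"overlapping ORFs ({a.start}-{a.end}) and ({b.start}-{b.end})"
            )
        if b.end > n or a.end > n:
            raise StructureError("ORF extends beyond the genome")
    if ordered and ordered[-1].end > n:
        raise StructureError("ORF extends beyond the genome")

    if not ordered:
        sense = "unknown"
        utr5 = utr3 = None
        igrs: list[tuple[int, int]] = []
        coverage = 0.0
    else:
        strands = {o.strand for o in ordered}
        sense = {"+": "positive", "-": "negative"}[strands.pop()] if len(strands) == 1 else "unknown"
        utr5 = (1, ordered[0].start - 1) if ordered[0].start > 1 else None
        utr3 = (ordered[-1].end + 1, n) if ordered[-1].end < n else None
        igrs = [
            (a.end + 1, b.start - 1)
            for a, b in zip(ordered, ordered[1:])
            if b.start - a.end > 1
        ]
        coverage = 100.0 * sum(o.span for o in ordered) / n

    complete, reasons = completeness([genome], ordered)
    return GenomeAnnotation(
        genome_id=genome.id,
        length_bp=n,
        sense=sense,
        orfs=list(ordered),
        utr5=utr5,
        utr3=utr3,
        igrs=igrs,
        composition=base_composition(genome),
        coding_coverage_pct=round(coverage, 1),
        coding_complete=complete,
        completeness_reasons=reasons,
    )


def pairwise_identity_matrix(seqs: Sequence[SeqRecord]) -> np.ndarray:
    """Percent-identity matrix over aligned, equal-length sequences.

    Columns where either sequence carries N or a gap are excluded from both
    numerator and denominator. Diagonal is 100 by definition.
    """
    if len(seqs) < 2:
        raise InputError("at least two sequences are required")
    lengths = {len(s.seq) for s in seqs}
    if len(lengths) != 1:
        raise InputError("sequences must be equal length (pre-aligned)")
    arrays = [np.frombuffer(s.seq.encode(), dtype="S1") for s in seqs]
    k = len(seqs)
    mat = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            valid = ~(
                np.isin(arrays[i], [b"N", b"-"]) | np.isin(arrays[j], [b"N", b"-"])
            )
            n_valid = int(valid.sum())
            if n_valid == 0:
                ident = float("nan")
            else:
                ident = 100.0 * float((arrays[i][valid] == arrays[j][valid]).sum()) / n_valid
            mat[i, j] = mat[j, i] = ident
    return mat


def genome_table(annotations: Sequence[GenomeAnnotation]):
    """One-row-per-genome summary table (genome-table style)."""
    import pandas as pd

    rows = []
    for ann in annotations:
        c = ann.composition
        rows.append(
            {
                "Virus": ann.genome_id,
                "Genome length (bp)": ann.length_bp,
                "ORFs": ", ".join(f"ORF{i}: {o.start}-{o.end}" for i, o in enumerate(ann.orfs, 1)),
                "Genome region covered by gene (%)": ann.coding_coverage_pct,
                "Base composition": (
                    f"{100 * c.frac_a:.2f}% A, {100 * c.frac_u:.2f}% U, "
                    f"{100 * c.frac_c:.2f}% C, {100 * c.frac_g:.2f}% G"
                ),
                "Sense": ann.sense,
                "Coding complete": ann.coding_complete,
            }
        )
    return pd.DataFrame(rows)
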