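"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ parsing is delegated to Biopython, SAM parsing to pysam; this
module adds the strict validation the pipeline relies on (duplicate-id checks,
alphabet enforcement, header/reference consistency) and converts everything to
plain dataclasses that the rest of the package consumes.

Coordinates are 1-based inclusive at every interface. ``U`` and ``T`` are
interchangeable on input; nucleotide sequences are stored with ``T``
internally, and RNA-style reporting (``U`` labels) happens only at the
composition-reporting layer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import ConsistencyError, FormatError, InputError

NT_CHARS = frozenset("ACGTN")
AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

#: CIGAR operations accepted by the SAM subset (pysam integer codes).
_CIGAR_OPS = {0: "M", 1: "I", 2: "D", 4: "S"}
_CIGAR_CODES = {v: k for k, v in _CIGAR_OPS.items()}


@dataclass
class SeqRecord:
    """A named sequence: the unit of all FASTA/FASTQ I/O.

    ``alphabet`` is ``"nt"`` (characters A/C/G/T/N after U→T normalisation)
    or ``"aa"`` (the 20 standard residues plus X and ``*``).
    """

    id: str
    seq: str
    desc: str = ""
    alphabet: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a non-empty token: {self.id!r}")
        seq = self.seq.upper()
        if not seq:
            raise FormatError(f"empty sequence for id {self.id!r}")
        if not self.alphabet:
            self.alphabet = "nt" if set(seq) <= (NT_CHARS | {"U"}) else "aa"
        if self.alphabet == "nt":
            seq = seq.replace("U", "T")
            bad = set(seq) - NT_CHARS
        elif self.alphabet == "aa":
            bad = set(seq) - AA_CHARS
        else:
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)}"
            )
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def rna(self) -> str:
        """The sequence with RNA (U) lettering; nucleotide records only."""
        if self.alphabet != "nt":
            raise InputError("rna view is only defined for nucleotide records")
        return self.seq.replace("T", "U")

    def reverse_complement(self) -> str:
        if self.alphabet != "nt":
            raise InputError("reverse complement needs a nucleotide record")
        return str(Seq(self.seq).reverse_complement())


@dataclass
class ReadPair:
    """A paired-end read: two mates with phred+33 quality strings."""

    id: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str
    mate2_qual: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"read id must be a non-empty token: {self.id!r}")
        for rank, (s, q) in enumerate(
            [(self.mate1_seq, self.mate1_qual), (self.mate2_seq, self.mate2_qual)], 1
        ):
            if not s:
                raise FormatError(f"read {self.id!r} mate {rank} is empty")
            if len(s) != len(q):
                raise FormatError(
                    f"read {self.id!r} mate {rank}: quality length {len(q)} "
                    f"!= sequence length {len(s)}"
                )


@dataclass
class AlignmentRecord:
    """One aligned mate, in the M/I/D/S SAM subset.

    ``pos`` is the 1-based leftmost reference coordinate. ``seq`` holds the
    read bases in reference-forward orientation (as in a SAM line) and is
    required by the consensus caller.
    """

    read_id: str
    ref_id: str
    pos: int
    cigar: tuple[tuple[int, str], ...]
    mapq: int
    is_proper_pair: bool
    mate_rank: int
    is_reverse: bool = False
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"alignment position must be >= 1, got {self.pos}")
        if not 0 <= self.mapq <= 60:
            raise FormatError(f"mapq {self.mapq} outside [0, 60]")
        if self.mate_rank not in (1, 2):
            raise FormatError(f"mate_rank must be 1 or 2, got {self.mate_rank}")
        self.cigar = tuple((int(n), op) for n, op in self.cigar)
        for n, op in self.cigar:
            if op not in _CIGAR_CODES or n < 1:
                raise FormatError(f"bad CIGAR element ({n}, {op!r})")

    @property
    def reference_span(self) -> int:
        """Number of reference bases consumed (M + D lengths)."""
        return sum(n for n, op in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference coordinate."""
        return self.pos + self.reference_span - 1


def decode_flag(flag: int) -> dict:
    """Decode the SAM flag bits the subset cares about.

    Returns unmapped (bit 0x4), proper-pair (0x2), reverse-strand (0x10) and
    mate rank (0x40 → 1, 0x80 → 2; an unpaired read counts as rank 1).
    """
    if not 0 <= flag <= 4095:
        raise FormatError(f"SAM flag {flag} outside [0, 4095]")
    return {
        "is_unmapped": bool(flag & 0x4),
        "is_proper_pair": bool(flag & 0x2),
        "is_reverse": bool(flag & 0x10),
        "mate_rank": 2 if (flag & 0x80 and not flag & 0x40) else 1,
    }


def encode_flag(record: AlignmentRecord) -> int:
    flag = 0x1  # the pipeline only emits paired reads
    if record.is_proper_pair:
        flag |= 0x2
    if record.is_reverse:
        flag |= 0x10
    flag |= 0x40 if record.mate_rank == 1 else 0x80
    return flag


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, preserving order.

    Raises :class:`FormatError` on an empty file or a duplicated id.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), desc=desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.desc}" if rec.desc else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike) -> list[ReadPair]:
    """Read two mate FASTQ files (phred+33) into ReadPairs, paired by order."""
    mates1 = list(SeqIO.parse(str(path1), "fastq"))
    mates2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(mates1) != len(mates2):
        raise ConsistencyError(
            f"mate files differ in record count: {len(mates1)} vs {len(mates2)}"
        )
    pairs = []
    for m1, m2 in zip(mates1, mates2):
        if m1.id != m2.id:
            raise ConsistencyError(f"mate ids differ: {m1.id!r} vs {m2.id!r}")
        q1 = "".join(chr(q + 33) for q in m1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in m2.letter_annotations["phred_quality"])
        pairs.append(ReadPair(m1.id, str(m1.seq), str(m2.seq), q1, q2))
    if not pairs:
        raise FormatError(f"no FASTQ records in {path1}")
    return pairs


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.mate1_seq}\n+\n{p.mate1_qual}\n")
            f2.write(f"@{p.id}\n{p.mate2_seq}\n+\n{p.mate2_qual}\n")


# ---------------------------------------------------------------------------
# SAM subset


def read_sam_subset(
    path: str | os.PathLike, references: Sequence[SeqRecord]
) -> list[AlignmentRecord]:
    """Parse a plain-text SAM file restricted to M/I/D/S CIGAR operations.

    Unmapped records (flag bit 0x4) are dropped. The @SQ header lines must
    agree with ``references`` in name and length.
    """
    ref_lens = {r.id: len(r.seq) for r in references}
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot parse SAM file {path}: {exc}") from exc
    with sam:
        for sq in sam.header.get("SQ", []):
            name, length = sq["SN"], sq["LN"]
            if name not in ref_lens:
                raise ConsistencyError(f"@SQ reference {name!r} not among provided references")
            if ref_lens[name] != length:
                raise ConsistencyError(
                    f"@SQ length {length} for {name!r} != reference length {ref_lens[name]}"
                )
        records = []
        try:
            for aln in sam:
                bits = decode_flag(aln.flag)
                if bits["is_unmapped"]:
                    continue
                cigartuples = aln.cigartuples or []
                for code, _n in cigartuples:
                    if code not in _CIGAR_OPS:
                        raise FormatError(
                            f"CIGAR op {code} of read {aln.query_name!r} outside the M/I/D/S subset"
                        )
                rec = AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    pos=aln.reference_start + 1,
                    cigar=tuple((n, _CIGAR_OPS[code]) for code, n in cigartuples),
                    mapq=min(aln.mapping_quality, 60),
                    is_proper_pair=bits["is_proper_pair"],
                    mate_rank=bits["mate_rank"],
                    is_reverse=bits["is_reverse"],
                    seq=aln.query_sequence,
                )
                if rec.end > ref_lens[rec.ref_id]:
                    raise ConsistencyError(
                        f"read {rec.read_id!r} extends to {rec.end} beyond reference "
                        f"{rec.ref_id!r} of length {ref_lens[rec.ref_id]}"
                    )
                records.append(rec)
        except ValueError as exc:  # pysam's malformed-record errors
            raise FormatError(f"malformed SAM record in {path}: {exc}") from exc
    return records


def write_sam_subset(
    records: Iterable[AlignmentRecord],
    references: Sequence[SeqRecord],
    path: str | os.PathLike,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in references],
    }
    ref_index = {r.id: i for i, r in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = rec.read_id
            seg.flag = encode_flag(rec)
            seg.reference_id = ref_index[rec.ref_id]
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = rec.mapq
            seg.cigartuples = [(_CIGAR_CODES[op], n) for n, op in rec.cigar]
            if rec.seq is not None:
                seg.query_sequence = rec.seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(rec.seq))
            sam.write(seg)


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation, path: str | os.PathLike) -> None:
    """Serialize a genome annotation as GFF3 (1-based inclusive coordinates).

    One ``CDS`` feature per ORF, one ``region`` feature per UTR/IGR segment.
    """
    gid = annotation.genome_id
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {gid} 1 {annotation.length_bp}\n")

        def line(ftype, start, end, strand, attrs):
            phase = "0" if ftype == "CDS" else "."
            fh.write(
                f"{gid}\tvirsift\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attrs}\n"
            )

        if annotation.utr5 is not None:
            line("region", annotation.utr5[0], annotation.utr5[1], "+", "ID=utr5;Name=5'UTR")
        for i, orf in enumerate(annotation.orfs, 1):
            line("CDS", orf.start, orf.end, orf.strand, f"ID=orf{i};Name=ORF{i}")
        for i, (s, e) in enumerate(annotation.igrs, 1):
            line("region", s, e, "+", f"ID=igr{i};Name=IGR{i}")
        if annotation.utr3 is not None:
            line("region", annotation.utr3[0], annotation.utr3[1], "+", "ID=utr3;Name=3'UTR")


def read_gff3(path: str | os.PathLike) -> list[tuple[str, str, int, int, str]]:
    """Minimal GFF3 reader: (seqid, type, start, end, strand) per feature."""
    feats = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line does not have 9 columns: {raw!r}")
            start, end = int(cols[3]), int(cols[4])
            if start > end:
                raise FormatError(f"GFF3 feature with start > end: {raw!r}")
            feats.append((cols[0], cols[2], start, end, cols[6]))
    return feats
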