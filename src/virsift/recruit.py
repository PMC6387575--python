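"""Read recruitment against candidate viral genomes.

A deliberately simple seed-anchored, ungapped read mapper places each mate at
the reference position maximizing the match count, assigns a bespoke mapping
quality from the gap between the best and second-best placements, flags
proper pairs, and feeds a per-position consensus caller that marks positions
ambiguous (N) when coverage or majority support is insufficient.

Counting semantics follow the study's misalignment guard: a read pair counts
toward a virus only when both mates align to it with mapping quality >= 25
(and, by default, as a proper pair), and a virus is detected only at >= 5
qualifying pairs.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import InputError
from .seqio import AlignmentRecord, ReadPair, SeqRecord

#: phred-scale weight of one extra matching base in the mapq formula
#: (a uniquely best placement with m more matches scores ~6 points per base).
_MAPQ_PER_MATCH = 10.0 * math.log10(4.0)


@dataclass
class CountFilter:
    """Read-pair filters applied before a virus is counted as present."""

    min_pairs: int = 5
    min_mapq: int = 25
    require_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.min_pairs < 0 or not 0 <= self.min_mapq <= 60:
            raise InputError("invalid count filter")


@dataclass
class ConsensusReport:
    """A consensus sequence and its alignment statistics versus the reference.

    ``aln_len_bp`` counts the unambiguously called (non-N) consensus columns;
    identity is computed over those columns only, so
    ``identical_bp + nonidentical_bp == aln_len_bp`` always holds.
    """

    ref_id: str
    query_label: str
    consensus_seq: str
    length_bp: int
    ambiguous_bp: int
    aln_len_bp: int
    identical_bp: int
    nonidentical_bp: int
    pct_identity: float
    identity_defined: bool = True

    @classmethod
    def from_counts(
        cls,
        identical_bp: int,
        aln_len_bp: int,
        *,
        ref_id: str = "",
        query_label: str = "",
        length_bp: int = 0,
        ambiguous_bp: int = 0,
        consensus_seq: str = "",
    ) -> "ConsensusReport":
        """Build a report from identical/alignment-length counts alone.

        Used to recompute identity statistics from tabulated counts; the
        non-identical count and percent identity follow from the invariant.
        """
        if aln_len_bp < 0 or not 0 <= identical_bp <= max(aln_len_bp, 0):
            raise InputError("identical count outside [0, alignment length]")
        defined = aln_len_bp > 0
        return cls(
            ref_id=ref_id,
            query_label=query_label,
            consensus_seq=consensus_seq,
            length_bp=length_bp or aln_len_bp + ambiguous_bp,
            ambiguous_bp=ambiguous_bp,
            aln_len_bp=aln_len_bp,
            identical_bp=identical_bp,
            nonidentical_bp=aln_len_bp - identical_bp,
            pct_identity=100.0 * identical_bp / aln_len_bp if defined else 0.0,
            identity_defined=defined,
        )


class _ReferenceIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, references: Sequence[SeqRecord], seed_len: int):
        self.seed_len = seed_len
        self.refs = list(references)
        self.seqs = {r.id: r.seq for r in references}
        self.kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref in references:
            s = ref.seq
            for i in range(len(s) - seed_len + 1):
                self.kmers[s[i : i + seed_len]].append((ref.id, i))


def _candidate_placements(index: _ReferenceIndex, seq: str) -> set[tuple[str, int, str]]:
    """(ref_id, 0-based start, strand) placements implied by exact seeds."""
    k = index.seed_len
    cands: set[tuple[str, int, str]] = set()
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        if len(s) < k:
            continue
        offsets = list(range(0, len(s) - k + 1, k))
        if offsets[-1] != len(s) - k:
            offsets.append(len(s) - k)
        for off in offsets:
            for ref_id, pos in index.kmers.get(s[off : off + k], ()):
                cands.add((ref_id, pos - off, strand))
    return cands


def _score_placement(index: _ReferenceIndex, seq: str, ref_id: str, start: int) -> tuple[int, int]:
    """(matches, overlap) of an ungapped placement; ``seq`` already oriented."""
    ref = index.seqs[ref_id]
    lo = max(start, 0)
    hi = min(start + len(seq), len(ref))
    if hi <= lo:
        return 0, 0
    matches = sum(
        1 for i in range(lo, hi) if ref[i] == seq[i - start] and ref[i] != "N"
    )
    return matches, hi - lo


def map_reads(
    pairs: Sequence[ReadPair],
    references: Sequence[SeqRecord],
    seed_len: int = 21,
    min_match_frac: float = 0.8,
    insert_bounds: tuple[int, int] = (100, 600),
) -> list[AlignmentRecord]:
    """Place both mates of each pair by exact-seed anchoring + ungapped scoring.

    Mapping quality is 60 for a unique placement, otherwise
    ``min(60, round(6.02 * (best_matches - second_matches)))`` so that two
    equally good placements force mapq 0. Mates with no seed hit or with
    fewer than ``min_match_frac`` matching bases are omitted. A pair is
    proper when both mates hit the same reference on opposite strands with an
    implied insert inside ``insert_bounds``.
    """
    if not references:
        raise InputError("map_reads needs at least one reference")
    index = _ReferenceIndex(references, seed_len)
    records: list[AlignmentRecord] = []

    for pair in pairs:
        placed: dict[int, tuple[str, int, str, str, int]] = {}
        for rank, seq in ((1, pair.mate1_seq), (2, pair.mate2_seq)):
            best: tuple[int, str, int, str] | None = None  # (matches, ref, start, strand)
            second = 0
            for ref_id, start, strand in sorted(_candidate_placements(index, seq)):
                oriented = seq if strand == "+" else str(Seq(seq).reverse_complement())
                matches, overlap = _score_placement(index, oriented, ref_id, start)
                if overlap == 0 or matches < min_match_frac * overlap:
                    continue
                if best is None or matches > best[0]:
                    second = best[0] if best else 0
                    best = (matches, ref_id, start, strand)
                elif matches > second:
                    second = matches
            if best is None:
                continue
            matches, ref_id, start, strand = best
            mapq = 60 if second == 0 else min(
                60, int(round(_MAPQ_PER_MATCH * (matches - second)))
            )
            oriented = seq if strand == "+" else str(Seq(seq).reverse_complement())
            placed[rank] = (ref_id, start, strand, oriented, mapq)

        proper = False
        if len(placed) == 2:
            (r1, s1, st1, o1, _), (r2, s2, st2, o2, _) = placed[1], placed[2]
            if r1 == r2 and st1 != st2:
                left = min(s1, s2)
                right = max(s1 + len(o1), s2 + len(o2))
                proper = insert_bounds[0] <= right - left <= insert_bounds[1]

        for rank, (ref_id, start, strand, oriented, mapq) in placed.items():
            ref_len = len(index.seqs[ref_id])
            lo = max(start, 0)
            hi = min(start + len(oriented), ref_len)
            cigar = []
            if lo > start:
                cigar.append((lo - start, "S"))
            cigar.append((hi - lo, "M"))
            if start + len(oriented) > hi:
                cigar.append((start + len(oriented) - hi, "S"))
            records.append(
                AlignmentRecord(
                    read_id=pair.id,
                    ref_id=ref_id,
                    pos=lo + 1,
                    cigar=tuple(cigar),
                    mapq=mapq,
                    is_proper_pair=proper,
                    mate_rank=rank,
                    is_reverse=strand == "-",
                    seq=oriented,
                )
            )
    return records


def count_virus_reads(
    alignments: Sequence[AlignmentRecord],
    refs: Sequence[SeqRecord],
    count_filter: CountFilter | None = None,
) -> dict[str, tuple[int, bool]]:
    """Qualifying read-pair count and detection verdict per reference.

    A pair qualifies for a reference when both mates aligned to it, both have
    mapq >= ``min_mapq``, and (if required) the proper-pair flag is set.
    """
    f = count_filter or CountFilter()
    by_read: dict[tuple[str, str], dict[int, AlignmentRecord]] = defaultdict(dict)
    for a in alignments:
        by_read[(a.ref_id, a.read_id)].setdefault(a.mate_rank, a)
    counts: dict[str, int] = defaultdict(int)
    for (ref_id, _read), mates in by_read.items():
        if set(mates) != {1, 2}:
            continue
        if any(m.mapq < f.min_mapq for m in mates.values()):
            continue
        if f.require_proper_pair and not all(m.is_proper_pair for m in mates.values()):
            continue
        counts[ref_id] += 1
    return {r.id: (counts[r.id], counts[r.id] >= f.min_pairs) for r in refs}


def call_consensus(
    alignments: Sequence[AlignmentRecord],
    reference: SeqRecord,
    min_depth: int = 1,
    min_base_frac: float = 0.5,
    query_label: str = "",
) -> ConsensusReport:
    """Majority-rule consensus with conservative ambiguity calling.

    Per reference position, the consensus base is the single most frequent
    read base when depth >= ``min_depth`` and its fraction of the depth is
    >= ``min_base_frac``; otherwise N (exact ties are always N). Alignment
    statistics are computed versus the reference over non-N columns.
    """
    n = len(reference.seq)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((n, 4), dtype=np.int64)
    for aln in alignments:
        if aln.ref_id != reference.id:
            raise InputError(
                f"alignment of {aln.read_id!r} targets {aln.ref_id!r}, not {reference.id!r}"
            )
        if aln.seq is None:
            raise InputError(f"alignment of {aln.read_id!r} carries no sequence")
        rpos = aln.pos - 1
        qpos = 0
        for length, op in aln.cigar:
            if op == "M":
                for x in range(length):
                    b = base_idx.get(aln.seq[qpos + x])
                    if b is not None and rpos + x < n:
                        counts[rpos + x, b] += 1
                rpos += length
                qpos += length
            elif op == "D":
                rpos += length
            else:  # I or S consume the read only
                qpos += length

    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    top_is_unique = (counts == top[:, None]).sum(axis=1) == 1
    callable_ = (depth >= max(min_depth, 1)) & top_is_unique & (top >= min_base_frac * depth)
    consensus = np.full(n, "N", dtype="U1")
    bases = np.array(list("ACGT"))
    consensus[callable_] = bases[counts.argmax(axis=1)[callable_]]
    cons = "".join(consensus)

    ref_arr = np.frombuffer(reference.seq.encode(), dtype="S1")
    non_n = consensus != "N"
    aln_len = int(non_n.sum())
    identical = int((consensus[non_n].astype("S1") == ref_arr[non_n]).sum())
    return ConsensusReport(
        ref_id=reference.id,
        query_label=query_label,
        consensus_seq=cons,
        length_bp=n,
        ambiguous_bp=n - aln_len,
        aln_len_bp=aln_len,
        identical_bp=identical,
        nonidentical_bp=aln_len - identical,
        pct_identity=100.0 * identical / aln_len if aln_len else 0.0,
        identity_defined=aln_len > 0,
    )


def genome_coverage_pct(report: ConsensusReport, reference_len: int) -> int:
    """Percent of the reference covered by unambiguous consensus, whole percent."""
    if reference_len <= 0:
        raise InputError("reference length must be positive")
    return int(math.floor(100.0 * report.aln_len_bp / reference_len + 0.5))


def consensus_table(reports: Sequence[ConsensusReport]):
    """Wide TSV-ready table with the six alignment-statistics rows per query."""
    import pandas as pd

    rows = []
    for r in reports:
        rows.append(
            {
                "Query": r.query_label or r.ref_id,
                "Reference": r.ref_id,
                "Length (bp)": r.length_bp,
                "Ambiguous bases (bp)": r.ambiguous_bp,
                "Alignment length (bp)": r.aln_len_bp,
                "Percentage Identity": round(r.pct_identity, 2),
                "Identical bases (bp)": r.identical_bp,
                "Non-identical bases (bp)": r.nonidentical_bp,
            }
        )
    return pd.DataFrame(rows)
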