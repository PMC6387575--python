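"""Translated homology screening of contigs against a labeled protein database.

The detector is a simplified translated search in the blastx mould: each
contig is translated in all six frames, exact amino-acid k-mer seeds between a
frame and a database protein are extended without gaps under BLOSUM62, and the
best-scoring segment per (frame, subject, diagonal) is reported when it clears
the alignment-length, identity and E-value thresholds. E-values follow the
Karlin–Altschul form ``K * m * n * exp(-lambda * S)`` with fixed ungapped
BLOSUM62 constants; they mirror BLAST in form, not bit-exactly.

Default thresholds: minimum alignment length 100 nt, E-value 0.001, word size
11 nt (≡ 4-residue seeds), 30% identity — the screening parameters of the
study this pipeline reproduces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import ConsistencyError, InputError
from .genomechar import Orf
from .seqio import SeqRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_INDEX = {aa: i for i, aa in enumerate(_BLOSUM62.alphabet)}

#: Karlin–Altschul constants for ungapped BLOSUM62 scoring.
KA_LAMBDA = 0.267
KA_K = 0.041

FRAMES = (1, 2, 3, -1, -2, -3)


def blosum62_score(a: str, b: str) -> int:
    """BLOSUM62 score of one aligned residue pair (X and * included)."""
    ia = _B62_INDEX.get(a, _B62_INDEX["X"])
    ib = _B62_INDEX.get(b, _B62_INDEX["X"])
    return int(_BLOSUM62[ia, ib])


@dataclass
class ScreenParams:
    """Thresholds of the translated screen.

    ``word_size`` is expressed in nucleotides for continuity with the
    screening protocol being reproduced; the protein-level seed length is
    ``ceil(word_size / 3)`` residues (11 nt → 4 aa).
    """

    min_aln_nt: int = 100
    max_evalue: float = 0.001
    word_size: int = 11
    min_pct_identity: float = 30.0

    def __post_init__(self) -> None:
        if min(self.min_aln_nt, self.word_size) <= 0 or self.max_evalue <= 0:
            raise InputError("screen parameters must be positive")
        if self.min_pct_identity <= 0:
            raise InputError("screen parameters must be positive")

    @property
    def seed_aa(self) -> int:
        return -(-self.word_size // 3)


@dataclass
class ProteinHit:
    """One gap-free translated match between a contig frame and a protein."""

    query_id: str
    subject_id: str
    frame: int
    q_start: int  # 1-based nt, forward strand of the query
    q_end: int
    s_start: int  # 1-based aa on the subject
    s_end: int
    aln_len_aa: int
    pct_identity: float
    score: float
    evalue: float
    subject_label: str


def sixframe_translate(rec: SeqRecord) -> dict[int, str]:
    """Translate a nucleotide record in frames +1..+3 and −1..−3.

    Frames −1..−3 read the reverse complement. Stops render as ``*``,
    ambiguous codons as ``X``; trailing partial codons are dropped.
    """
    if rec.alphabet != "nt":
        raise InputError(f"sixframe_translate needs a nucleotide record, got {rec.alphabet}")
    fwd = rec.seq
    rev = rec.reverse_complement()
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        for strand, src in ((f, fwd), (-f, rev)):
            sub = src[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            out[strand] = str(Seq(sub).translate()) if sub else ""
    return out


def subject_label_of(rec: SeqRecord) -> str:
    """Taxonomy/domain label from the db header convention ``id|label...``."""
    if "|" in rec.id:
        return rec.id.split("|", 1)[1]
    return rec.desc


def _frame_to_query_coords(frame: int, aa_start: int, aa_len: int, query_len: int) -> tuple[int, int]:
    """Map a 0-based aa interval in a frame onto forward-strand nt coordinates."""
    f = abs(frame)
    r1 = f + 3 * aa_start  # 1-based on the reading strand
    r2 = r1 + 3 * aa_len - 1
    if frame > 0:
        return r1, r2
    return query_len - r2 + 1, query_len - r1 + 1


def _best_segment_through_seed(
    scores: list[int], a: int, k: int
) -> tuple[int, int, int]:
    """Maximal ungapped extension of the seed occupying columns [a, a+k).

    Returns (start, end_exclusive, total_score). The left extension reaches
    the farthest position achieving the maximal added score (smallest start);
    the right extension stops at the nearest (smallest end).
    """
    total = sum(scores[a : a + k])
    best_l, left_gain, run = a, 0, 0
    for i in range(a - 1, -1, -1):
        run += scores[i]
        if run >= left_gain:  # >= : farthest position achieving the max
            left_gain, best_l = run, i

    best_r, right_gain, run = a + k, 0, 0
    for j in range(a + k, len(scores)):
        run += scores[j]
        if run > right_gain:  # > : nearest position achieving the max
            right_gain, best_r = run, j + 1
    return best_l, best_r, total + left_gain + right_gain


def translated_search(
    queries: Sequence[SeqRecord],
    protein_db: Sequence[SeqRecord],
    params: ScreenParams | None = None,
) -> list[ProteinHit]:
    """Six-frame seed-and-extend search of nucleotide queries against proteins.

    For every (query frame, subject, diagonal) with at least one exact
    ``seed_aa``-mer match, the maximal gap-free BLOSUM62-scoring segment is
    computed; segments shorter than ``min_aln_nt/3`` residues, below
    ``min_pct_identity``, or above ``max_evalue`` are discarded. Hits are
    sorted by score descending (ties: E-value, subject id, query id, frame).
    """
    params = params or ScreenParams()
    if not protein_db:
        raise InputError("protein database is empty")
    for q in queries:
        if q.alphabet != "nt":
            raise InputError(f"query {q.id!r} is not a nucleotide sequence")

    k = params.seed_aa
    db_residues = sum(len(s.seq) for s in protein_db)
    min_aln_aa = -(-params.min_aln_nt // 3)

    # k-mer index over the whole database
    index: dict[str, list[tuple[int, int]]] = {}
    for si, subj in enumerate(protein_db):
        s = subj.seq
        for j in range(len(s) - k + 1):
            index.setdefault(s[j : j + k], []).append((si, j))

    hits: list[ProteinHit] = []
    for query in queries:
        frames = sixframe_translate(query)
        for frame in FRAMES:
            pep = frames[frame]
            if len(pep) < k:
                continue
            # collect seeds per (subject, diagonal)
            diagonals: dict[tuple[int, int], list[int]] = {}
            for i in range(len(pep) - k + 1):
                for si, j in index.get(pep[i : i + k], ()):
                    diagonals.setdefault((si, i - j), []).append(i)
            for (si, diag), seed_starts in diagonals.items():
                subj = protein_db[si]
                s = subj.seq
                # overlapping columns of this diagonal
                q0, s0 = (diag, 0) if diag >= 0 else (0, -diag)
                t = min(len(pep) - q0, len(s) - s0)
                scores = [blosum62_score(pep[q0 + x], s[s0 + x]) for x in range(t)]
                best: tuple[int, int, int] | None = None
                for a in seed_starts:
                    seg = _best_segment_through_seed(scores, a - q0, k)
                    if best is None or (seg[2], -seg[0], -seg[1]) > (best[2], -best[0], -best[1]):
                        best = seg
                l, r, score = best
                aln_len = r - l
                if aln_len < min_aln_aa:
                    continue
                ident = sum(pep[q0 + x] == s[s0 + x] for x in range(l, r))
                pct = 100.0 * ident / aln_len
                if pct < params.min_pct_identity:
                    continue
                evalue = KA_K * len(pep) * db_residues * math.exp(-KA_LAMBDA * score)
                if evalue > params.max_evalue:
                    continue
                qs, qe = _frame_to_query_coords(frame, q0 + l, aln_len, len(query.seq))
                hits.append(
                    ProteinHit(
                        query_id=query.id,
                        subject_id=subj.id,
                        frame=frame,
                        q_start=qs,
                        q_end=qe,
                        s_start=s0 + l + 1,
                        s_end=s0 + r,
                        aln_len_aa=aln_len,
                        pct_identity=pct,
                        score=float(score),
                        evalue=evalue,
                        subject_label=subject_label_of(subj),
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.evalue, h.subject_id, h.query_id, h.frame))
    return hits


_DOMAIN_NAMES = {"virus": "virus", "bacteria": "bacteria", "fungi": "fungi"}


def classify_contigs(
    queries: Sequence[SeqRecord],
    hits: Sequence[ProteinHit],
    params: ScreenParams | None = None,
) -> dict[str, str]:
    """Assign each contig the taxonomy domain of its best surviving hit.

    Contigs with no surviving hit are host. Best-hit ties break on
    (score desc, E-value asc, subject id lexicographic).
    """
    known = {q.id for q in queries}
    best: dict[str, ProteinHit] = {}
    for h in hits:
        if h.query_id not in known:
            raise ConsistencyError(f"hit references unknown query {h.query_id!r}")
        cur = best.get(h.query_id)
        if cur is None or (-h.score, h.evalue, h.subject_id) < (-cur.score, cur.evalue, cur.subject_id):
            best[h.query_id] = h
    labels: dict[str, str] = {}
    for q in queries:
        h = best.get(q.id)
        if h is None:
            labels[q.id] = "host"
        else:
            domain = h.subject_label.split("|", 1)[0].strip().lower()
            labels[q.id] = _DOMAIN_NAMES.get(domain, "other")
    return labels


def annotate_domains(
    genome: SeqRecord,
    orfs: Sequence[Orf],
    domain_db: Sequence[SeqRecord],
    params: ScreenParams | None = None,
) -> list[tuple[int, str, int, int]]:
    """Locate labeled domain exemplars within each ORF and order them.

    Each ORF's coding sequence is searched against ``domain_db``; the
    best-scoring non-overlapping hits are kept and reported as
    ``(orf_index, domain_label, genome_start, genome_end)`` sorted by genome
    coordinate, yielding domain-order strings such as ``Hel-Pro-RdRp``.
    """
    results: list[tuple[int, str, int, int]] = []
    for oi, orf in enumerate(orfs, 1):
        sub = genome.seq[orf.start - 1 : orf.end]
        if orf.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        qrec = SeqRecord(id=f"{genome.id}_orf{oi}", seq=sub, alphabet="nt")
        hits = [h for h in translated_search([qrec], domain_db, params) if h.frame == 1]
        kept: list[ProteinHit] = []
        for h in hits:  # already score-sorted
            if all(h.q_end < x.q_start or h.q_start > x.q_end for x in kept):
                kept.append(h)
        for h in kept:
            if orf.strand == "+":
                gs = orf.start + h.q_start - 1
                ge = orf.start + h.q_end - 1
            else:
                gs = orf.end - h.q_end + 1
                ge = orf.end - h.q_start + 1
            label = h.subject_label.split("|", 1)[0].strip()
            results.append((oi, label, gs, ge))
    results.sort(key=lambda x: (x[2], x[3]))
    return results


def domain_order_string(domains: Iterable[tuple[int, str, int, int]]) -> str:
    """Join annotated domain labels in genome order, e.g. ``Hel-Pro-RdRp``."""
    return "-".join(d[1] for d in domains)


def write_hits_tsv(hits: Sequence[ProteinHit], path) -> None:
    """Write hits as 12-column tab text in BLAST outfmt-6 column order."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_len_aa,
                        h.aln_len_aa - round(h.aln_len_aa * h.pct_identity / 100),
                        0,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.2e}",
                        f"{h.score:.1f}",
                    )
                )
                + "\n"
            )
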