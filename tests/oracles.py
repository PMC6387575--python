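"""Independent oracles used by the test suite.

Each oracle re-derives expected results by brute force or direct arithmetic,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_B62 = substitution_matrices.load("BLOSUM62")
_IDX = {aa: i for i, aa in enumerate(_B62.alphabet)}


def flag_bits_oracle(flag: int) -> dict:
    """SAM flag decoding by integer division, no bitwise operators."""
    def bit(b):
        return (flag // (2**b)) % 2 == 1

    return {
        "is_unmapped": bit(2),
        "is_proper_pair": bit(1),
        "is_reverse": bit(4),
        "mate_rank": 2 if (bit(7) and not bit(6)) else 1,
    }


def brute_force_orfs(seq: str, min_aa: int) -> list[tuple[int, int, str]]:
    """All maximal (ATG, in-frame stop) spans on both strands, 1-based forward.

    Enumerates every ATG, walks to its nearest in-frame stop, keeps the
    5'-most ATG per stop, filters by encoded length.
    """
    stops = {"TAA", "TAG", "TGA"}

    def one_strand(s: str) -> list[tuple[int, int]]:
        by_stop: dict[int, int] = {}  # stop-end (exclusive) -> min ATG index
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= len(s):
                if s[j : j + 3] in stops:
                    by_stop[j + 3] = min(by_stop.get(j + 3, j), i)
                    break
                j += 3
        return [
            (a, e)
            for e, a in by_stop.items()
            if (e - a) // 3 - 1 >= min_aa
        ]

    n = len(seq)
    out = [(a + 1, e, "+") for a, e in one_strand(seq)]
    rc = str(Seq(seq).reverse_complement())
    out += [(n - e + 1, n - a, "-") for a, e in one_strand(rc)]
    return sorted(out)


def _score(a: str, b: str) -> int:
    return int(_B62[_IDX.get(a, _IDX["X"]), _IDX.get(b, _IDX["X"])])


def _six_frames(nt: str) -> dict[int, str]:
    frames = {}
    rc = str(Seq(nt).reverse_complement())
    for f in (1, 2, 3):
        for sgn, src in ((f, nt), (-f, rc)):
            sub = src[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sgn] = str(Seq(sub).translate()) if sub else ""
    return frames


def brute_force_translated_hits(
    query_id: str,
    query_nt: str,
    db: list[tuple[str, str]],
    min_aln_nt: int = 100,
    max_evalue: float = 0.001,
    min_pct_identity: float = 30.0,
    ka_k: float = 0.041,
    ka_lambda: float = 0.267,
) -> set[tuple]:
    """Exhaustive ungapped scan: best BLOSUM62 segment per (frame, subject,
    diagonal) via prefix sums, thresholded like the screen.

    Returns hit keys ``(query_id, subject_id, frame, q_start, q_end, s_start,
    s_end, score)`` for set comparison. Ties in the per-diagonal maximum are
    broken toward the smallest end, then the smallest start.
    """
    db_residues = sum(len(s) for _i, s in db)
    min_aa = math.ceil(min_aln_nt / 3)
    hits: set[tuple] = set()
    frames = _six_frames(query_nt)
    qlen = len(query_nt)
    for frame, pep in frames.items():
        for subj_id, subj in db:
            for diag in range(-(len(subj) - 1), len(pep)):
                q0 = max(diag, 0)
                s0 = max(-diag, 0)
                t = min(len(pep) - q0, len(subj) - s0)
                if t <= 0:
                    continue
                col = np.array(
                    [_score(pep[q0 + x], subj[s0 + x]) for x in range(t)], dtype=float
                )
                prefix = np.concatenate([[0.0], np.cumsum(col)])
                cummin = np.minimum.accumulate(prefix[:-1])
                seg_scores = prefix[1:] - cummin
                e = int(np.argmax(seg_scores))  # first max: smallest end
                score = seg_scores[e]
                s = int(np.argmin(prefix[: e + 1]))  # first min: smallest start
                aln_len = e + 1 - s
                if score <= 0 or aln_len < min_aa:
                    continue
                ident = sum(pep[q0 + x] == subj[s0 + x] for x in range(s, e + 1))
                if 100.0 * ident / aln_len < min_pct_identity:
                    continue
                evalue = ka_k * len(pep) * db_residues * math.exp(-ka_lambda * score)
                if evalue > max_evalue:
                    continue
                f = abs(frame)
                r1 = f + 3 * (q0 + s)
                r2 = r1 + 3 * aln_len - 1
                if frame > 0:
                    qs, qe = r1, r2
                else:
                    qs, qe = qlen - r2 + 1, qlen - r1 + 1
                hits.add(
                    (query_id, subj_id, frame, qs, qe, s0 + s + 1, s0 + e + 1, int(score))
                )
    return hits
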