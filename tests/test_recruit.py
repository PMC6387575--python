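import math

import pytest

from virsift import recruit, synthdata
from virsift.errors import InputError
from virsift.recruit import ConsensusReport, CountFilter
from virsift.seqio import AlignmentRecord, ReadPair, SeqRecord


def _pair_from(seq, start, insert, read_len=91, pid="p1"):
    from Bio.Seq import Seq

    frag = seq[start : start + insert]
    return ReadPair(
        id=pid,
        mate1_seq=frag[:read_len],
        mate2_seq=str(Seq(frag[-read_len:]).reverse_complement()),
        mate1_qual="I" * read_len,
        mate2_qual="I" * read_len,
    )


@pytest.fixture(scope="module")
def genome():
    spec = synthdata.study_architectures()[0]
    g, _ann = synthdata.make_viral_genome(spec, seed=21)
    return g


class TestMapReads:
    def test_error_free_pair_unique_proper(self, genome):
        pair = _pair_from(genome.seq, 1000, 300)
        recs = recruit.map_reads([pair], [genome])
        assert len(recs) == 2
        assert all(r.mapq == 60 and r.is_proper_pair for r in recs)
        by_rank = {r.mate_rank: r for r in recs}
        assert by_rank[1].pos == 1001
        assert by_rank[2].pos == 1001 + 300 - 91
        assert {r.is_reverse for r in recs} == {True, False}

    def test_foreign_pair_omitted(self, genome):
        host = synthdata.make_host_transcriptome(1, (500, 600), seed=3, avoid=[genome])[0]
        pair = _pair_from(host.seq, 10, 250)
        assert recruit.map_reads([pair], [genome]) == []

    def test_duplicated_reference_forces_mapq_zero(self, genome):
        dup = SeqRecord(id="copy", seq=genome.seq)
        pair = _pair_from(genome.seq, 2000, 300)
        recs = recruit.map_reads([pair], [genome, dup])
        assert recs and all(r.mapq == 0 for r in recs)

    def test_no_references_rejected(self, genome):
        with pytest.raises(InputError):
            recruit.map_reads([_pair_from(genome.seq, 0, 250)], [])


def _aln(ref="v1", read="p1", rank=1, mapq=60, proper=True, pos=1, seq=None):
    s = seq or "A" * 10
    return AlignmentRecord(
        read_id=read, ref_id=ref, pos=pos, cigar=((len(s), "M"),),
        mapq=mapq, is_proper_pair=proper, mate_rank=rank, seq=s,
    )


class TestCountVirusReads:
    REF = [SeqRecord(id="v1", seq="A" * 500)]

    def _pairs(self, n, **kw):
        out = []
        for i in range(n):
            out.append(_aln(read=f"p{i}", rank=1, **kw))
            out.append(_aln(read=f"p{i}", rank=2, **kw))
        return out

    def test_four_pairs_not_detected(self):
        counts = recruit.count_virus_reads(self._pairs(4), self.REF)
        assert counts["v1"] == (4, False)

    def test_five_pairs_detected_boundary(self):
        counts = recruit.count_virus_reads(self._pairs(5), self.REF)
        assert counts["v1"] == (5, True)

    def test_low_mapq_pairs_excluded(self):
        alns = self._pairs(4, mapq=60) + self._pairs(6, mapq=20)
        # the mapq-20 pairs share read ids with the mapq-60 ones? use distinct ids
        alns = self._pairs(4, mapq=60)
        for i in range(6):
            alns.append(_aln(read=f"q{i}", rank=1, mapq=20))
            alns.append(_aln(read=f"q{i}", rank=2, mapq=20))
        counts = recruit.count_virus_reads(alns, self.REF, CountFilter(min_mapq=25))
        assert counts["v1"] == (4, False)

    def test_mapq_boundary_25_counts(self):
        counts = recruit.count_virus_reads(self._pairs(5, mapq=25), self.REF)
        assert counts["v1"] == (5, True)
        counts = recruit.count_virus_reads(self._pairs(5, mapq=24), self.REF)
        assert counts["v1"] == (0, False)

    def test_improper_pairs_need_flag(self):
        alns = self._pairs(5, proper=False)
        strict = recruit.count_virus_reads(alns, self.REF, CountFilter())
        loose = recruit.count_virus_reads(
            alns, self.REF, CountFilter(require_proper_pair=False)
        )
        assert strict["v1"] == (0, False) and loose["v1"] == (5, True)

    def test_filter_monotonicity(self):
        alns = self._pairs(5, mapq=30)
        for min_mapq in (0, 25, 31):
            for min_pairs in (1, 5, 6):
                c = recruit.count_virus_reads(
                    alns, self.REF, CountFilter(min_pairs=min_pairs, min_mapq=min_mapq)
                )
                expected = (5 if min_mapq <= 30 else 0)
                assert c["v1"][0] == expected
                assert c["v1"][1] == (expected >= min_pairs)


class TestCallConsensus:
    def test_planted_snvs_recovered(self, genome):
        mutated = list(genome.seq)
        positions = [100, 500, 1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000]
        for p in positions:
            mutated[p] = "ACGT"["ACGT".index(mutated[p]) - 1]
        mutant = SeqRecord(id=genome.id, seq="".join(mutated))
        starts = list(range(0, len(mutant.seq) - 300, 10)) + [len(mutant.seq) - 300]
        pairs = [_pair_from(mutant.seq, s, 300, pid=f"p{s}") for s in starts]
        alns = recruit.map_reads(pairs, [genome])
        report = recruit.call_consensus(alns, genome)
        assert report.ambiguous_bp == 0
        assert report.nonidentical_bp == len(positions)
        mismatch_at = [
            i for i, (a, b) in enumerate(zip(report.consensus_seq, genome.seq)) if a != b
        ]
        assert mismatch_at == positions

    def test_exact_recovery_at_30x(self, genome):
        n_pairs = math.ceil(30 * len(genome.seq) / 182)
        step = max(1, (len(genome.seq) - 300) // n_pairs)
        starts = list(range(0, len(genome.seq) - 300, step)) + [len(genome.seq) - 300]
        pairs = [_pair_from(genome.seq, s, 300, pid=f"p{s}") for s in starts]
        alns = recruit.map_reads(pairs, [genome])
        report = recruit.call_consensus(alns, genome)
        assert report.consensus_seq == genome.seq
        assert report.ambiguous_bp == 0 and report.nonidentical_bp == 0

    def test_tie_yields_n(self):
        ref = SeqRecord(id="r", seq="ACGTACGTAC")
        a1 = _aln(ref="r", read="p1", seq="AAGTACGTAC")
        a2 = _aln(ref="r", read="p2", seq="ACGTACGTAC")
        report = recruit.call_consensus([a1, a2], ref)
        assert report.consensus_seq[1] == "N"  # 1 C vs 1 A at position 2
        assert report.consensus_seq[0] == "A"

    def test_empty_alignments_all_n(self):
        ref = SeqRecord(id="r", seq="ACGT" * 25)
        report = recruit.call_consensus([], ref)
        assert set(report.consensus_seq) == {"N"}
        assert report.aln_len_bp == 0 and report.pct_identity == 0.0
        assert not report.identity_defined

    def test_min_depth_marks_low_coverage_ambiguous(self):
        ref = SeqRecord(id="r", seq="ACGTACGTAC")
        a1 = _aln(ref="r", read="p1", seq="ACGTACGTAC")
        report = recruit.call_consensus([a1], ref, min_depth=2)
        assert set(report.consensus_seq) == {"N"}


class TestReportArithmetic:
    def test_identity_from_counts(self):
        r = ConsensusReport.from_counts(646, 666)
        assert round(r.pct_identity, 2) == 97.00
        assert r.nonidentical_bp == 20

    def test_nonidentical_from_counts(self):
        r = ConsensusReport.from_counts(2079, 2337)
        assert r.nonidentical_bp == 258

    def test_conservation_invariant(self):
        for ident, aln in [(646, 666), (2079, 2337), (8226, 9040), (0, 0)]:
            r = ConsensusReport.from_counts(ident, aln)
            assert r.identical_bp + r.nonidentical_bp == r.aln_len_bp

    def test_bad_counts_rejected(self):
        with pytest.raises(InputError):
            ConsensusReport.from_counts(10, 5)


class TestGenomeCoveragePct:
    def test_prose_value(self):
        r = ConsensusReport.from_counts(8226, 9040)
        assert recruit.genome_coverage_pct(r, 9160) == 99

    def test_zero_alignment(self):
        assert recruit.genome_coverage_pct(ConsensusReport.from_counts(0, 0), 100) == 0

    def test_full_alignment(self):
        assert recruit.genome_coverage_pct(ConsensusReport.from_counts(90, 100), 100) == 100

    def test_zero_reference_rejected(self):
        with pytest.raises(InputError):
            recruit.genome_coverage_pct(ConsensusReport.from_counts(1, 1), 0)
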