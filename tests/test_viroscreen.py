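import numpy as np
import pytest
from Bio.Seq import Seq

from virsift import synthdata, viroscreen
from virsift.errors import ConsistencyError, InputError
from virsift.genomechar import Orf
from virsift.seqio import SeqRecord
from virsift.viroscreen import ScreenParams

from .oracles import brute_force_translated_hits

CODON = {}
for _c in synthdata.SENSE_CODONS:
    CODON.setdefault(str(Seq(_c).translate()), _c)


def back_translate(pep: str) -> str:
    return "".join(CODON[a] for a in pep)


def random_peptide(rng, n):
    residues = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(residues[i] for i in rng.integers(0, 20, size=n))


class TestSixFrame:
    def test_standard_code_frame1(self):
        rec = SeqRecord(id="q", seq="ATGAAATAA")
        assert viroscreen.sixframe_translate(rec)[1] == "MK*"

    def test_reverse_complement_symmetry(self):
        rec = SeqRecord(id="q", seq="ATGAAATAA")
        rc = SeqRecord(id="r", seq=rec.reverse_complement())
        assert viroscreen.sixframe_translate(rc)[-1] == "MK*"

    def test_partial_trailing_codon_dropped(self):
        rec = SeqRecord(id="q", seq="ATGAA")
        frames = viroscreen.sixframe_translate(rec)
        assert frames[3] == "E"  # "GAA"
        assert frames[2] == "*"  # "TGA", trailing "A" dropped
        assert frames[1] == "M"

    def test_n_translates_to_x(self):
        rec = SeqRecord(id="q", seq="ATGNNNAAA")
        assert viroscreen.sixframe_translate(rec)[1] == "MXK"

    def test_peptide_query_rejected(self):
        rec = SeqRecord(id="q", seq="MKLV", alphabet="aa")
        with pytest.raises(InputError):
            viroscreen.sixframe_translate(rec)


class TestTranslatedSearch:
    def test_exact_backtranslation_self_hit(self, rng):
        pep = random_peptide(rng, 100)
        query = SeqRecord(id="q", seq=back_translate(pep))
        subject = SeqRecord(id="s|virus", seq=pep, alphabet="aa")
        hits = viroscreen.translated_search([query], [subject])
        assert len(hits) == 1
        h = hits[0]
        assert h.frame == 1 and h.pct_identity == 100.0 and h.aln_len_aa == 100
        assert (h.q_start, h.q_end) == (1, 300)
        assert (h.s_start, h.s_end) == (1, 100)

    def test_identity_threshold_semantics(self, rng):
        pep = random_peptide(rng, 100)
        # mutate 30 residues -> 70% identity
        mutated = list(pep)
        idx = rng.choice(100, size=30, replace=False)
        for i in idx:
            mutated[i] = "ACDEFGHIKLMNPQRSTVWY".replace(mutated[i], "")[0]
        query = SeqRecord(id="q", seq=back_translate("".join(mutated)))
        subject = SeqRecord(id="s|virus", seq=pep, alphabet="aa")
        lo = viroscreen.translated_search([query], [subject], ScreenParams(min_pct_identity=30))
        hi = viroscreen.translated_search([query], [subject], ScreenParams(min_pct_identity=80))
        assert any(h.pct_identity >= 30 for h in lo)
        assert lo and not hi

    def test_empty_db_rejected(self):
        with pytest.raises(InputError):
            viroscreen.translated_search([SeqRecord(id="q", seq="ACGT")], [])

    def test_monotonicity_in_thresholds(self, rng):
        pep = random_peptide(rng, 120)
        query = SeqRecord(id="q", seq=back_translate(pep))
        db = [SeqRecord(id="s|virus", seq=pep, alphabet="aa")]
        base = viroscreen.translated_search([query], db, ScreenParams())
        stricter_id = viroscreen.translated_search(
            [query], db, ScreenParams(min_pct_identity=90)
        )
        stricter_e = viroscreen.translated_search(
            [query], db, ScreenParams(max_evalue=1e-30)
        )
        keys = lambda hs: {(h.subject_id, h.frame, h.q_start, h.q_end) for h in hs}
        assert keys(stricter_id) <= keys(base)
        assert keys(stricter_e) <= keys(base)

    @pytest.mark.parametrize("n_instances", [30])
    def test_matches_bruteforce_scan(self, n_instances):
        """Seed-and-extend equals the exhaustive ungapped diagonal scan."""
        rng = np.random.default_rng(2024)
        params = ScreenParams()
        for _ in range(n_instances):
            db = []
            for si in range(int(rng.integers(2, 5))):
                db.append((f"s{si}|virus", random_peptide(rng, int(rng.integers(60, 180)))))
            qlen = int(rng.integers(150, 500))
            query_nt = "".join(rng.choice(list("ACGT"), size=qlen))
            if rng.random() < 0.6:  # plant a diverged homolog
                subj = db[int(rng.integers(len(db)))][1]
                a = int(rng.integers(0, max(len(subj) - 45, 1)))
                frag = subj[a : a + 40]
                nt = list(back_translate(frag))
                for i in range(len(nt)):
                    if rng.random() < 0.05:
                        nt[i] = "ACGT"[int(rng.integers(4))]
                nt = "".join(nt)
                if rng.random() < 0.5:
                    nt = str(Seq(nt).reverse_complement())
                pos = int(rng.integers(0, qlen - len(nt) + 1))
                query_nt = query_nt[:pos] + nt + query_nt[pos + len(nt):]
            got = viroscreen.translated_search(
                [SeqRecord(id="q", seq=query_nt)],
                [SeqRecord(id=i, seq=s, alphabet="aa") for i, s in db],
                params,
            )
            got_keys = {
                (h.query_id, h.subject_id, h.frame, h.q_start, h.q_end,
                 h.s_start, h.s_end, int(h.score))
                for h in got
            }
            expected = brute_force_translated_hits("q", query_nt, db)
            assert got_keys == expected


class TestClassifyContigs:
    def _screen(self, study_genomes, divergence=0.0):
        db = synthdata.make_protein_db(
            study_genomes, taxonomy=synthdata.TAXONOMY, aa_divergence=divergence, seed=9
        )
        return db

    def test_viral_contig_labeled_virus(self, study_genomes):
        genome, _ = study_genomes[0]
        db = self._screen(study_genomes)
        hits = viroscreen.translated_search([genome], db)
        labels = viroscreen.classify_contigs([genome], hits)
        assert labels[genome.id] == "virus"

    def test_no_hit_means_host(self):
        q = SeqRecord(id="c1", seq="ACGT" * 100)
        labels = viroscreen.classify_contigs([q], [])
        assert labels == {"c1": "host"}

    def test_unknown_query_in_hits_rejected(self, study_genomes):
        genome, _ = study_genomes[0]
        db = self._screen(study_genomes)
        hits = viroscreen.translated_search([genome], db)
        with pytest.raises(ConsistencyError):
            viroscreen.classify_contigs([SeqRecord(id="other", seq="ACGT")], hits)

    def test_tie_breaks_deterministically(self):
        h = lambda sid, label: viroscreen.ProteinHit(
            query_id="q", subject_id=sid, frame=1, q_start=1, q_end=120,
            s_start=1, s_end=40, aln_len_aa=40, pct_identity=100.0,
            score=200.0, evalue=1e-20, subject_label=label,
        )
        q = SeqRecord(id="q", seq="ACGT" * 50)
        labels = viroscreen.classify_contigs(
            [q], [h("b|nonviral", "nonviral"), h("a|virus", "virus")]
        )
        assert labels["q"] == "virus"  # subject id "a|virus" < "b|nonviral"

    def test_planted_virus_recall_with_diverged_db(self, small_dataset):
        labels = viroscreen.classify_contigs(
            small_dataset.contigs,
            viroscreen.translated_search(small_dataset.contigs, small_dataset.protein_db),
        )
        viral_ids = {g.id for g, _ in small_dataset.genomes}
        assert {cid for cid, lab in labels.items() if lab == "virus"} == viral_ids


class TestAnnotateDomains:
    def _planted_genome(self, order):
        rng = np.random.default_rng(8)
        domains = {
            "Hel": random_peptide(rng, 80),
            "Pro": random_peptide(rng, 80),
            "RdRp": random_peptide(rng, 80),
        }
        linker = random_peptide(rng, 40)
        pep = "M" + linker + linker.join(domains[d] for d in order) + linker
        spec = synthdata.ArchSpec(
            name="poly", n_cistrons=1, utr5_len=60, utr3_len=60,
            orf_aa_lens=(len(pep),), peptides=(pep,),
        )
        genome, ann = synthdata.make_viral_genome(spec, seed=4)
        db = [
            SeqRecord(id=f"{name}|{name}", seq=seq, alphabet="aa")
            for name, seq in domains.items()
        ]
        return genome, ann, db

    def test_planted_order_recovered(self):
        genome, ann, db = self._planted_genome(("Hel", "Pro", "RdRp"))
        found = viroscreen.annotate_domains(genome, ann.orfs, db)
        assert viroscreen.domain_order_string(found) == "Hel-Pro-RdRp"
        assert all(oi == 1 for oi, *_rest in found)

    def test_reversed_order_recovered(self):
        genome, ann, db = self._planted_genome(("RdRp", "Pro", "Hel"))
        found = viroscreen.annotate_domains(genome, ann.orfs, db)
        assert viroscreen.domain_order_string(found) == "RdRp-Pro-Hel"

    def test_no_domain_hits_empty(self, study_genomes, rng):
        genome, ann = study_genomes[0]
        db = [SeqRecord(id="Zn|Zn", seq=random_peptide(rng, 90), alphabet="aa")]
        assert viroscreen.annotate_domains(genome, ann.orfs, db) == []
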