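# Methods

This note documents the models, algorithms and numerical choices behind
`virsift`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Translated homology screen (`viroscreen`)

The detector is a simplified translated search in the blastx mould. Each
nucleotide query is translated in six frames (standard code; ambiguous
codons → X, stops → `*`, trailing partial codons dropped). Exact amino-acid
k-mer seeds between a frame and a database protein define candidate
diagonals; on each (frame, subject, diagonal) the maximal-scoring gap-free
segment through the best seed is computed under BLOSUM62 (Biopython's
matrix, which includes X and `*` columns). Ties in the per-diagonal maximum
resolve to the smallest end, then the smallest start, making results
deterministic and directly comparable to an exhaustive diagonal-scan oracle.

* **Word size.** The screening protocol's word size of 11 is a
  nucleotide-centric number; for a protein-level search it is interpreted as
  ceil(11/3) = 4-residue exact seeds. The parameter stays exposed in
  `ScreenParams.word_size` in nucleotide units.
* **E-values** follow the ungapped Karlin–Altschul form
  `E = K·m·n·exp(−λS)` with K = 0.041 and λ = 0.267 (standard ungapped
  BLOSUM62 constants), where `m` is the frame's peptide length and `n` the
  total residue count of the database. They mirror BLAST in form, not
  bit-exactly; the default threshold E ≤ 0.001 is a screen parameter, and
  the same formula is applied by the test oracle, so only the *form* is
  load-bearing.
* **Thresholds.** Defaults are minimum alignment length 100 nt (a hit of
  `a` aligned residues spans `3a` nt, so `a ≥ 34`), identity ≥ 30%
  (amino-acid level — translated searches report residue identity), E ≤
  0.001. Raising the identity floor or lowering the E-value ceiling can only
  remove hits (tested property).
* **Ungapped only.** Extension is ungapped; gapped alignment would change
  borderline identities but not thresholded detection of the planted-truth
  kind this package quantifies, and it would preclude the simple exhaustive
  oracle. Declared non-goal.
* **Classification** takes the taxonomy domain (`virus`/`bacteria`/`fungi`,
  anything else → `other`) of the best surviving hit, ties broken by
  (score desc, E-value asc, subject id); contigs without hits are host.

## Genome characterization (`genomechar`)

An ORF is a maximal ATG-to-stop span in one frame, stop codon included;
among in-frame ATGs sharing a stop only the 5′-most is reported. Both
strands are searched and coordinates are always reported on the forward
strand of the input, so negative-sense genomes carry minus-strand ORFs in
genome coordinates. `select_cistrons` greedily keeps the longest-peptide
ORFs that do not overlap anything already kept (ties → smaller start),
which discards the short antisense ORFs that long cistrons inevitably
contain. `organize` partitions the genome into 5′UTR / cistrons / IGRs /
3′UTR (length conservation is a tested invariant), computes base
composition over non-N bases (reported with U labels — the subjects are
ssRNA viruses even though sequencing data use the DNA alphabet), and codes
the sense as positive/negative when all cistrons agree, else unknown.

* **min_aa = 50** by default: small enough to admit every cistron of the
  genome architectures of interest (smallest is 183 aa), large enough to
  suppress spurious micro-ORFs. Exposed in `PipelineConfig`.
* **Coding coverage** = 100 · Σ(cistron spans) / genome length, reported at
  one decimal, with `coding_coverage_int` for whole-percent prose-style
  reporting (round-half-up).
* **Completeness**: coding-complete requires a single contig, no N anywhere,
  and every cistron beginning with ATG and ending in a stop inside the
  sequence. A start codon at the very first base of a span is sufficient —
  genomes trimmed flush to the ORF (e.g. an ORF starting at position 2)
  still count.
* **Pairwise identity** over pre-aligned equal-length sequences excludes
  columns where either sequence carries N or a gap from both numerator and
  denominator; all-masked pairs yield NaN.

## Read recruitment and consensus (`recruit`)

The mapper anchors each mate by exact 21-mer lookup at staggered offsets on
both strands, scores every candidate placement by ungapped match count, and
keeps the best if at least 80% of overlapping bases match. Mapping quality
is 60 for a unique placement, otherwise
`min(60, round(10·log10(4)·(m₁ − m₂)))` from the best and second-best match
counts — a phred-style gap score in which two equally good placements force
MAPQ 0 (reads from exactly duplicated references are thereby excluded by
the MAPQ ≥ 25 filter, which is the point of the misalignment guard). A pair
is proper when both mates hit the same reference on opposite strands with
an implied insert inside configurable bounds (default 100–600 nt,
bracketing the simulator's 300 ± 30 insert distribution).

Counting follows the guard exactly: a pair qualifies iff both mates align
to the reference with MAPQ ≥ 25 (and as a proper pair, by default), and a
virus is detected at ≥ 5 qualifying pairs. Raising either threshold can
only lose detections (tested).

The consensus caller takes per-position base counts from the M segments of
qualifying alignments; the call is the single most frequent base when depth
≥ `min_depth` (default 1) and its fraction ≥ `min_base_frac` (default 0.5),
otherwise N — exact ties are always N, a deliberately conservative
ambiguity rule. The report defines **alignment length** as the unambiguous
(non-N) consensus columns, so identical + non-identical = alignment length
holds by construction, and percent identity is computed over those columns
(0 with an `identity_defined=False` flag when nothing is callable).
Indels are out of scope throughout: the mapper is ungapped, matching the
substitution-only simulator, and SAM output is restricted to M/S operations
(I/D/S are still parsed on input).

## Viral-load quantification (`viralload`)

RPKM = pairs · 10⁹ / (genome length bp · total mapped reads), where the
denominator counts reads mapped to *any* reference in the library (host
transcriptome + viruses) — the natural in-package reading of "per million
reads mapped"; it is a configuration default, not a hard assumption.
Pool-size adjustment divides by the number of individuals *before* the
ln(x+1) transform; the detection floor (0.001 by default) applies on the
transformed scale, boundary inclusive. The queen-vs-worker comparison is a
classical paired t-test (scipy) over stage-matched library pairs; fewer
than two pairs or zero variance of differences raises a degenerate-test
error rather than returning a fabricated statistic.

## Synthetic data (`synthdata`)

The generator emulates the data structure of a pooled ant-colony
metatranscriptome study:

* **Genomes.** Three default architectures mirror the characterized
  genomes: a 9,554-bp dicistronic picorna-like genome (ORFs at 597–6413 and
  6802–9318; 1938-aa and 838-aa polyproteins; composition 33.04/28.72/
  18.52/19.72% A/U/C/G), a 9,160-bp monocistronic iflavirus-like genome
  (ORF 165–8897, 2910 aa; its published composition sums to 93.4% — clearly
  a typographic artifact — so the fractions are renormalized to 1), and a
  9,866-bp negative-sense pentacistronic mononegavirus-like genome (five
  ORFs from position 2 to 9,766; G+C 44.92%). Coding-strand codons are
  drawn from a 61-codon distribution calibrated by iterative proportional
  fitting so realized mononucleotide composition lands within a percentage
  point or so of target (±3 points is the tested guarantee); UTR/IGR bases
  are drawn i.i.d. from the target. Planted peptides, when supplied, are
  preserved exactly via weighted synonymous-codon choice.
* **Recoverability.** Candidate genomes are rejection-sampled
  (deterministically in the seed) until `select_cistrons(find_orfs(·))` at
  min_aa = min(50, smallest planted ORF) returns exactly the planted
  coordinates: this removes chance ORFs in non-coding regions and chance
  in-frame upstream ATGs that would extend a planted cistron. A bare
  `find_orfs` call still reports antisense ORFs nested inside long
  cistrons — those are statistically unavoidable and are exactly what the
  cistron-selection step exists to discard.
* **Libraries.** Default plan: 7 caste/stage classes (queen/worker ×
  pupae/new/old, plus mixed males) × 2 replicate sets = 14 libraries,
  pools of 10–30 individuals, PE-91 reads, insert 300 ± 30 (truncated to
  ≥ 2 read lengths), 0.5% substitution errors, non-strand-specific
  (fragment strand random). Per-library virus fractions follow the
  qualitative infection pattern being emulated (the dicistrovirus-like
  virus peaks in newly emerged individuals, the iflavirus-like virus only
  in mature ones, the mononegavirus-like virus everywhere with higher loads
  in queens). Source counts are a single multinomial draw and are returned
  as exact truth; host reads are length-weighted across contigs.
* **Problem sizes.** Defaults of 2,000 pairs per library and a 40-contig
  host transcriptome keep a full run at desk scale while leaving dozens to
  hundreds of qualifying pairs per planted virus; the real study's
  million-read libraries differ only in depth, not structure.
* **What it does not emulate.** Indels and quality-profiled errors,
  strand-specific protocols, codon-usage realism, chimeric/misassembled
  contigs, and uneven transcript-level expression within the host. Tests
  passing on this generator therefore certify the algorithms' correctness
  on substitution-only, well-assembled data, not robustness to assembly
  artifacts.
* **Edge coverage.** With uniformly random fragment starts the expected
  depth in the terminal ~read-length of a genome is far below the mean
  coverage, so exact consensus recovery from a random library is
  unattainable at the termini no matter the depth; the exact-recovery test
  therefore tiles fragments to a uniform ≥ 30× depth at every position.

## Pipeline and CLI (`pipeline`, `cli`)

`run_pipeline` chains the four stages, carrying every parameter in
`PipelineConfig` (YAML-serializable; the config is echoed into each output
directory). Failures carry the stage name. Given fixed inputs the pipeline
is fully deterministic — there is no RNG outside the generator. The CLI
exposes each stage (`simulate`, `screen`, `recruit`, `characterize`,
`quantify`, `run-all`); domain validation errors exit with status 2.

## Known limitations

* No gapped alignment anywhere; divergent homologs detectable only through
  indel-free segments.
* The mapper's MAPQ model is bespoke; only its threshold semantics
  (≥ 25 ≡ "uniquely placed with a clear margin") are calibrated, not its
  absolute scale.
* Consensus calling ignores base qualities.
* The paired caste test assumes a sensible pairing of queen and worker
  libraries by stage; unpaired libraries are dropped from the test.
* E-values are comparable within a run, not across databases of different
  composition, and are not BLAST-identical.
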