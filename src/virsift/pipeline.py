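"""End-to-end orchestration: screen → characterize → recruit → quantify.

The pipeline takes assembled transcriptome contigs, per-library read pairs, a
labeled viral protein database and library metadata, and produces genome
annotations, consensus reports, viral-load records and the tabular outputs.
Every stage parameter is surfaced in :class:`PipelineConfig`, defaulting to
the study's values (100 nt / E 0.001 / word 11 / 30% identity; 5 pairs /
MAPQ 25; detection floor 0.001).
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import genomechar, recruit, seqio, viralload, viroscreen
from .errors import InputError, StageError, VirsiftError
from .genomechar import GenomeAnnotation
from .recruit import ConsensusReport, CountFilter
from .seqio import ReadPair, SeqRecord
from .viralload import LoadRecord
from .viroscreen import ProteinHit, ScreenParams

logger = logging.getLogger("virsift")


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, serializable to/from YAML."""

    screen: ScreenParams = field(default_factory=ScreenParams)
    count_filter: CountFilter = field(default_factory=CountFilter)
    min_aa: int = 50
    min_depth: int = 1
    min_base_frac: float = 0.5
    detection_floor: float = viralload.DETECTION_FLOOR
    seed_len: int = 21
    insert_bounds: tuple[int, int] = (100, 600)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["insert_bounds"] = list(self.insert_bounds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "screen" in d:
            d["screen"] = ScreenParams(**d["screen"])
        if "count_filter" in d:
            d["count_filter"] = CountFilter(**d["count_filter"])
        if "insert_bounds" in d:
            d["insert_bounds"] = tuple(d["insert_bounds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus the tables it wrote."""

    classifications: dict[str, str]
    hits: list[ProteinHit]
    viral_contigs: list[SeqRecord]
    annotations: dict[str, GenomeAnnotation]
    consensus_reports: list[ConsensusReport]
    loads: list[LoadRecord]
    genome_table: pd.DataFrame
    consensus_table: pd.DataFrame
    load_df: pd.DataFrame
    heatmap: pd.DataFrame | None
    caste_tests: pd.DataFrame


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except VirsiftError as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_pipeline(
    contigs: Sequence[SeqRecord],
    read_libraries: Mapping[str, Sequence[ReadPair]],
    protein_db: Sequence[SeqRecord],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the full discovery/characterization/quantification workflow.

    ``metadata`` must carry one row per library with columns ``library_id``,
    ``caste``, ``stage`` and ``n_individuals``. Deterministic given its
    inputs: reruns produce byte-identical tables.
    """
    cfg = config or PipelineConfig()
    meta = metadata.set_index("library_id")
    missing = [lib for lib in read_libraries if lib not in meta.index]
    if missing:
        raise InputError(f"libraries without metadata: {missing}")

    # --- screen -----------------------------------------------------------
    hits = _stage("screen")(viroscreen.translated_search, contigs, protein_db, cfg.screen)
    labels = _stage("screen")(viroscreen.classify_contigs, contigs, hits, cfg.screen)
    viral = [c for c in contigs if labels[c.id] == "virus"]
    logger.info(
        "screen: %d contigs, %d hits, %d classified viral", len(contigs), len(hits), len(viral)
    )

    # --- characterize -----------------------------------------------------
    annotations: dict[str, GenomeAnnotation] = {}
    for contig in viral:
        orfs = _stage("characterize")(genomechar.find_orfs, contig, cfg.min_aa)
        cistrons = genomechar.select_cistrons(orfs)
        annotations[contig.id] = _stage("characterize")(genomechar.organize, contig, cistrons)
    logger.info("characterize: %d genomes annotated", len(annotations))

    # --- recruit ----------------------------------------------------------
    consensus_reports: list[ConsensusReport] = []
    loads: list[LoadRecord] = []
    lib_ids = sorted(read_libraries)
    for lib_id in lib_ids:
        pairs = read_libraries[lib_id]
        alignments = _stage("recruit")(
            recruit.map_reads,
            pairs,
            list(contigs),
            cfg.seed_len,
            insert_bounds=cfg.insert_bounds,
        )
        total_mapped = len(alignments)  # reads mapped to any reference
        viral_alns = [a for a in alignments if a.ref_id in annotations]
        counts = _stage("recruit")(recruit.count_virus_reads, viral_alns, viral, cfg.count_filter)
        n_ind = int(meta.loc[lib_id, "n_individuals"])
        for contig in viral:
            pair_count, _detected = counts[contig.id]
            good = [
                a
                for a in viral_alns
                if a.ref_id == contig.id and a.mapq >= cfg.count_filter.min_mapq
            ]
            consensus_reports.append(
                _stage("recruit")(
                    recruit.call_consensus,
                    good,
                    contig,
                    cfg.min_depth,
                    cfg.min_base_frac,
                    query_label=lib_id,
                )
            )
            if total_mapped > 0:
                loads.append(
                    viralload.make_load_record(
                        lib_id,
                        contig.id,
                        pair_count,
                        len(contig.seq),
                        total_mapped,
                        n_ind,
                        floor=cfg.detection_floor,
                    )
                )
        logger.info(
            "recruit: library %s, %d/%d mates mapped, counts %s",
            lib_id,
            len(alignments),
            2 * len(pairs),
            {k: v[0] for k, v in counts.items()},
        )

    # --- quantify ---------------------------------------------------------
    load_df = viralload.load_table(loads)
    heatmap = None
    if loads and viral:
        heatmap = viralload.heatmap_matrix(loads, lib_ids, [c.id for c in viral])
    caste_tests = _caste_tests(loads, meta, [c.id for c in viral])

    gtable = genomechar.genome_table([annotations[c.id] for c in viral])
    ctable = recruit.consensus_table(consensus_reports)

    if out_dir is not None:
        _write_outputs(out_dir, cfg, viral, annotations, gtable, ctable, load_df, heatmap, caste_tests, consensus_reports)
    return PipelineResult(
        classifications=labels,
        hits=list(hits),
        viral_contigs=viral,
        annotations=annotations,
        consensus_reports=consensus_reports,
        loads=loads,
        genome_table=gtable,
        consensus_table=ctable,
        load_df=load_df,
        heatmap=heatmap,
        caste_tests=caste_tests,
    )


def _caste_tests(
    loads: Sequence[LoadRecord], meta: pd.DataFrame, virus_ids: Sequence[str]
) -> pd.DataFrame:
    """Paired queen-vs-worker t-tests per virus over stage-matched libraries."""
    rows = []
    by_key = {(r.library_id, r.virus_id): r.ln1p for r in loads}
    for vid in virus_ids:
        queens, workers = [], []
        for stage in sorted(set(meta["stage"])):
            q_libs = sorted(meta.index[(meta["caste"] == "queen") & (meta["stage"] == stage)])
            w_libs = sorted(meta.index[(meta["caste"] == "worker") & (meta["stage"] == stage)])
            for q, w in zip(q_libs, w_libs):
                if (q, vid) in by_key and (w, vid) in by_key:
                    queens.append(by_key[(q, vid)])
                    workers.append(by_key[(w, vid)])
        row = {"virus_id": vid, "n_pairs": len(queens)}
        try:
            t, df, p = viralload.paired_caste_test(queens, workers)
            row.update({"t": t, "df": df, "p": p})
        except VirsiftError as exc:
            row.update({"t": float("nan"), "df": max(len(queens) - 1, 0), "p": float("nan")})
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(
    out_dir, cfg, viral, annotations, gtable, ctable, load_df, heatmap, caste_tests, reports
) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(out_dir, "config.yml"))
    gtable.to_csv(os.path.join(out_dir, "table1.tsv"), sep="\t", index=False)
    ctable.to_csv(os.path.join(out_dir, "table2.tsv"), sep="\t", index=False)
    load_df.to_csv(os.path.join(out_dir, "loads.tsv"), sep="\t", index=False)
    if heatmap is not None:
        heatmap.to_csv(os.path.join(out_dir, "heatmap.tsv"), sep="\t")
        viralload.plot_heatmap(heatmap, os.path.join(out_dir, "heatmap.png"))
    caste_tests.to_csv(os.path.join(out_dir, "caste_tests.tsv"), sep="\t", index=False)
    cons_dir = os.path.join(out_dir, "consensus")
    os.makedirs(cons_dir, exist_ok=True)
    for contig in viral:
        seqio.write_gff3(annotations[contig.id], os.path.join(out_dir, f"{contig.id}.gff3"))
    by_virus: dict[str, list] = {}
    for rep in reports:
        by_virus.setdefault(rep.ref_id, []).append(rep)
    for vid, reps in by_virus.items():
        seqio.write_fasta(
            [
                SeqRecord(
                    id=f"{vid}_{r.query_label}", seq=r.consensus_seq, alphabet="nt"
                )
                for r in reps
                if set(r.consensus_seq) != {"N"}
            ]
            or [SeqRecord(id=f"{vid}_all_ambiguous", seq="N", alphabet="nt")],
            os.path.join(cons_dir, f"{vid}.fasta"),
        )


#: TSV schemas of the tables the pipeline writes, used for output validation.
OUTPUT_SCHEMAS = {
    "table1.tsv": [
        "Virus",
        "Genome length (bp)",
        "ORFs",
        "Genome region covered by gene (%)",
        "Base composition",
        "Sense",
        "Coding complete",
    ],
    "table2.tsv": [
        "Query",
        "Reference",
        "Length (bp)",
        "Ambiguous bases (bp)",
        "Alignment length (bp)",
        "Percentage Identity",
        "Identical bases (bp)",
        "Non-identical bases (bp)",
    ],
    "loads.tsv": [
        "library_id",
        "virus_id",
        "pair_count",
        "total_mapped",
        "rpkm",
        "rpkm_per_ind",
        "ln1p",
        "detected",
    ],
}
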