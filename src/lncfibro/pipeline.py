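"""End-to-end orchestration: filter -> DE (tissue, urine) -> cis -> Smad scan
-> concordance -> optional qPCR, with a machine-readable run report.

Stages hand off through plain files (TSV/BED/JSON); each stage is also an
importable operation, so the pipeline is a thin sequencer plus bookkeeping.
The Smad3 promoter scan runs on UP-regulated candidate lncRNAs only; the cis
search runs on ALL dysregulated candidate lncRNAs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .biomarker_qpcr import (
    concordance_summary,
    concordant_biomarkers,
    delta_delta_ct,
    qpcr_records_to_frame,
    spike_in_normalize,
)
from .cis_neighbors import find_cis_neighbors
from .expression_de import call_de, de_summary
from .io_formats import (
    read_counts,
    read_fasta,
    read_gtf,
    spliced_sequence,
    write_bed,
)
from .lncrna_filter import OrfLengthPredictor, consensus_lnc_filter, make_calls
from .models import de_records_to_frame, genome_as_dict
from .promoter_motif import (
    prioritize_tgfb_candidates,
    promoter_interval,
    scan_promoter,
)

logger = logging.getLogger("lncfibro")


class PipelineValidationError(ValueError):
    """Configuration or input problem detected before any stage runs."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Input paths and the analysis parameters of a pipeline run."""

    genome: str
    annotation: str
    tissue_counts: str
    tissue_samples: str
    urine_counts: str
    urine_samples: str
    out_dir: str = "pipeline_out"
    qpcr_tissue: str | None = None
    qpcr_urine: str | None = None
    qpcr_tissue_reference: str = "GAPDH"
    qpcr_urine_reference: str = "cel-miR-39"
    min_lnc_length: int = 200
    lfc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    cis_window: int = 100_000
    promoter_length: int = 5000
    motif: str = "CAGACA"
    motif_threshold: int = 4
    pseudocount: float = 0.25
    orf_coding_threshold: int = 300
    seed: int = 1
    both_strands: bool = False
    bh_correction: bool = False
    scan_all_dysregulated: bool = False

    def validate(self) -> None:
        for name in ("min_lnc_length", "lfc_cutoff", "p_cutoff", "cis_window",
                     "promoter_length", "motif_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineValidationError(f"{name} must be positive")
        if self.pseudocount < 0:
            raise PipelineValidationError("pseudocount must be >= 0")
        if not self.motif or set(self.motif) - set("ACGT"):
            raise PipelineValidationError(f"motif must be over ACGT, got {self.motif!r}")
        for name in ("genome", "annotation", "tissue_counts", "tissue_samples",
                     "urine_counts", "urine_samples"):
            if not Path(getattr(self, name)).exists():
                raise PipelineValidationError(f"input path {name} does not exist: {getattr(self, name)}")
        for name in ("qpcr_tissue", "qpcr_urine"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise PipelineValidationError(f"input path {name} does not exist: {val}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class RunReport:
    parameters: dict
    version: str = __version__
    started: str = ""
    finished: str = ""
    n_transcripts: int = 0
    n_lnc_candidates: int = 0
    tissue_de: dict = field(default_factory=dict)
    urine_de: dict = field(default_factory=dict)
    n_dysregulated_lnc_tissue: int = 0
    n_up_lnc_tissue: int = 0
    n_cis_pairs: int = 0
    n_prioritized: int = 0
    prioritized_genes: list[str] = field(default_factory=list)
    concordance: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _stage(name: str):
    logger.info("=== stage: %s ===", name)


def run_pipeline(config: PipelineConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        parameters={k: v for k, v in config.__dict__.items()},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    _stage("load inputs")
    try:
        genome = genome_as_dict(read_fasta(config.genome))
        genes = read_gtf(config.annotation)
    except Exception as exc:
        raise StageError(f"load inputs: {exc}") from exc
    by_gene = {g.gene_id: g for g in genes}
    transcripts = [t for g in genes for t in g.transcripts]
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    lengths = {t.transcript_id: t.exonic_length for t in transcripts}
    report.n_transcripts = len(transcripts)

    _stage("consensus lncRNA filter")
    try:
        sequences = {t.transcript_id: spliced_sequence(t, genome) for t in transcripts}
        calls = make_calls(sequences, [OrfLengthPredictor(config.orf_coding_threshold)])
        candidate_set = consensus_lnc_filter(transcripts, calls, config.min_lnc_length)
    except Exception as exc:
        raise StageError(f"lncRNA filter: {exc}") from exc
    candidates = candidate_set.candidate_ids
    report.n_lnc_candidates = len(candidates)
    with open(out / "lnc_candidates.tsv", "w") as fh:
        fh.write("transcript_id\n")
        for tid in sorted(candidates):
            fh.write(tid + "\n")
    with open(out / "filter_removed.tsv", "w") as fh:
        fh.write("transcript_id\treason\n")
        for tid, reason in sorted(candidate_set.removed.items()):
            fh.write(f"{tid}\t{reason}\n")

    de_records = {}
    for compartment, counts_path, sheet_path in (
        ("tissue", config.tissue_counts, config.tissue_samples),
        ("urine", config.urine_counts, config.urine_samples),
    ):
        _stage(f"differential expression ({compartment})")
        try:
            matrix = read_counts(counts_path, sheet_path, annotation_ids=set(lengths))
            records = call_de(
                matrix,
                lengths,
                lfc_cutoff=config.lfc_cutoff,
                p_cutoff=config.p_cutoff,
                pseudocount=config.pseudocount,
                bh_correction=config.bh_correction,
            )
        except Exception as exc:
            raise StageError(f"DE {compartment}: {exc}") from exc
        de_records[compartment] = records
        frame = de_records_to_frame(records)
        frame.to_csv(out / f"de_{compartment}.tsv", sep="\t", index=False)
        summary = de_summary(records)
        lnc_records = [r for r in records if r.transcript_id in candidates]
        summary["lnc"] = de_summary(lnc_records)
        coding_records = [
            r for r in records
            if r.transcript_id in gene_of
            and by_gene[gene_of[r.transcript_id]].biotype == "protein_coding"
        ]
        summary["protein_coding"] = de_summary(coding_records)
        setattr(report, f"{compartment}_de", summary)

    tissue_records = de_records["tissue"]
    dysregulated_lnc = sorted(
        {gene_of[r.transcript_id] for r in tissue_records
         if r.significant and r.transcript_id in candidates}
    )
    up_lnc = sorted(
        {gene_of[r.transcript_id] for r in tissue_records
         if r.significant and r.direction == "up" and r.transcript_id in candidates}
    )
    report.n_dysregulated_lnc_tissue = len(dysregulated_lnc)
    report.n_up_lnc_tissue = len(up_lnc)

    _stage("cis-neighbor search")
    try:
        coding_genes = [g for g in genes if g.biotype == "protein_coding"]
        pairs = find_cis_neighbors(
            [by_gene[g] for g in dysregulated_lnc], coding_genes, window=config.cis_window
        )
    except Exception as exc:
        raise StageError(f"cis neighbors: {exc}") from exc
    report.n_cis_pairs = len(pairs)
    with open(out / "cis_pairs.tsv", "w") as fh:
        fh.write("lnc_gene_id\tcoding_gene_id\tdistance\trelation\n")
        for p in pairs:
            fh.write(f"{p.lnc_gene_id}\t{p.coding_gene_id}\t{p.distance}\t{p.relation}\n")

    _stage("Smad3 promoter scan")
    scan_targets = dysregulated_lnc if config.scan_all_dysregulated else up_lnc
    try:
        scan_results = []
        promoter_rows, hit_rows = [], []
        for gid in scan_targets:
            prom = promoter_interval(by_gene[gid], genome, config.promoter_length)
            res = scan_promoter(
                prom,
                motif=config.motif,
                include_reverse_complement=config.both_strands,
                threshold=config.motif_threshold,
            )
            scan_results.append(res)
            promoter_rows.append((prom.contig, prom.start, prom.end, gid, res.k, prom.strand))
            for pos, strand_label in zip(res.hit_positions, res.hit_strands):
                # report hits in genomic coordinates
                if prom.strand == "+":
                    gs = prom.start + pos
                else:
                    gs = prom.end - pos - len(config.motif)
                hit_rows.append(
                    (prom.contig, gs, gs + len(config.motif), f"{gid}:{strand_label}", 0, prom.strand)
                )
        prioritized = prioritize_tgfb_candidates(scan_results, config.motif_threshold)
    except Exception as exc:
        raise StageError(f"Smad3 scan: {exc}") from exc
    report.n_prioritized = len(prioritized)
    report.prioritized_genes = sorted(prioritized)
    write_bed(promoter_rows, out / "promoters.bed")
    write_bed(hit_rows, out / "motif_hits.bed")
    with open(out / "smad_scan.tsv", "w") as fh:
        fh.write("gene_id\tk\tprioritized\n")
        for res in scan_results:
            fh.write(f"{res.gene_id}\t{res.k}\t{res.prioritized}\n")

    _stage("tissue-urine concordance")
    try:
        lnc_tissue = [r for r in tissue_records if r.transcript_id in candidates]
        lnc_urine = [r for r in de_records["urine"] if r.transcript_id in candidates]
        conc = concordant_biomarkers(lnc_tissue, lnc_urine)
    except Exception as exc:
        raise StageError(f"concordance: {exc}") from exc
    report.concordance = concordance_summary(conc)
    with open(out / "concordant_biomarkers.tsv", "w") as fh:
        fh.write("transcript_id\ttissue_direction\turine_direction\tconcordant\n")
        for r in conc:
            fh.write(f"{r.transcript_id}\t{r.tissue_direction}\t{r.urine_direction}\t{r.concordant}\n")

    for table_name, path, reference in (
        ("tissue", config.qpcr_tissue, config.qpcr_tissue_reference),
        ("urine", config.qpcr_urine, config.qpcr_urine_reference),
    ):
        if path is None:
            continue
        _stage(f"qPCR quantification ({table_name})")
        try:
            import pandas as pd

            table = pd.read_csv(path, sep="\t")
            if table_name == "urine":
                records, summary = spike_in_normalize(table, spike_id=reference)
            else:
                records, summary = delta_delta_ct(table, reference_gene=reference)
        except Exception as exc:
            raise StageError(f"qPCR {table_name}: {exc}") from exc
        qpcr_records_to_frame(records).to_csv(out / f"qpcr_{table_name}_folds.tsv", sep="\t", index=False)
        summary.to_csv(out / f"qpcr_{table_name}_summary.tsv", sep="\t", index=False)
        report.qpcr[table_name] = {
            row["target"]: {"group": row["group"], "mean_fold": row["mean_fold"], "p_value": row["p_value"]}
            for _, row in summary.iterrows()
            if row["group"] == "UUO"
        }

    # internal consistency assertions on every run
    assert set(report.prioritized_genes) <= set(scan_targets)
    tissue_sig = {r.transcript_id for r in tissue_records if r.significant}
    urine_sig = {r.transcript_id for r in de_records["urine"] if r.significant}
    assert all(r.transcript_id in tissue_sig & urine_sig for r in conc)
    assert all(p.lnc_gene_id in set(dysregulated_lnc) for p in pairs)

    report.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report.to_json(out / "report.json")
    return report
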