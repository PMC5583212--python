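"""Readers and writers for the flat formats the pipeline touches.

GTF is 1-based closed on disk; everything in memory is 0-based half-open,
with the +/-1 conversion done here and nowhere else. FASTA goes through
Biopython; tables through pandas.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .dna import revcomp
from .models import ExpressionMatrix, GeneModel, GenomeSequence, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

# GTF biotype tokens mapped onto the three classes the pipeline distinguishes
_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "lncRNA": "lncRNA_candidate",
    "lincRNA": "lncRNA_candidate",
    "lncRNA_candidate": "lncRNA_candidate",
    "other": "other",
}


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF into GeneModels (exon features only; coordinates converted).

    Raises ValueError naming the offending line number on malformed input.
    """
    transcripts: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GTF parse error at line {lineno}: expected 9 fields, got {len(fields)}")
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"GTF parse error at line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ValueError(f"GTF parse error at line {lineno}: bad interval {start1}-{end1}")
            attrs = _parse_attributes(attr_s)
            if "transcript_id" not in attrs:
                raise ValueError(f"GTF parse error at line {lineno}: exon without transcript_id")
            if "gene_id" not in attrs:
                raise ValueError(f"GTF parse error at line {lineno}: exon without gene_id")
            if strand == ".":
                warnings.warn(f"GTF line {lineno}: unstranded exon treated as '+'")
                strand = "+"
            if strand not in ("+", "-"):
                raise ValueError(f"GTF parse error at line {lineno}: bad strand {strand!r}")
            tid = attrs["transcript_id"]
            biotype_token = (
                attrs.get("transcript_biotype")
                or attrs.get("gene_biotype")
                or attrs.get("biotype")
            )
            rec = transcripts.get(tid)
            if rec is None:
                rec = {
                    "gene_id": attrs["gene_id"],
                    "contig": contig,
                    "strand": strand,
                    "exons": [],
                    "biotype": _BIOTYPE_MAP.get(biotype_token, "other") if biotype_token else "other",
                }
                transcripts[tid] = rec
                order.append(tid)
            # 1-based closed -> 0-based half-open
            rec["exons"].append((start1 - 1, end1))

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tid in order:
        rec = transcripts[tid]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            contig=rec["contig"],
            strand=rec["strand"],
            exons=sorted(rec["exons"]),
            biotype=rec["biotype"],
        )
        gid = rec["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, contig=rec["contig"], strand=rec["strand"])
            gene_order.append(gid)
        genes[gid].transcripts.append(model)
    return [genes[g] for g in gene_order]


def write_gtf(genes: list[GeneModel], path: str | Path) -> None:
    """Emit exon lines (0-based half-open back to 1-based closed)."""
    with open(path, "w") as fh:
        for gene in genes:
            for t in gene.transcripts:
                for start, end in t.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'gene_biotype "{t.biotype}";'
                    )
                    fh.write(
                        f"{t.contig}\tlncfibro\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA contigs, uppercased, description after first whitespace dropped."""
    contigs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id  # SeqIO id is the first whitespace token
        if name in seen:
            raise ValueError(f"duplicate contig name: {name}")
        seen.add(name)
        contigs.append(GenomeSequence(contig_name=name, sequence=str(rec.seq).upper()))
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_fasta(contigs: list[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_name}\n")
            seq = c.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_CONDITION_NORM = {"uuo": "UUO", "sham": "Sham"}


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "condition", "compartment", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet["condition"] = [
        _CONDITION_NORM.get(c.lower(), c) for c in sheet["condition"]
    ]
    bad = set(sheet["condition"]) - {"UUO", "Sham"}
    if bad:
        raise ValueError(f"unknown conditions in sample sheet: {sorted(bad)}")
    sheet["compartment"] = sheet["compartment"].str.lower()
    return sheet.set_index("sample")


def read_counts(
    path: str | Path,
    sample_sheet_path: str | Path,
    annotation_ids: set[str] | None = None,
) -> ExpressionMatrix:
    """Load a transcript x sample count TSV plus its sample sheet.

    Counts must be non-negative integers; every sample column must appear in
    the sheet. Transcripts absent from ``annotation_ids`` (when given) are
    retained but flagged unannotated, with a warning.
    """
    table = pd.read_csv(path, sep="\t")
    if "transcript_id" not in table.columns:
        raise ValueError("count table must have a transcript_id column")
    table = table.set_index("transcript_id")
    numeric = table.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError("count table contains non-numeric entries")
    if (numeric < 0).any().any():
        raise ValueError("count table contains negative counts")
    if ((numeric % 1) != 0).any().any():
        raise ValueError("count table contains non-integer counts")
    counts = numeric.astype(int)

    sheet = read_sample_sheet(sample_sheet_path)
    missing = set(counts.columns) - set(sheet.index)
    if missing:
        raise ValueError(f"samples in count matrix missing from sample sheet: {sorted(missing)}")
    sheet = sheet.loc[list(counts.columns)]

    unannotated: set[str] = set()
    if annotation_ids is not None:
        unannotated = set(counts.index) - set(annotation_ids)
        if unannotated:
            warnings.warn(
                f"{len(unannotated)} transcript rows absent from the annotation "
                "(retained, flagged unannotated)"
            )
    return ExpressionMatrix(counts=counts, samples=sheet, unannotated=unannotated)


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path, sheet_path: str | Path) -> None:
    matrix.counts.rename_axis("transcript_id").to_csv(counts_path, sep="\t")
    matrix.samples.rename_axis("sample").to_csv(sheet_path, sep="\t")


def write_bed(intervals: list[tuple], path: str | Path) -> None:
    """Write BED6 lines from (contig, start, end, name, score, strand) tuples."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in intervals:
            if start >= end:
                raise ValueError(f"BED interval {name}: start {start} >= end {end}")
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple]:
    rows: list[tuple] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, score, strand = line.rstrip("\n").split("\t")
            rows.append((contig, int(start), int(end), name, int(score), strand))
    return rows


def spliced_sequence(transcript: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence in transcription orientation."""
    if transcript.contig not in genome:
        raise ValueError(f"contig {transcript.contig} not in genome")
    seq = "".join(genome[transcript.contig][s:e] for s, e in transcript.exons)
    return seq if transcript.strand == "+" else revcomp(seq)
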