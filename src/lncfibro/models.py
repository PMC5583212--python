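"""Core domain containers: genome sequences, gene/transcript models, count matrices.

All genomic intervals are 0-based half-open; format readers convert at the
boundary (GTF is 1-based closed on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GenomeSequence:
    """A single contig: name plus uppercase DNA over {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def genome_as_dict(contigs: list[GenomeSequence]) -> dict[str, str]:
    return {c.contig_name: c.sequence for c in contigs}


@dataclass
class TranscriptModel:
    """One transcript: stranded exon chain on a contig.

    ``exons`` are non-overlapping 0-based half-open intervals sorted by start.
    ``exonic_length`` is the spliced length (sum of exon lengths), the L of
    RPKM's "per kilobase of exon".
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"transcript {self.transcript_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if self.exons and self.exonic_length <= 0:
            raise ValueError(f"transcript {self.transcript_id}: non-positive exonic length")

    @property
    def exonic_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene locus: the span covering all isoforms, with a strand-aware TSS.

    TSS is the most 5' transcript start across isoforms: span start on the
    + strand, span end - 1 on the - strand. One promoter per gene keeps the
    Smad-motif count per gene well-defined.
    """

    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for t in self.transcripts:
            if t.contig != self.contig:
                raise ValueError(f"gene {self.gene_id}: transcript {t.transcript_id} on other contig")

    @property
    def span(self) -> tuple[int, int]:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def tss(self) -> int:
        start, end = self.span
        return start if self.strand == "+" else end - 1

    @property
    def biotype(self) -> str:
        """Gene-level biotype: protein_coding if any isoform is, else the first isoform's."""
        if any(t.biotype == "protein_coding" for t in self.transcripts):
            return "protein_coding"
        return self.transcripts[0].biotype if self.transcripts else "other"


@dataclass
class ExpressionMatrix:
    """Transcript x sample integer counts with per-sample metadata.

    ``counts``: DataFrame indexed by transcript_id, one column per sample.
    ``samples``: DataFrame indexed by sample id with columns
    condition ({UUO, Sham}), compartment ({tissue, urine}), replicate.
    Library size N[j] is the column sum of the analyzed matrix.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unannotated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_compartment(self, compartment: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["compartment"] == compartment]
        return ExpressionMatrix(
            counts=self.counts[list(keep)],
            samples=self.samples.loc[keep],
            unannotated=set(self.unannotated),
        )


@dataclass
class DERecord:
    """Per-transcript differential-expression call (UUO vs Sham)."""

    transcript_id: str
    mean_rpkm_uuo: float
    mean_rpkm_sham: float
    log2fc: float
    p_value: float
    direction: str  # up / down / none
    significant: bool


def de_records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "mean_rpkm_uuo": [r.mean_rpkm_uuo for r in records],
            "mean_rpkm_sham": [r.mean_rpkm_sham for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )
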