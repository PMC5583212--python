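"""Promoter extraction and Smad-binding-element (CAGACA) scanning.

The putative promoter is the 5 kb immediately upstream of a gene's TSS,
returned in transcription orientation (reverse-complemented for - strand
genes) so that position 0 is the end farthest from the TSS. The scan counts
every exact, possibly overlapping occurrence of the motif on the sense
strand by default; genes whose promoter carries more than 4 motifs
(strictly: k = 5 passes, k = 4 fails) are prioritized as TGF-beta/Smad3
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dna import is_acgt, revcomp
from .models import GeneModel

SMAD3_MOTIF = "CAGACA"
DEFAULT_PROMOTER_LENGTH = 5000
DEFAULT_THRESHOLD = 4


@dataclass
class PromoterInterval:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    clipped: bool
    sequence: str  # transcription orientation


@dataclass
class MotifScanResult:
    gene_id: str
    motif: str
    hit_positions: list[int]
    hit_strands: list[str]
    strands_scanned: set[str] = field(default_factory=lambda: {"sense"})
    prioritized: bool = False

    @property
    def k(self) -> int:
        return len(self.hit_positions)


def promoter_interval(
    gene: GeneModel,
    genome: dict[str, str],
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> PromoterInterval:
    """Extract the promoter window upstream of the gene's TSS.

    + strand: [max(0, tss - length), tss); - strand: [tss + 1,
    min(contig_end, tss + 1 + length)), reverse-complemented. ``clipped``
    marks truncation at a contig edge; a zero-length window is an error.
    """
    if gene.contig not in genome:
        raise ValueError(f"gene {gene.gene_id}: contig {gene.contig} not in genome")
    contig_seq = genome[gene.contig]
    tss = gene.tss
    if gene.strand == "+":
        start, end = max(0, tss - length), tss
        clipped = start == 0 and tss < length
        seq = contig_seq[start:end]
    else:
        start = tss + 1
        end = min(len(contig_seq), tss + 1 + length)
        clipped = end == len(contig_seq) and len(contig_seq) - start < length
        seq = revcomp(contig_seq[start:end])
    if end <= start:
        raise ValueError(f"gene {gene.gene_id}: promoter window is empty (TSS at contig edge)")
    return PromoterInterval(gene.gene_id, gene.contig, start, end, gene.strand, clipped, seq)


def scan_motif(
    sequence: str,
    motif: str = SMAD3_MOTIF,
    include_reverse_complement: bool = False,
) -> tuple[list[int], list[str]]:
    """All (possibly overlapping) exact motif occurrences in ``sequence``.

    Returns (positions, strands) sorted by position; with
    ``include_reverse_complement`` occurrences of the reverse complement are
    added as antisense hits. N never matches.
    """
    if not motif or not is_acgt(motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    for word, label in [(motif, "sense")] + (
        [(revcomp(motif), "antisense")] if include_reverse_complement else []
    ):
        pos = seq.find(word)
        while pos != -1:
            hits.append((pos, label))
            pos = seq.find(word, pos + 1)
    hits.sort()
    return [p for p, _ in hits], [s for _, s in hits]


def scan_promoter(
    promoter: PromoterInterval,
    motif: str = SMAD3_MOTIF,
    include_reverse_complement: bool = False,
    threshold: int = DEFAULT_THRESHOLD,
) -> MotifScanResult:
    positions, strands = scan_motif(promoter.sequence, motif, include_reverse_complement)
    result = MotifScanResult(
        gene_id=promoter.gene_id,
        motif=motif,
        hit_positions=positions,
        hit_strands=strands,
        strands_scanned={"sense", "antisense"} if include_reverse_complement else {"sense"},
    )
    result.prioritized = result.k > threshold
    return result


def prioritize_tgfb_candidates(
    results: list[MotifScanResult], threshold: int = DEFAULT_THRESHOLD
) -> set[str]:
    """Genes with strictly more than ``threshold`` motif hits in the promoter."""
    seen: set[str] = set()
    prioritized: set[str] = set()
    for r in results:
        if r.gene_id in seen:
            raise ValueError(f"duplicate scan result for gene {r.gene_id}")
        seen.add(r.gene_id)
        r.prioritized = r.k > threshold
        if r.prioritized:
            prioritized.add(r.gene_id)
    return prioritized
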