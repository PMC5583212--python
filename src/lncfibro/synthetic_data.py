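"""Synthetic genome, annotation, counts and qPCR tables with planted truth.

Emulates the study design the pipeline targets: UUO vs Sham, renal tissue
and urine compartments, 3 replicates per group, negative-binomial transcript
counts with planted log2 fold changes, CAGACA copies planted in selected
lncRNA promoters, and protein-coding genes placed at exact gap distances
inside (or outside) the +/-100 kb cis window of lncRNA loci.

Layout guarantees that make planted truth exactly recoverable:

* every lncRNA promoter (5 kb) is built explicitly — background CAGACA
  occurrences are disrupted before planting, so the sense-strand scan count
  equals the planted count exactly;
* lncRNA blocks are separated by >100 kb from every coding gene except the
  intended cis partner, whose span gap is realized exactly;
* lncRNA transcripts are scrubbed of ORFs longer than 300 nt while coding
  transcripts carry a planted 456 nt ORF, so the built-in ORF predictor
  separates the classes perfectly.

One global seed drives a named substream per artifact (genome, counts per
compartment, qPCR per table), so artifacts regenerate independently and all
outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dna import STOP_CODONS, revcomp
from .io_formats import write_counts, write_fasta, write_gtf
from .lncrna_filter import _longest_orf
from .models import ExpressionMatrix, GeneModel, GenomeSequence, TranscriptModel
from .promoter_motif import SMAD3_MOTIF, scan_motif

# fixed geometry of every synthetic gene
GENE_BODY = 2000
EXONS_REL = ((0, 400), (1200, 2000))  # genomic, transcript length 1200
TRANSCRIPT_LEN = 1200
PROMOTER_LEN = 5000
BLOCK_SPACING = 110_001  # > cis window, isolates lncRNA blocks
BG_SPACING = 8000  # background coding gene pitch
ORF_PLANT_OFFSET = 30
ORF_PLANT_CODONS = 150  # 3 + 450 + 3 = 456 nt ORF, past the 300 nt threshold

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_MUTATE = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}

_STREAMS = {
    "genome": 0,
    "counts_tissue": 1,
    "counts_urine": 2,
    "qpcr_tissue": 3,
    "qpcr_urine": 4,
}

_CIS_GAPS = [100, 1000, 5000, 20000, 50000, 75000, 99_999, 100_000]
_PRIORITIZED_KS = [5, 6, 7, 8, 9, 10]
_BACKGROUND_KS = [0, 1, 2, 3, 4]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def lnc_id(i: int) -> str:
    return f"LNC{i + 1:04d}"


def pcg_id(i: int) -> str:
    return f"PCG{i + 1:04d}"


def transcript_of(gene_id: str) -> str:
    return gene_id + ".1"


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults encode the reference conditions the test suite exercises:
    3 replicates per group, 40 DE lncRNAs at |log2FC| = 2 (20 up, 20 down),
    baseline mean 200, NB dispersion 0.05, 6 promoters planted with 5..10
    CAGACA copies and 14 with 0..4, and 25 cis pairs at exact gap distances
    including the inclusive 100 kb boundary.
    """

    seed: int = 1
    n_contigs: int = 2
    contig_length: int | None = None  # None: auto-sized to fit the layout
    n_coding_genes: int = 600
    n_lnc_genes: int = 60
    n_de_lnc_up: int = 20
    n_de_lnc_down: int = 20
    n_de_mrna: int = 20
    true_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean: float = 200.0
    replicates_per_group: int = 3
    n_cis_pairs: int = 25
    planted_motif_counts: dict[str, int] | None = None  # lnc gene id -> copies
    neighbor_layout: dict[str, int] | None = None  # lnc gene id -> exact span gap
    qpcr_noise_sd: float = 0.15
    qpcr_base_ct_range: tuple[float, float] = (18.0, 26.0)

    def __post_init__(self) -> None:
        if min(self.n_coding_genes, self.n_lnc_genes) < 1:
            raise ValueError("need at least one coding and one lncRNA gene")
        if min(self.n_de_lnc_up, self.n_de_lnc_down, self.n_de_mrna, self.n_cis_pairs) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_de_lnc_up + self.n_de_lnc_down > self.n_lnc_genes:
            raise ValueError("n_de_lnc_up + n_de_lnc_down exceeds n_lnc_genes")
        if self.n_de_mrna > self.n_coding_genes:
            raise ValueError("n_de_mrna exceeds n_coding_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.qpcr_noise_sd < 0:
            raise ValueError("qpcr_noise_sd must be >= 0")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")

    # ---- derived planted truth ----------------------------------------

    @property
    def up_lnc_ids(self) -> list[str]:
        return [lnc_id(i) for i in range(self.n_de_lnc_up)]

    @property
    def down_lnc_ids(self) -> list[str]:
        return [lnc_id(self.n_de_lnc_up + i) for i in range(self.n_de_lnc_down)]

    @property
    def nonde_lnc_ids(self) -> list[str]:
        first = self.n_de_lnc_up + self.n_de_lnc_down
        return [lnc_id(i) for i in range(first, self.n_lnc_genes)]

    def motif_counts(self) -> dict[str, int]:
        if self.planted_motif_counts is not None:
            return dict(self.planted_motif_counts)
        counts: dict[str, int] = {}
        ups = self.up_lnc_ids
        n_prior = min(len(_PRIORITIZED_KS), len(ups))
        for i, gid in enumerate(ups[:n_prior]):
            counts[gid] = _PRIORITIZED_KS[i]
        for i, gid in enumerate(ups[n_prior:]):
            counts[gid] = _BACKGROUND_KS[i % len(_BACKGROUND_KS)]
        return counts

    def cis_layout(self) -> dict[str, int]:
        if self.neighbor_layout is not None:
            return dict(self.neighbor_layout)
        # interleave up- and down-regulated lncRNAs so both carry partners
        targets: list[str] = []
        for u, d in zip(self.up_lnc_ids, self.down_lnc_ids):
            targets.extend([u, d])
        longer = self.up_lnc_ids[len(self.down_lnc_ids):] or self.down_lnc_ids[len(self.up_lnc_ids):]
        targets.extend(longer)
        targets = targets[: min(self.n_cis_pairs, len(targets))]
        return {gid: _CIS_GAPS[i % len(_CIS_GAPS)] for i, gid in enumerate(targets)}

    def urine_de(self) -> tuple[dict[str, float], dict[str, float]]:
        """Urine lncRNA DE sets (id -> signed log2FC), independent of tissue.

        Planted so the tissue/urine intersection yields 5 concordant-up,
        2 concordant-down and 1 discordant lncRNA, plus urine-only calls.
        """
        lfc = self.true_log2fc
        up: dict[str, float] = {}
        down: dict[str, float] = {}
        for gid in self.up_lnc_ids[: min(5, len(self.up_lnc_ids))]:
            up[gid] = lfc  # concordant up
        if self.down_lnc_ids:
            up[self.down_lnc_ids[0]] = lfc  # discordant (down in tissue)
        for gid in self.down_lnc_ids[1 : min(3, len(self.down_lnc_ids))]:
            down[gid] = -lfc  # concordant down
        extra = self.nonde_lnc_ids
        for gid in extra[: min(3, len(extra))]:
            up[gid] = lfc  # urine-only up
        for gid in extra[3 : 3 + min(2, max(0, len(extra) - 3))]:
            down[gid] = -lfc  # urine-only down
        return up, down


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests (ids are gene ids)."""

    de_lnc_up: dict[str, float]
    de_lnc_down: dict[str, float]
    de_mrna: dict[str, float]
    urine_de_lnc_up: dict[str, float]
    urine_de_lnc_down: dict[str, float]
    urine_de_mrna: dict[str, float]
    motif_counts: dict[str, int]
    cis_pairs: set[tuple[str, str, int]]
    qpcr_true_folds: dict[str, dict[str, float]] = field(default_factory=dict)

    def tissue_lfc(self, gene_id: str) -> float:
        for table in (self.de_lnc_up, self.de_lnc_down, self.de_mrna):
            if gene_id in table:
                return table[gene_id]
        return 0.0

    def urine_lfc(self, gene_id: str) -> float:
        for table in (self.urine_de_lnc_up, self.urine_de_lnc_down, self.urine_de_mrna):
            if gene_id in table:
                return table[gene_id]
        return 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_lnc_up": self.de_lnc_up,
            "de_lnc_down": self.de_lnc_down,
            "de_mrna": self.de_mrna,
            "urine_de_lnc_up": self.urine_de_lnc_up,
            "urine_de_lnc_down": self.urine_de_lnc_down,
            "urine_de_mrna": self.urine_de_mrna,
            "motif_counts": self.motif_counts,
            "cis_pairs": sorted(list(p) for p in self.cis_pairs),
            "qpcr_true_folds": self.qpcr_true_folds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["cis_pairs"] = {(a, b, int(d)) for a, b, d in payload["cis_pairs"]}
        return cls(**payload)


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_dna(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=n)].tobytes())


def _disrupt_and_plant(
    promoter: bytearray, k: int, rng: np.random.Generator, motif: str = SMAD3_MOTIF
) -> list[int]:
    """Force the sense-strand motif count of ``promoter`` to exactly ``k``.

    Background occurrences are broken by a single-base substitution; planted
    copies are written at offsets spaced >= 16 nt so no two planted intervals
    can cover a spurious overlapping occurrence.
    """
    m = len(motif)
    slots = np.arange(0, (len(promoter) - m) // 16) * 16
    if k > len(slots):
        raise ValueError(f"cannot plant {k} motif copies in {len(promoter)} nt")
    planted = sorted(int(p) for p in rng.choice(slots, size=k, replace=False))
    motif_b = motif.encode()
    for p in planted:
        promoter[p : p + m] = motif_b
    covered = set()
    for p in planted:
        covered.update(range(p, p + m))
    for _ in range(1000):
        seq = promoter.decode()
        positions, _ = scan_motif(seq, motif)
        stray = [p for p in positions if p not in planted]
        if not stray and len(positions) == k:
            return planted
        for occ in stray:
            mutable = [i for i in range(occ, occ + m) if i not in covered]
            pos = mutable[len(mutable) // 2]
            promoter[pos] = ord(_MUTATE[chr(promoter[pos])])
    raise RuntimeError("motif planting did not converge")


def _scrub_long_orfs(transcript: bytearray, max_orf: int = 300) -> None:
    """Mutate ATG starts until no forward-frame ORF exceeds ``max_orf`` nt."""
    while True:
        length, start = _longest_orf(transcript.decode())
        if length <= max_orf:
            return
        transcript[start] = ord("C")


def _plant_orf(transcript: bytearray, rng: np.random.Generator) -> None:
    codons = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), size=ORF_PLANT_CODONS)
    )
    orf = ("ATG" + codons + "TAA").encode()
    transcript[ORF_PLANT_OFFSET : ORF_PLANT_OFFSET + len(orf)] = orf


def _embed_transcript(
    contig: bytearray, gene_start: int, strand: str, transcript_seq: bytes
) -> list[tuple[int, int]]:
    """Write a 1200 nt transcript into the 2000 nt gene body; return genomic exons."""
    t1, t2 = transcript_seq[:400], transcript_seq[400:]
    if strand == "+":
        contig[gene_start : gene_start + 400] = t1
        contig[gene_start + 1200 : gene_start + 2000] = t2
        return [(gene_start, gene_start + 400), (gene_start + 1200, gene_start + 2000)]
    contig[gene_start : gene_start + 800] = revcomp(t2.decode()).encode()
    contig[gene_start + 1600 : gene_start + 2000] = revcomp(t1.decode()).encode()
    return [(gene_start, gene_start + 800), (gene_start + 1600, gene_start + 2000)]


# ---------------------------------------------------------------------------
# main generator


def generate_genome_and_annotation(
    config: SyntheticConfig,
) -> tuple[list[GenomeSequence], list[GeneModel], GroundTruth]:
    rng = _rng(config.seed, "genome")
    lfc = config.true_log2fc

    motif_counts = config.motif_counts()
    cis_layout = config.cis_layout()
    urine_up, urine_down = config.urine_de()

    lnc_ids = [lnc_id(i) for i in range(config.n_lnc_genes)]
    pcg_ids = [pcg_id(i) for i in range(config.n_coding_genes)]
    unknown = set(motif_counts) - set(lnc_ids)
    if unknown:
        raise ValueError(f"planted_motif_counts names unknown lncRNA genes: {sorted(unknown)}")
    unknown = set(cis_layout) - set(lnc_ids)
    if unknown:
        raise ValueError(f"neighbor_layout names unknown lncRNA genes: {sorted(unknown)}")
    if any(g < 1 or g > 100_000 for g in cis_layout.values()):
        raise ValueError("cis gaps must be in [1, 100000] nt")

    # strands drawn up front, in a fixed order
    lnc_strand = {gid: ("+", "-")[int(rng.integers(0, 2))] for gid in lnc_ids}
    pcg_strand = {gid: ("+", "-")[int(rng.integers(0, 2))] for gid in pcg_ids}

    # ---- layout: chr1 holds lncRNA blocks (+ cis partners); the remaining
    # coding genes are packed on the other contigs (or appended to chr1).
    partner_of: dict[str, str] = {}
    partner_iter = iter(pcg_ids)
    for gid in sorted(cis_layout):
        partner_of[gid] = next(partner_iter)
    background_pcg = [g for g in pcg_ids if g not in set(partner_of.values())]

    placements: dict[str, tuple[str, int]] = {}  # gene id -> (contig, gene_start)
    cursor = 1000
    chr1 = "chr1"
    cis_truth: set[tuple[str, str, int]] = set()
    for gid in lnc_ids:
        strand = lnc_strand[gid]
        gap = cis_layout.get(gid)
        if strand == "+":
            gene_start = cursor + PROMOTER_LEN
            block_end = gene_start + GENE_BODY
            if gap is not None:
                partner_start = block_end + gap
                placements[partner_of[gid]] = (chr1, partner_start)
                block_end = partner_start + GENE_BODY
        else:
            gene_start = cursor
            if gap is not None:
                gene_start = cursor + GENE_BODY + gap
                placements[partner_of[gid]] = (chr1, cursor)
            block_end = gene_start + GENE_BODY + PROMOTER_LEN
        placements[gid] = (chr1, gene_start)
        if gap is not None:
            cis_truth.add((gid, partner_of[gid], gap))
        cursor = block_end + BLOCK_SPACING
    chr1_len = cursor + 1000

    contig_names = [f"chr{i + 1}" for i in range(config.n_contigs)]
    bg_contigs = contig_names[1:] if config.n_contigs > 1 else [chr1]
    contig_cursor = {name: 1000 for name in contig_names[1:]}
    if config.n_contigs == 1:
        contig_cursor[chr1] = chr1_len + BLOCK_SPACING
    per_contig = -(-len(background_pcg) // len(bg_contigs))  # ceil split
    for i, gid in enumerate(background_pcg):
        name = bg_contigs[min(i // per_contig, len(bg_contigs) - 1)]
        placements[gid] = (name, contig_cursor[name])
        contig_cursor[name] += BG_SPACING

    contig_len: dict[str, int] = {}
    for name in contig_names:
        need = contig_cursor.get(name, 0) + 1000
        if name == chr1 and config.n_contigs > 1:
            need = chr1_len
        elif name == chr1:
            need = max(need, chr1_len)
        if config.contig_length is not None:
            if config.contig_length < need:
                raise ValueError(
                    f"contig_length {config.contig_length} too small for layout on {name} "
                    f"(needs {need}); increase contig_length"
                )
            need = config.contig_length
        contig_len[name] = need

    # ---- background sequence, then gene bodies, then promoters
    contigs = {name: _random_dna(rng, contig_len[name]) for name in contig_names}

    genes: list[GeneModel] = []
    for gid in lnc_ids + pcg_ids:
        contig_name, gene_start = placements[gid]
        is_coding = gid.startswith("PCG")
        strand = pcg_strand[gid] if is_coding else lnc_strand[gid]
        t_seq = _random_dna(rng, TRANSCRIPT_LEN)
        if is_coding:
            _plant_orf(t_seq, rng)
        else:
            _scrub_long_orfs(t_seq)
        exons = _embed_transcript(contigs[contig_name], gene_start, strand, bytes(t_seq))
        biotype = "protein_coding" if is_coding else "other"
        transcript = TranscriptModel(
            transcript_id=transcript_of(gid),
            gene_id=gid,
            contig=contig_name,
            strand=strand,
            exons=exons,
            biotype=biotype,
        )
        genes.append(GeneModel(gene_id=gid, contig=contig_name, strand=strand, transcripts=[transcript]))

    for gene in genes:
        if gene.gene_id.startswith("PCG"):
            continue
        k = motif_counts.get(gene.gene_id, 0)
        promoter = _random_dna(rng, PROMOTER_LEN)
        _disrupt_and_plant(promoter, k, rng)
        contig = contigs[gene.contig]
        start, end = gene.span
        if gene.strand == "+":
            contig[start - PROMOTER_LEN : start] = promoter
        else:
            contig[end : end + PROMOTER_LEN] = revcomp(promoter.decode()).encode()

    # exact-gap sanity check on the realized layout
    by_id = {g.gene_id: g for g in genes}
    for gid, partner, gap in cis_truth:
        ls, le = by_id[gid].span
        ps, pe = by_id[partner].span
        measured = max(0, max(ls, ps) - min(le, pe))
        if measured != gap:
            raise RuntimeError(f"cis layout broken for {gid}/{partner}: {measured} != {gap}")

    genome = [GenomeSequence(name, contigs[name].decode()) for name in contig_names]
    genes.sort(key=lambda g: (g.contig, g.span[0]))

    truth = GroundTruth(
        de_lnc_up={gid: lfc for gid in config.up_lnc_ids},
        de_lnc_down={gid: -lfc for gid in config.down_lnc_ids},
        de_mrna={
            gid: (lfc if i < -(-config.n_de_mrna // 2) else -lfc)
            for i, gid in enumerate(pcg_ids[: config.n_de_mrna])
        },
        urine_de_lnc_up=urine_up,
        urine_de_lnc_down=urine_down,
        urine_de_mrna={gid: (lfc if i < -(-config.n_de_mrna // 2) else -lfc)
                       for i, gid in enumerate(pcg_ids[: config.n_de_mrna])},
        motif_counts=motif_counts,
        cis_pairs=cis_truth,
        qpcr_true_folds=_default_qpcr_folds(config),
    )
    return genome, genes, truth


def _default_qpcr_folds(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    folds: dict[str, dict[str, float]] = {"tissue": {}, "urine": {}}
    if config.up_lnc_ids:
        folds["tissue"][config.up_lnc_ids[0]] = 4.0
        folds["urine"][config.up_lnc_ids[0]] = 4.0
    if len(config.up_lnc_ids) > 1:
        folds["urine"][config.up_lnc_ids[1]] = 2.5
    if config.down_lnc_ids:
        folds["tissue"][config.down_lnc_ids[0]] = 0.25
    if len(config.down_lnc_ids) > 1:
        folds["urine"][config.down_lnc_ids[1]] = 0.25
    return folds


# ---------------------------------------------------------------------------
# count and qPCR simulation


def simulate_counts(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SyntheticConfig,
    compartment: str,
) -> ExpressionMatrix:
    """Negative-binomial counts for one compartment (UUO vs Sham).

    mean = baseline for Sham; baseline * 2^lfc for planted DE genes in UUO;
    variance = mu + dispersion * mu^2.
    """
    if compartment not in ("tissue", "urine"):
        raise ValueError(f"unknown compartment {compartment!r}")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = _rng(config.seed, f"counts_{compartment}")
    lfc_of = truth.tissue_lfc if compartment == "tissue" else truth.urine_lfc

    reps = config.replicates_per_group
    sample_ids = [f"Sham_{compartment}_{r + 1}" for r in range(reps)] + [
        f"UUO_{compartment}_{r + 1}" for r in range(reps)
    ]
    conditions = ["Sham"] * reps + ["UUO"] * reps

    mu = np.empty((len(genes), 2 * reps))
    for i, gene in enumerate(genes):
        base = config.baseline_mean
        uuo_mean = base * 2.0 ** lfc_of(gene.gene_id)
        mu[i, :reps] = base
        mu[i, reps:] = uuo_mean

    alpha = config.nb_dispersion
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    counts_df = pd.DataFrame(
        counts,
        index=[transcript_of(g.gene_id) for g in genes],
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "compartment": compartment,
            "replicate": [r + 1 for r in range(reps)] * 2,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(counts=counts_df, samples=samples)


def stub_genes(n: int, contig: str = "chrS", length: int = 1200, prefix: str = "G") -> list[GeneModel]:
    """Minimal single-exon gene models (no sequence) for count-only simulations."""
    genes = []
    for i in range(n):
        start = i * (length + 100)
        gid = f"{prefix}{i + 1:05d}"
        t = TranscriptModel(
            transcript_id=transcript_of(gid),
            gene_id=gid,
            contig=contig,
            strand="+",
            exons=[(start, start + length)],
        )
        genes.append(GeneModel(gene_id=gid, contig=contig, strand="+", transcripts=[t]))
    return genes


def empty_truth() -> GroundTruth:
    """Truth with nothing planted (global-null count simulations)."""
    return GroundTruth(
        de_lnc_up={}, de_lnc_down={}, de_mrna={},
        urine_de_lnc_up={}, urine_de_lnc_down={}, urine_de_mrna={},
        motif_counts={}, cis_pairs=set(),
    )


QPCR_REFERENCES = {"tissue": ["GAPDH", "18S"], "urine": ["cel-miR-39"]}


def simulate_qpcr(
    truth: GroundTruth,
    config: SyntheticConfig,
    table: str = "tissue",
) -> pd.DataFrame:
    """Long-format Ct table (sample_id, group, gene, ct) for one compartment.

    Ct = base_ct - log2(relative abundance) + N(0, qpcr_noise_sd); reference
    genes (and the urine spike-in) have constant abundance across groups.
    """
    if table not in QPCR_REFERENCES:
        raise ValueError(f"unknown qPCR table {table!r}")
    folds = truth.qpcr_true_folds.get(table, {})
    if any(f <= 0 for f in folds.values()):
        raise ValueError("qPCR true fold must be > 0")
    rng = _rng(config.seed, f"qpcr_{table}")
    lo, hi = config.qpcr_base_ct_range
    genes = list(folds) + QPCR_REFERENCES[table]
    base_ct = {g: float(rng.uniform(lo, hi)) for g in genes}
    reps = config.replicates_per_group

    rows = []
    for gene in genes:
        fold = folds.get(gene, 1.0)
        for group, abundance in (("Sham", 1.0), ("UUO", fold)):
            for r in range(reps):
                noise = float(rng.normal(0.0, config.qpcr_noise_sd)) if config.qpcr_noise_sd else 0.0
                rows.append(
                    {
                        "sample_id": f"{group}_{r + 1}",
                        "group": group,
                        "gene": gene,
                        "ct": base_ct[gene] - float(np.log2(abundance)) + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file emission


def emit_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic dataset; returns the path of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome_and_annotation(config)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "tissue_counts": outdir / "counts_tissue.tsv",
        "tissue_samples": outdir / "samples_tissue.tsv",
        "urine_counts": outdir / "counts_urine.tsv",
        "urine_samples": outdir / "samples_urine.tsv",
        "qpcr_tissue": outdir / "qpcr_tissue.tsv",
        "qpcr_urine": outdir / "qpcr_urine.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_gtf(genes, paths["annotation"])
    for compartment in ("tissue", "urine"):
        matrix = simulate_counts(genes, truth, config, compartment)
        write_counts(matrix, paths[f"{compartment}_counts"], paths[f"{compartment}_samples"])
        simulate_qpcr(truth, config, compartment).to_csv(
            paths[f"qpcr_{compartment}"], sep="\t", index=False
        )
    truth.to_json(paths["truth"])
    return paths
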