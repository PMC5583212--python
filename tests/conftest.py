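import pytest

from lncfibro.models import GeneModel, TranscriptModel
from lncfibro.pipeline import PipelineConfig, run_pipeline
from lncfibro.synthetic_data import GroundTruth, SyntheticConfig, emit_dataset


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    contig: str = "chrT",
    biotype: str = "other",
) -> GeneModel:
    """Single-exon gene spanning [start, end) — enough for span/TSS logic."""
    t = TranscriptModel(
        transcript_id=gene_id + ".1",
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        exons=[(start, end)],
        biotype=biotype,
    )
    return GeneModel(gene_id=gene_id, contig=contig, strand=strand, transcripts=[t])


def small_config(**overrides) -> SyntheticConfig:
    """A compact study design: 12 lncRNAs (4 up, 4 down), 30 coding genes."""
    fields = dict(
        seed=7,
        n_coding_genes=30,
        n_lnc_genes=12,
        n_de_lnc_up=4,
        n_de_lnc_down=4,
        n_de_mrna=4,
        n_cis_pairs=6,
    )
    fields.update(overrides)
    return SyntheticConfig(**fields)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Emitted files + truth for the compact design."""
    outdir = tmp_path_factory.mktemp("small_data")
    config = small_config()
    paths = emit_dataset(config, outdir)
    truth = GroundTruth.from_json(paths["truth"])
    return config, paths, truth


def pipeline_config_for(paths, out_dir) -> PipelineConfig:
    return PipelineConfig(
        genome=str(paths["genome"]),
        annotation=str(paths["annotation"]),
        tissue_counts=str(paths["tissue_counts"]),
        tissue_samples=str(paths["tissue_samples"]),
        urine_counts=str(paths["urine_counts"]),
        urine_samples=str(paths["urine_samples"]),
        qpcr_tissue=str(paths["qpcr_tissue"]),
        qpcr_urine=str(paths["qpcr_urine"]),
        out_dir=str(out_dir),
    )


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """Full pipeline executed once on the compact dataset."""
    config, paths, truth = small_dataset
    out = tmp_path_factory.mktemp("small_out")
    report = run_pipeline(pipeline_config_for(paths, out))
    return config, paths, truth, report, out


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The reference study conditions (seed 1): 40 DE lncRNAs at |log2FC| = 2,
    baseline mean 200, NB dispersion 0.05, 6 promoters with 5..10 motifs,
    25 cis pairs."""
    outdir = tmp_path_factory.mktemp("default_data")
    config = SyntheticConfig(seed=1)
    paths = emit_dataset(config, outdir)
    truth = GroundTruth.from_json(paths["truth"])
    return config, paths, truth


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    config, paths, truth = default_dataset
    out = tmp_path_factory.mktemp("default_out")
    report = run_pipeline(pipeline_config_for(paths, out))
    return config, paths, truth, report, out
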