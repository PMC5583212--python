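"""RPKM-based differential expression, UUO vs Sham, per compartment.

Cutoffs: |log2FC| >= 1 and Welch p < 0.05 on log2(RPKM + 0.25). Writes
results/de_tissue.tsv and results/de_urine.tsv and prints the up/down counts
split by candidate lncRNAs vs protein-coding genes.
"""

import argparse
from pathlib import Path

from lncfibro.expression_de import call_de, de_summary
from lncfibro.io_formats import read_counts, read_gtf
from lncfibro.models import de_records_to_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    genes = read_gtf(args.data / "annotation.gtf")
    lengths = {t.transcript_id: t.exonic_length for g in genes for t in g.transcripts}
    coding = {
        t.transcript_id for g in genes for t in g.transcripts
        if g.biotype == "protein_coding"
    }
    candidates = set((args.out / "lnc_candidates.tsv").read_text().split()[1:])

    args.out.mkdir(parents=True, exist_ok=True)
    for compartment in ("tissue", "urine"):
        matrix = read_counts(
            args.data / f"counts_{compartment}.tsv",
            args.data / f"samples_{compartment}.tsv",
            annotation_ids=set(lengths),
        )
        records = call_de(matrix, lengths)
        de_records_to_frame(records).to_csv(
            args.out / f"de_{compartment}.tsv", sep="\t", index=False
        )
        lnc = de_summary([r for r in records if r.transcript_id in candidates])
        mrna = de_summary([r for r in records if r.transcript_id in coding])
        print(f"{compartment}: lncRNA {lnc['n_up']} up / {lnc['n_down']} down; "
              f"mRNA {mrna['n_up']} up / {mrna['n_down']} down "
              f"(of {len(records)} transcripts)")


if __name__ == "__main__":
    main()
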