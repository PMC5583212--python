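"""Urinary biomarker candidates and qPCR validation math.

Intersects the tissue and urine DE lncRNA sets requiring the same direction
of change, then quantifies the simulated qPCR tables with 2^-ddCt (GAPDH
reference in tissue, cel-miR-39 spike-in in urine).

Writes results/concordant_biomarkers.tsv and results/qpcr_*_summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lncfibro.biomarker_qpcr import (
    concordance_summary,
    concordant_biomarkers,
    delta_delta_ct,
    spike_in_normalize,
)
from lncfibro.models import DERecord


def load_de(path: Path) -> list[DERecord]:
    return [DERecord(**row) for row in pd.read_csv(path, sep="\t").to_dict("records")]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    candidates = set((args.out / "lnc_candidates.tsv").read_text().split()[1:])
    tissue = [r for r in load_de(args.out / "de_tissue.tsv") if r.transcript_id in candidates]
    urine = [r for r in load_de(args.out / "de_urine.tsv") if r.transcript_id in candidates]
    records = concordant_biomarkers(tissue, urine)
    with open(args.out / "concordant_biomarkers.tsv", "w") as fh:
        fh.write("transcript_id\ttissue_direction\turine_direction\tconcordant\n")
        for r in records:
            fh.write(f"{r.transcript_id}\t{r.tissue_direction}\t{r.urine_direction}\t{r.concordant}\n")
    summary = concordance_summary(records)
    print(f"{summary['n_overlapping']} lncRNAs dysregulated in both compartments; "
          f"{summary['n_concordant_up']} concordant up, "
          f"{summary['n_concordant_down']} concordant down")

    for table_name, normalize in (("tissue", None), ("urine", "cel-miR-39")):
        table = pd.read_csv(args.data / f"qpcr_{table_name}.tsv", sep="\t")
        if normalize:
            _, qsum = spike_in_normalize(table, spike_id=normalize)
        else:
            _, qsum = delta_delta_ct(table, reference_gene="GAPDH")
        qsum.to_csv(args.out / f"qpcr_{table_name}_summary.tsv", sep="\t", index=False)
        uuo = qsum[qsum["group"] == "UUO"]
        print(f"qPCR ({table_name}):")
        for _, row in uuo.iterrows():
            print(f"  {row['target']}: fold = {row['mean_fold']:.2f} "
                  f"+/- {row['sd_fold']:.2f}, p = {row['p_value']:.2g}")


if __name__ == "__main__":
    main()
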