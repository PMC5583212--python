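"""Protein-coding genes within +/-100 kb of each dysregulated lncRNA locus.

Reads the tissue DE table and candidate list from results/, writes
results/cis_pairs.tsv with span-gap distances and strand-aware relations.
"""

import argparse
from pathlib import Path

import pandas as pd

from lncfibro.cis_neighbors import find_cis_neighbors
from lncfibro.io_formats import read_gtf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--window", type=int, default=100_000)
    args = parser.parse_args()

    genes = read_gtf(args.data / "annotation.gtf")
    by_id = {g.gene_id: g for g in genes}
    candidates = set((args.out / "lnc_candidates.tsv").read_text().split()[1:])
    de = pd.read_csv(args.out / "de_tissue.tsv", sep="\t")
    dysregulated = sorted({
        r.transcript_id[:-2] for r in de.itertuples()
        if r.significant and r.transcript_id in candidates
    })

    pairs = find_cis_neighbors(
        [by_id[g] for g in dysregulated],
        [g for g in genes if g.biotype == "protein_coding"],
        window=args.window,
    )
    with open(args.out / "cis_pairs.tsv", "w") as fh:
        fh.write("lnc_gene_id\tcoding_gene_id\tdistance\trelation\n")
        for p in pairs:
            fh.write(f"{p.lnc_gene_id}\t{p.coding_gene_id}\t{p.distance}\t{p.relation}\n")

    print(f"{len(dysregulated)} dysregulated lncRNA genes searched "
          f"(+/-{args.window // 1000} kb): {len(pairs)} coding neighbors")
    if pairs:
        nearest = min(pairs, key=lambda p: p.distance)
        print(f"  nearest: {nearest.coding_gene_id} at {nearest.distance} nt "
              f"({nearest.relation} of {nearest.lnc_gene_id})")


if __name__ == "__main__":
    main()
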