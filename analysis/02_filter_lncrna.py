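"""Classify transcripts as candidate lncRNAs: >200 nt spliced length and no
coding-potential call from any predictor (union-removal consensus).

Reads results/data/, writes results/lnc_candidates.tsv and
results/filter_removed.tsv.
"""

import argparse
from pathlib import Path

from lncfibro.io_formats import read_fasta, read_gtf, spliced_sequence
from lncfibro.lncrna_filter import OrfLengthPredictor, consensus_lnc_filter, make_calls
from lncfibro.models import genome_as_dict


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    genome = genome_as_dict(read_fasta(args.data / "genome.fa"))
    genes = read_gtf(args.data / "annotation.gtf")
    transcripts = [t for g in genes for t in g.transcripts]
    sequences = {t.transcript_id: spliced_sequence(t, genome) for t in transcripts}
    calls = make_calls(sequences, [OrfLengthPredictor()])
    result = consensus_lnc_filter(transcripts, calls)

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "lnc_candidates.tsv").write_text(
        "transcript_id\n" + "".join(t + "\n" for t in sorted(result.candidate_ids))
    )
    (args.out / "filter_removed.tsv").write_text(
        "transcript_id\treason\n"
        + "".join(f"{t}\t{r}\n" for t, r in sorted(result.removed.items()))
    )
    reasons = {}
    for r in result.removed.values():
        key = r.split(":")[0]
        reasons[key] = reasons.get(key, 0) + 1
    print(f"{len(transcripts)} transcripts in; {len(result.candidate_ids)} lncRNA candidates")
    for reason, n in sorted(reasons.items()):
        print(f"  removed {reason}: {n}")


if __name__ == "__main__":
    main()
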