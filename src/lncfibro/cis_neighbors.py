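"""Cis-neighbor search: protein-coding genes within +/-100 kb of lncRNA loci.

Distance is the gap between gene spans (0 when they overlap), the boundary is
inclusive (a gap of exactly 100,000 nt is reported), and upstream/downstream
is assigned relative to the lncRNA's strand. The production path uses an
interval tree; the O(n*m) brute force is kept as the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import GeneModel

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class CisPair:
    lnc_gene_id: str
    coding_gene_id: str
    distance: int
    relation: str  # overlap / upstream / downstream (relative to the lncRNA strand)


def _span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between half-open spans; 0 when they intersect or touch."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def _pair(lnc: GeneModel, coding: GeneModel, window: int) -> CisPair | None:
    if lnc.contig != coding.contig:
        return None
    ls, le = lnc.span
    cs, ce = coding.span
    distance = _span_distance((ls, le), (cs, ce))
    if distance > window:
        return None
    strand = lnc.strand
    if strand not in ("+", "-"):
        warnings.warn(f"lncRNA {lnc.gene_id} unstranded; treating as '+'")
        strand = "+"
    if cs < le and ce > ls:
        relation = "overlap"
    else:
        coding_is_left = ce <= ls
        if strand == "+":
            relation = "upstream" if coding_is_left else "downstream"
        else:
            relation = "downstream" if coding_is_left else "upstream"
    return CisPair(lnc.gene_id, coding.gene_id, distance, relation)


def find_cis_neighbors(
    lnc_genes: list[GeneModel],
    coding_genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[CisPair]:
    """All (lncRNA, coding) pairs on the same contig with span gap <= window."""
    if window <= 0:
        raise ValueError("window must be positive")
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for g in coding_genes:
        s, e = g.span
        trees.setdefault(g.contig, IntervalTree()).addi(s, e, g.gene_id)
        by_id[g.gene_id] = g

    pairs: list[CisPair] = []
    for lnc in lnc_genes:
        tree = trees.get(lnc.contig)
        if tree is None:
            continue
        s, e = lnc.span
        # envelope is padded by one past the window; exact gap filtering below
        hits = tree.overlap(max(0, s - window - 1), e + window + 1)
        for hit in sorted(hits, key=lambda h: (h.begin, h.data)):
            pair = _pair(lnc, by_id[hit.data], window)
            if pair is not None:
                pairs.append(pair)
    return pairs


def find_cis_neighbors_bruteforce(
    lnc_genes: list[GeneModel],
    coding_genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[CisPair]:
    """All-pairs reference implementation (test oracle)."""
    pairs = []
    for lnc in lnc_genes:
        for coding in coding_genes:
            pair = _pair(lnc, coding, window)
            if pair is not None:
                pairs.append(pair)
    return pairs
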