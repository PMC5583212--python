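"""Candidate-lncRNA classification.

The external coding-potential tools (CPC, CNCI, Pfam Scan, PhyloCSF) are not
wrapped; this module defines a predictor interface (score + threshold ->
is_coding) with two built-ins — longest-ORF length and hexamer usage bias —
and applies the consensus union-removal rule: a transcript flagged coding by
ANY predictor is filtered out, as is anything not longer than 200 nt
(spliced). What survives is the candidate lncRNA set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .dna import STOP_CODONS
from .models import TranscriptModel

START_CODON = "ATG"


@dataclass
class CodingCall:
    transcript_id: str
    predictor_name: str
    score: float
    is_coding: bool


@dataclass
class LncCandidateSet:
    """Partition of the input transcripts into candidates and removed-with-reason."""

    candidate_ids: set[str]
    removed: dict[str, str] = field(default_factory=dict)


def _longest_orf(sequence: str) -> tuple[int, int]:
    """(length, start) of the longest ORF over the 3 forward frames.

    An ORF runs from an ATG to the first in-frame stop; the length includes
    the stop codon. Returns (0, -1) when no complete ORF exists.
    """
    seq = sequence.upper()
    best_len, best_start = 0, -1
    n = len(seq)
    for frame in range(3):
        open_start = -1  # earliest unclosed ATG in this frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if open_start < 0:
                if codon == START_CODON:
                    open_start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - open_start
                if length > best_len:
                    best_len, best_start = length, open_start
                open_start = -1
    return best_len, best_start


def longest_orf_length(sequence: str) -> int:
    """Length (nt, stop included) of the longest forward-frame ORF; 0 if none."""
    return _longest_orf(sequence)[0]


def hexamer_bias_score(
    sequence: str,
    coding_freq_table: dict[str, float],
    noncoding_freq_table: dict[str, float],
) -> float:
    """Mean log(coding/noncoding) frequency ratio over in-frame hexamers.

    Hexamers are read in frame 0 with step 3; sequences shorter than 6 nt
    score 0. Positive scores look coding-like.
    """
    seq = sequence.upper()
    if len(seq) < 6:
        return 0.0
    total, n = 0.0, 0
    for pos in range(0, len(seq) - 5, 3):
        hexamer = seq[pos : pos + 6]
        if set(hexamer) - set("ACGT"):
            continue  # ambiguity codes contribute nothing
        try:
            c = coding_freq_table[hexamer]
            nc = noncoding_freq_table[hexamer]
        except KeyError as exc:
            raise ValueError(f"frequency table missing hexamer {exc.args[0]}") from None
        total += math.log(c / nc)
        n += 1
    return total / n if n else 0.0


class OrfLengthPredictor:
    """Flags a transcript coding when its longest ORF exceeds a length threshold."""

    def __init__(self, threshold: int = 300, name: str = "orf_length"):
        self.threshold = threshold
        self.name = name

    def __call__(self, transcript_id: str, sequence: str) -> CodingCall:
        score = float(longest_orf_length(sequence))
        return CodingCall(transcript_id, self.name, score, score > self.threshold)


class HexamerBiasPredictor:
    """Flags coding when in-frame hexamer usage leans toward the coding table."""

    def __init__(
        self,
        coding_freq_table: dict[str, float],
        noncoding_freq_table: dict[str, float],
        threshold: float = 0.0,
        name: str = "hexamer_bias",
    ):
        self.coding = coding_freq_table
        self.noncoding = noncoding_freq_table
        self.threshold = threshold
        self.name = name

    def __call__(self, transcript_id: str, sequence: str) -> CodingCall:
        score = hexamer_bias_score(sequence, self.coding, self.noncoding)
        return CodingCall(transcript_id, self.name, score, score > self.threshold)


def make_calls(sequences: dict[str, str], predictors: list) -> list[CodingCall]:
    """Run every predictor over every transcript sequence."""
    return [pred(tid, seq) for tid, seq in sequences.items() for pred in predictors]


def consensus_lnc_filter(
    transcripts: list[TranscriptModel],
    calls: list[CodingCall],
    min_length: int = 200,
) -> LncCandidateSet:
    """Union-removal consensus: drop a transcript flagged coding by ANY predictor.

    A transcript is removed when its spliced length is <= ``min_length``
    ("more than 200 nt" read strictly; checked first, reason ``too_short``)
    or when at least one predictor calls it coding (reason lists every
    flagging predictor). Every transcript must carry >= 1 predictor call.
    """
    by_transcript: dict[str, list[CodingCall]] = {}
    for call in calls:
        by_transcript.setdefault(call.transcript_id, []).append(call)

    candidates: set[str] = set()
    removed: dict[str, str] = {}
    for t in transcripts:
        t_calls = by_transcript.get(t.transcript_id)
        if not t_calls:
            raise ValueError(f"transcript {t.transcript_id} has no predictor calls")
        if t.exonic_length <= min_length:
            removed[t.transcript_id] = "too_short"
            continue
        flagging = sorted(c.predictor_name for c in t_calls if c.is_coding)
        if flagging:
            removed[t.transcript_id] = "coding_by:" + ",".join(flagging)
        else:
            candidates.add(t.transcript_id)
    return LncCandidateSet(candidate_ids=candidates, removed=removed)
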