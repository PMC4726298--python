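"""Coding-potential screen and lncRNA gating.

The screen is a deliberately simple two-feature linear score over the longest
open reading frame (ORF): normalised ORF length and ORF coverage of the
transcript.  It is a documented desk-scale classifier for separating
ORF-bearing coding-like transcripts from noncoding-like candidates; an
external scorer's TSV output can be plugged in instead via
``load_external_scores``.  The retained set additionally obeys the
conventional lncRNA length definition (> 200 nt).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class CodingParams:
    w_orf: float = 0.5
    w_coverage: float = 0.5
    orf_norm_nt: int = 300      # ORF length at which the length feature saturates
    min_orf_nt: int = 300       # coding-like requires >= 100 codons
    score_threshold: float = 0.5
    frames: int = 3             # 3 = annotated strand only, 6 = both strands

    def __post_init__(self) -> None:
        if self.frames not in (3, 6):
            raise ValueError("frames must be 3 or 6")


@dataclass
class CodingAssessment:
    transcript_id: str
    orf_length: int          # nt, includes the stop codon; always a multiple of 3
    orf_coverage: float      # orf_length / transcript length
    score: float
    verdict: str             # "coding-like" | "noncoding-like"


def _scan_frame(seq: str, frame_offset: int) -> tuple[int, int]:
    """Longest ATG..stop ORF in one frame; returns (length_nt, start_offset).

    A codon containing N is never a start or a stop.  Returns (0, -1) when no
    complete ORF exists in the frame.
    """
    best_len, best_start = 0, -1
    orf_start = -1
    for pos in range(frame_offset, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if orf_start < 0:
            if codon == START_CODON:
                orf_start = pos
        elif codon in STOP_CODONS:
            length = pos + 3 - orf_start
            if length > best_len:
                best_len, best_start = length, orf_start
            orf_start = -1
    return best_len, best_start


def find_longest_orf(sequence: str, frames: int = 3) -> tuple[int, int, int]:
    """Longest ATG-initiated, stop-terminated ORF across reading frames.

    Returns (length_nt, start_offset, frame).  Frames 0-2 scan the given
    sequence; frames 3-5 (``frames=6``) scan its reverse complement, with the
    offset reported on that scanned strand.  Ties break by smallest start
    offset, then lowest frame index.  Length includes the stop codon.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    strands = [sequence]
    if frames == 6:
        strands.append(str(Seq(sequence).reverse_complement()))
    elif frames != 3:
        raise ValueError("frames must be 3 or 6")

    best = (0, -1, -1)  # (length, offset, frame)
    for strand_idx, seq in enumerate(strands):
        for f in range(3):
            frame_idx = strand_idx * 3 + f
            length, start = _scan_frame(seq, f)
            if length == 0:
                continue
            candidate = (length, start, frame_idx)
            # longer wins; then smaller offset; then lower frame
            if (candidate[0], -candidate[1], -candidate[2]) > (best[0], -best[1], -best[2]):
                best = candidate
    return best


def coding_score(transcript_id: str, sequence: str,
                 params: CodingParams | None = None) -> CodingAssessment:
    """Score one transcript: score = w1*min(ORF/300, 1) + w2*coverage;
    coding-like iff score > threshold AND ORF >= 300 nt."""
    params = params or CodingParams()
    orf_length, _, _ = find_longest_orf(sequence, frames=params.frames)
    coverage = orf_length / len(sequence)
    score = (
        params.w_orf * min(orf_length / params.orf_norm_nt, 1.0)
        + params.w_coverage * coverage
    )
    coding_like = score > params.score_threshold and orf_length >= params.min_orf_nt
    return CodingAssessment(
        transcript_id=transcript_id,
        orf_length=orf_length,
        orf_coverage=coverage,
        score=score,
        verdict="coding-like" if coding_like else "noncoding-like",
    )


def assess_sequences(sequences: dict[str, str],
                     params: CodingParams | None = None) -> dict[str, CodingAssessment]:
    return {tid: coding_score(tid, seq, params) for tid, seq in sequences.items()}


def load_external_scores(path) -> dict[str, CodingAssessment]:
    """Bypass hook: ingest an external coding-potential scorer's TSV
    (columns transcript_id, orf_length, orf_coverage, score, verdict)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    out = {}
    for row in frame.itertuples():
        verdict = str(row.verdict)
        if verdict not in ("coding-like", "noncoding-like"):
            raise ValueError(f"unknown verdict {verdict!r} for {row.transcript_id}")
        out[str(row.transcript_id)] = CodingAssessment(
            str(row.transcript_id), int(row.orf_length),
            float(row.orf_coverage), float(row.score), verdict,
        )
    return out


def apply_lncrna_gates(candidates, assessments: dict[str, CodingAssessment] | None,
                       min_length_nt: int = 200) -> list[str]:
    """Retain candidate ids with length strictly > min_length_nt whose coding
    verdict is noncoding-like.  In sequence-less mode (assessments None) the
    coding gate is skipped and only the length convention applies."""
    retained = []
    for t in candidates:
        if t.length <= min_length_nt:
            continue
        if assessments is not None:
            a = assessments.get(t.id)
            if a is None or a.verdict != "noncoding-like":
                continue
        retained.append(t.id)
    return retained
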