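"""Intergenic novelty filter.

A candidate transcript is novel iff it (1) overlaps no annotated gene or UTR
extension and (2) is not a near-duplicate of a previously reported noncoding
transcript, where "near-duplicate" means both end coordinates lie within the
end-divergence threshold (default 50 bp) of the known transcript's ends.

Overlap is strand-blind by default: antisense transcripts overlapping coding
genes are excluded from the intergenic analysis either way, so a gene overlap
on the opposite strand still rejects.  A strand-aware mode is available.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import AnnotationSet, GenomicInterval, TranscriptModel


class Verdict(str, enum.Enum):
    NOVEL = "novel"
    GENE_OVERLAP = "rejected_gene_overlap"
    UTR_OVERLAP = "rejected_utr_overlap"
    KNOWN_NCRNA_MATCH = "rejected_known_ncRNA_match"


@dataclass(frozen=True)
class NoveltyParams:
    """end_divergence_threshold: max bp offset at which an end still "matches"
    a known ncRNA end.  end_rule: "both" requires both ends within threshold
    for a match (the default reading); "either" lets a single close end match.
    """

    end_divergence_threshold: int = 50
    min_overlap: int = 1
    strand_aware: bool = False
    end_rule: str = "both"

    def __post_init__(self) -> None:
        if self.end_divergence_threshold < 0:
            raise ValueError("end_divergence_threshold must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.end_rule not in ("both", "either"):
            raise ValueError("end_rule must be 'both' or 'either'")


@dataclass
class NoveltyDecision:
    transcript_id: str
    verdict: Verdict
    matched_id: str | None = None
    d5: float | None = None
    d3: float | None = None

    def __post_init__(self) -> None:
        if self.verdict is Verdict.NOVEL and self.matched_id is not None:
            raise ValueError("novel decisions carry no matched id")
        if self.verdict is not Verdict.NOVEL and self.matched_id is None:
            raise ValueError("rejected decisions must carry a matched id")


def overlaps(a: GenomicInterval, b: GenomicInterval, params: NoveltyParams | None = None) -> int:
    """Shared base-pair count between two intervals (0 across chroms, 0 for
    half-open abutment, 0 for incompatible strands in strand-aware mode)."""
    params = params or NoveltyParams()
    return a.overlap_length(b, strand_aware=params.strand_aware)


def end_divergence(candidate: TranscriptModel, known: TranscriptModel) -> tuple[float, float]:
    """Absolute end offsets (start-vs-start, end-vs-end) in bp; infinite when
    the transcripts sit on different chromosomes (no match possible)."""
    if candidate.chrom != known.chrom:
        return (math.inf, math.inf)
    d5 = abs(candidate.interval.start - known.interval.start)
    d3 = abs(candidate.interval.end - known.interval.end)
    return (float(d5), float(d3))


class AnnotationIndex:
    """Interval-tree index over gene bodies and UTR extensions.

    query() returns (kind, feature) pairs for every indexed feature
    overlapping the query by >= 1 bp; equivalent to a brute-force scan.
    """

    def __init__(self, annotation: AnnotationSet):
        self.annotation = annotation
        self._trees: dict[str, IntervalTree] = {}
        for gene in annotation.genes:
            body = gene.interval
            self._add(body, ("gene", gene, body))
            extended = annotation.gene_with_utrs(gene)
            # UTR extensions indexed as separate segments flanking the body.
            if extended.start < body.start:
                utr = GenomicInterval(body.chrom, extended.start, body.start, body.strand)
                self._add(utr, ("utr", gene, utr))
            if extended.end > body.end:
                utr = GenomicInterval(body.chrom, body.end, extended.end, body.strand)
                self._add(utr, ("utr", gene, utr))

    def _add(self, interval: GenomicInterval, payload) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, payload)

    def query(self, interval: GenomicInterval, *, strand_aware: bool = False):
        """All (kind, gene, feature_interval) overlapping >= 1 bp."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(interval.start, interval.end):
            kind, gene, feat = iv.data
            if strand_aware and not interval.strands_compatible(feat):
                continue
            hits.append((kind, gene, feat))
        hits.sort(key=lambda h: (h[0], h[1].id, h[2].start))
        return hits


def build_interval_index(annotation: AnnotationSet) -> AnnotationIndex:
    return AnnotationIndex(annotation)


def _match_known(candidate: TranscriptModel, known: TranscriptModel,
                 params: NoveltyParams) -> bool:
    d5, d3 = end_divergence(candidate, known)
    if params.end_rule == "both":
        return d5 <= params.end_divergence_threshold and d3 <= params.end_divergence_threshold
    return d5 <= params.end_divergence_threshold or d3 <= params.end_divergence_threshold


def classify_novelty(transcripts: list[TranscriptModel], annotation: AnnotationSet,
                     params: NoveltyParams | None = None,
                     index: AnnotationIndex | None = None) -> list[NoveltyDecision]:
    """Classify each transcript, in input order.

    Gene-body overlap is checked first, then UTR overlap, then end proximity
    to every known ncRNA on the same chromosome.  Containment inside a longer
    known ncRNA with distant ends does not reject (the ends govern).
    """
    params = params or NoveltyParams()
    index = index or build_interval_index(annotation)
    known_by_chrom: dict[str, list[TranscriptModel]] = {}
    for k in annotation.known_ncrnas:
        known_by_chrom.setdefault(k.chrom, []).append(k)

    decisions = []
    for t in transcripts:
        hits = index.query(t.interval, strand_aware=params.strand_aware)
        gene_hits = [
            (gene, feat) for kind, gene, feat in hits
            if kind == "gene" and t.interval.overlap_length(feat) >= params.min_overlap
        ]
        if gene_hits:
            gene_hits.sort(key=lambda h: (-t.interval.overlap_length(h[1]), h[0].id))
            decisions.append(
                NoveltyDecision(t.id, Verdict.GENE_OVERLAP, matched_id=gene_hits[0][0].id)
            )
            continue
        utr_hits = [
            (gene, feat) for kind, gene, feat in hits
            if kind == "utr" and t.interval.overlap_length(feat) >= params.min_overlap
        ]
        if utr_hits:
            utr_hits.sort(key=lambda h: (-t.interval.overlap_length(h[1]), h[0].id))
            decisions.append(
                NoveltyDecision(t.id, Verdict.UTR_OVERLAP, matched_id=utr_hits[0][0].id)
            )
            continue

        best = None  # (d5 + d3, id, known, d5, d3) among matching knowns
        for known in known_by_chrom.get(t.chrom, []):
            if params.strand_aware and not t.interval.strands_compatible(known.interval):
                continue
            if _match_known(t, known, params):
                d5, d3 = end_divergence(t, known)
                key = (d5 + d3, known.id)
                if best is None or key < best[0]:
                    best = (key, known, d5, d3)
        if best is not None:
            _, known, d5, d3 = best
            decisions.append(
                NoveltyDecision(t.id, Verdict.KNOWN_NCRNA_MATCH,
                                matched_id=known.id, d5=d5, d3=d3)
            )
        else:
            decisions.append(NoveltyDecision(t.id, Verdict.NOVEL))
    return decisions


def classify_novelty_bruteforce(transcripts: list[TranscriptModel],
                                annotation: AnnotationSet,
                                params: NoveltyParams | None = None) -> list[NoveltyDecision]:
    """O(n*m) reference classification without the interval index; used as an
    internal cross-check (must agree exactly with classify_novelty)."""
    params = params or NoveltyParams()

    class _ScanIndex(AnnotationIndex):
        def __init__(self, annotation):
            self.annotation = annotation

        def query(self, interval, *, strand_aware=False):
            hits = []
            for gene in self.annotation.genes:
                body = gene.interval
                if interval.overlap_length(body, strand_aware=strand_aware) >= 1:
                    hits.append(("gene", gene, body))
                extended = self.annotation.gene_with_utrs(gene)
                for seg in (
                    (extended.start, body.start),
                    (body.end, extended.end),
                ):
                    if seg[0] >= seg[1]:
                        continue
                    utr = GenomicInterval(body.chrom, seg[0], seg[1], body.strand)
                    if interval.overlap_length(utr, strand_aware=strand_aware) >= 1:
                        hits.append(("utr", gene, utr))
            hits.sort(key=lambda h: (h[0], h[1].id, h[2].start))
            return hits

    return classify_novelty(transcripts, annotation, params, index=_ScanIndex(annotation))
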