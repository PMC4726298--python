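"""Core in-memory containers for the lncRNA discovery pipeline.

All coordinates are 0-based half-open (BED-like) on named chromosomes.
Format readers shift at the boundary (GTF is 1-based inclusive), so overlap
arithmetic inside the package never carries +/-1 bookkeeping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

STRANDS = ("+", "-", ".")

#: Ordered senescence time-course stages, keyed 1..5.
TIME_POINT_LABELS = {
    1: "presenescence",
    2: "early senescence",
    3: "late senescence",
    4: "early survivor",
    5: "survivor",
}
TIME_POINTS = tuple(TIME_POINT_LABELS)
GENOTYPES = ("mut", "wt")
REPLICATES = ("A", "B")


class Source(str, enum.Enum):
    """Provenance of a transcript model."""

    ASSEMBLED = "assembled"
    ANNOTATED_GENE = "annotated_gene"
    KNOWN_NCRNA = "known_ncRNA"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded); unstranded records are
    treated as matching both strands in strand-aware overlap queries.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        """True unless both intervals are stranded and on opposite strands."""
        if self.strand == "." or other.strand == ".":
            return True
        return self.strand == other.strand

    def overlap_length(self, other: "GenomicInterval", *, strand_aware: bool = False) -> int:
        """Number of shared base positions (0 for abutting half-open intervals)."""
        if self.chrom != other.chrom:
            return 0
        if strand_aware and not self.strands_compatible(other):
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """A (possibly multi-exon) transcript: the unit of lncRNA discovery."""

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    source: Source = Source.ASSEMBLED

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.interval]
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"transcript {self.id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"transcript {self.id}: overlapping exons")
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(
                    f"transcript {self.id}: exon chrom/strand differs from transcript"
                )
        if self.exons[0].start != self.interval.start or self.exons[-1].end != self.interval.end:
            raise ValueError(f"transcript {self.id}: interval does not span exons")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        """Genomic span in bp (single-exon transcripts: also mature length)."""
        return self.interval.length


@dataclass
class AnnotationSet:
    """Reference annotation: coding genes (with optional UTR extents) and
    previously reported noncoding transcripts (SUTs/CUTs/XUTs...)."""

    genes: list[TranscriptModel] = field(default_factory=list)
    known_ncrnas: list[TranscriptModel] = field(default_factory=list)
    #: per-gene UTR extensions in bp beyond the annotated gene interval,
    #: keyed by gene id -> (upstream_bp, downstream_bp) in genomic orientation.
    utr_extents: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.genes] + [t.id for t in self.known_ncrnas]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids across genes and known ncRNAs")
        for gid, (u5, u3) in self.utr_extents.items():
            if u5 < 0 or u3 < 0:
                raise ValueError(f"negative UTR extent for gene {gid}")

    def gene_with_utrs(self, gene: TranscriptModel) -> GenomicInterval:
        """Gene interval extended by its UTR extents (genomic left/right)."""
        left, right = self.utr_extents.get(gene.id, (0, 0))
        return GenomicInterval(
            gene.chrom,
            max(0, gene.interval.start - left),
            gene.interval.end + right,
            gene.strand,
        )


class ExpressionMatrix:
    """FPKM values keyed by (transcript, time point, genotype, replicate).

    Backed by a long-format DataFrame with columns
    ``transcript_id, time_point, genotype, replicate, fpkm``.  Missing
    conditions stay absent (no silent zeros); FPKM must be >= 0.
    """

    COLUMNS = ("transcript_id", "time_point", "genotype", "replicate", "fpkm")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"expression table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["time_point"] = frame["time_point"].astype(int)
        frame["fpkm"] = frame["fpkm"].astype(float)
        bad_tp = set(frame["time_point"]) - set(TIME_POINTS)
        if bad_tp:
            raise ValueError(f"unknown time point labels: {sorted(bad_tp)}")
        bad_gt = set(frame["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotype labels: {sorted(bad_gt)}")
        if (frame["fpkm"] < 0).any():
            bad = frame.loc[frame["fpkm"] < 0].iloc[0]
            raise ValueError(
                f"negative FPKM {bad['fpkm']} for transcript {bad['transcript_id']}"
            )
        key = frame[["transcript_id", "time_point", "genotype", "replicate"]]
        if key.duplicated().any():
            dup = frame.loc[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate expression entry for "
                f"({dup['transcript_id']}, t{dup['time_point']}, "
                f"{dup['genotype']}, {dup['replicate']})"
            )
        self._frame = frame.sort_values(
            ["transcript_id", "time_point", "genotype", "replicate"]
        ).reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ExpressionMatrix":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def transcripts(self) -> list[str]:
        return sorted(self._frame["transcript_id"].unique())

    def values_for(self, transcript_id: str, time_point: int, genotype: str):
        """Replicate FPKM values for one condition (possibly empty)."""
        f = self._frame
        sel = f[
            (f["transcript_id"] == transcript_id)
            & (f["time_point"] == time_point)
            & (f["genotype"] == genotype)
        ]
        return sel.sort_values("replicate")["fpkm"].to_numpy()

    def replicate_means(self, transcript_id: str) -> pd.DataFrame:
        """Replicate-mean FPKM, indexed by time_point with mut/wt columns.

        Raises KeyError naming the missing condition when a (time point,
        genotype) cell has no observations.
        """
        f = self._frame[self._frame["transcript_id"] == transcript_id]
        if f.empty:
            raise KeyError(f"no expression for transcript {transcript_id}")
        table = f.pivot_table(
            index="time_point", columns="genotype", values="fpkm", aggfunc="mean"
        )
        for tp in TIME_POINTS:
            for gt in GENOTYPES:
                if tp not in table.index or gt not in table.columns or pd.isna(
                    table.at[tp, gt] if tp in table.index and gt in table.columns else None
                ):
                    raise KeyError(
                        f"transcript {transcript_id}: missing condition "
                        f"(time point {tp}, genotype {gt})"
                    )
        return table.loc[list(TIME_POINTS), list(GENOTYPES)]
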