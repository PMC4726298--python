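"""Readers and writers for the formats the pipeline touches.

GTF records are 1-based inclusive; everything internal is 0-based half-open,
so the shift happens here and nowhere else.  BED output needs no shift.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    Source,
    TranscriptModel,
)


class GtfParseError(ValueError):
    pass


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcripts_gtf(path: str | os.PathLike, source: Source | str = Source.ASSEMBLED
                         ) -> list[TranscriptModel]:
    """Read exon-grouped GTF transcript models (assembler output dialect).

    Exon feature lines sharing a ``transcript_id`` attribute form one
    transcript; line order does not matter.  Coordinates are converted from
    1-based inclusive to internal 0-based half-open.  Returned transcripts are
    sorted by (chrom, start, id).
    """
    source = Source(source)
    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: bad coordinate range "
                    f"{start1}-{end1}"
                )
            if strand not in ("+", "-", "."):
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: bad strand {strand!r}"
                )
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(
                    f"{path}: malformed GTF line {lineno}: missing transcript_id"
                )
            exons_by_tid.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )

    transcripts = []
    for tid, exons in exons_by_tid.items():
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise GtfParseError(
                f"{path}: transcript {tid}: exons on mismatched chrom/strand"
            )
        exons = sorted(exons, key=lambda e: e.start)
        interval = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        transcripts.append(TranscriptModel(tid, interval, exons, source))
    transcripts.sort(key=lambda t: (t.chrom, t.interval.start, t.id))
    return transcripts


def write_transcripts_gtf(transcripts: list[TranscriptModel], path: str | os.PathLike,
                          source_label: str = "telolnc") -> None:
    """Write exon lines in GTF dialect (adds 1 to starts)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)):
            for e in t.exons:
                attrs = f'transcript_id "{t.id}"; gene_id "{t.id}";'
                fh.write(
                    f"{e.chrom}\t{source_label}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def read_utr_extents_tsv(path: str | os.PathLike) -> dict[str, tuple[int, int]]:
    """Read per-gene UTR extensions: columns gene_id, utr5, utr3 (bp,
    genomic left/right of the gene interval)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"gene_id", "utr5", "utr3"}
    if not required <= set(frame.columns):
        raise ValueError(f"UTR table must have columns {sorted(required)}")
    return {
        str(row.gene_id): (int(row.utr5), int(row.utr3))
        for row in frame.itertuples()
    }


def read_annotation(genes_gtf: str | os.PathLike, known_ncrnas_gtf: str | os.PathLike | None = None,
                    utr_extents_tsv: str | os.PathLike | None = None) -> AnnotationSet:
    genes = read_transcripts_gtf(genes_gtf, Source.ANNOTATED_GENE)
    known = (
        read_transcripts_gtf(known_ncrnas_gtf, Source.KNOWN_NCRNA)
        if known_ncrnas_gtf
        else []
    )
    utrs = read_utr_extents_tsv(utr_extents_tsv) if utr_extents_tsv else {}
    return AnnotationSet(genes=genes, known_ncrnas=known, utr_extents=utrs)


def read_expression_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a long-format FPKM table (transcript_id, time_point, genotype,
    replicate, fpkm).  Duplicate keys, negative FPKM and unknown labels are
    rejected by the ExpressionMatrix constructor."""
    frame = pd.read_csv(path, sep="\t")
    return ExpressionMatrix(frame)


def write_expression_tsv(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.to_frame().to_csv(path, sep="\t", index=False)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_transcript_sequences(transcripts: list[TranscriptModel],
                                 genome: dict[str, str]) -> dict[str, str]:
    """Spliced, strand-oriented transcript sequences from genome sequences."""
    out = {}
    for t in transcripts:
        parts = [genome[t.chrom][e.start:e.end] for e in t.exons]
        seq = "".join(parts)
        if t.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[t.id] = seq
    return out


def write_bed(transcripts: list[TranscriptModel], scores: dict[str, float],
              path: str | os.PathLike) -> None:
    """BED6 of transcripts; score column carries max |log2 DE| (0 if absent)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.id)):
            score = scores.get(t.id, 0.0)
            strand = t.strand if t.strand != "." else "."
            fh.write(
                f"{t.chrom}\t{t.interval.start}\t{t.interval.end}\t{t.id}\t"
                f"{score:.4f}\t{strand}\n"
            )


# Stable column orders for the result tables (documented in docs/methods.md).
RESULT_TABLE_COLUMNS = {
    "candidates": ["transcript_id", "chrom", "start", "end", "strand", "length"],
    "novelty": ["transcript_id", "verdict", "matched_id", "d5", "d3"],
    "coding": ["transcript_id", "orf_length", "orf_coverage", "score", "verdict"],
    "de_matrix": ["transcript_id", "de_t1", "de_t2", "de_t3", "de_t4", "de_t5"],
    "calls": [
        "transcript_id", "call_t1", "call_t2", "call_t3", "call_t4", "call_t5",
        "is_differential", "is_tml",
    ],
    "correlation": [
        "lncrna_id", "gene_id", "side", "gap", "n", "r", "r2", "p", "q",
        "sign", "strong", "significant",
    ],
    "enrichment": ["term", "k", "K", "n", "N", "fold_enrichment", "p", "q"],
}


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike,
                  novel_lncrnas: list[TranscriptModel] | None = None,
                  bed_scores: dict[str, float] | None = None) -> dict[str, Path]:
    """Write result tables as TSV (stable column order) plus a BED of novel
    lncRNAs.  Empty tables produce headers-only files.  Byte-deterministic
    for identical inputs."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths: dict[str, Path] = {}
    for name, frame in tables.items():
        columns = RESULT_TABLE_COLUMNS.get(name)
        if columns is not None:
            frame = frame.reindex(columns=columns)
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path
    if novel_lncrnas is not None:
        bed_path = out_dir / "novel_lncrnas.bed"
        write_bed(novel_lncrnas, bed_scores or {}, bed_path)
        paths["novel_lncrnas_bed"] = bed_path
    return paths
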