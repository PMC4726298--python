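"""Synthetic study generator with planted ground truth.

Emulates the inputs of a telomerase-negative senescence time course at desk
scale: a two-chromosome genome with non-overlapping protein-coding genes
(UTR extents attached), previously reported intergenic noncoding transcripts,
assembled candidate transcripts in planted categories (truly novel,
gene-overlapping, UTR-overlapping, near-duplicates of known ncRNAs with end
offsets straddling the 50-bp boundary, gene-extension decoys), and an FPKM
matrix over 5 time points x 2 genotypes x 2 replicates with log-normal noise.

Planted expression structure: broad telomerase-mutant lncRNAs (up at several
time points, never down), stage-specific transcripts detectable only in their
stage, down-regulated and flat decoys, and lncRNA-neighbor-gene pairs whose
noise-free differential profiles have an exactly constructed sample
correlation equal to the target r.  Everything is reproducible byte-for-byte
from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coding import find_longest_orf
from .correlation import find_adjacent
from .enrichment import TermMap
from .models import (
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    REPLICATES,
    Source,
    TIME_POINTS,
    TranscriptModel,
)

TERM_NAMES = (
    "membrane", "extracellular", "cell_wall", "transport",
    "metabolism", "ribosome", "nucleus", "mitochondrion",
)

_NONSTOP_CODONS = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic time course.

    Defaults are the package's reference conditions: noise and fold
    magnitudes sized to bulk yeast RNA-seq (log-normal replicate noise
    sigma 0.25, planted up-folds >= 4), novel transcript lengths with
    median 467 nt, low wild-type lncRNA baselines, and planted neighbor
    correlations in the 0.96-0.99 band.
    """

    seed: int = 0
    # genome & annotation
    n_chroms: int = 2
    chrom_length: int = 250_000
    n_genes: int = 48
    gene_length_range: tuple[int, int] = (900, 2400)
    min_gene_gap: int = 2500
    gene_gap_jitter: int = 1500
    utr5: int = 100
    utr3: int = 150
    n_known_ncrnas: int = 10
    known_ncrna_length_range: tuple[int, int] = (320, 700)
    placement_margin: int = 60
    known_clearance: int = 200
    # candidate categories
    n_truly_novel: int = 14
    n_gene_overlapping: int = 4
    n_utr_overlapping: int = 3
    n_known_duplicate: int = 5
    n_gene_extension: int = 3
    duplicate_end_offsets: tuple[tuple[int, int], ...] = (
        (10, 10), (49, 49), (50, 50), (51, 0), (120, 120),
    )
    end_divergence_threshold: int = 50
    end_rule: str = "both"
    novel_length_median: float = 467.0
    novel_length_sigma: float = 0.5
    novel_length_min: int = 230
    novel_length_max: int = 3000
    multi_exon: bool = False
    min_orf_nt: int = 300
    # expression structure
    n_tml: int = 8
    stage_specific_counts: tuple[int, int, int, int, int] = (0, 1, 1, 0, 2)
    n_down_decoys: int = 1
    tml_up_log2_range: tuple[float, float] = (2.0, 4.5)
    tml_up_prob: float = 0.6
    stage_log2_fold: float = 3.58
    down_log2_fold: float = -3.0
    lnc_baseline_range: tuple[float, float] = (1.5, 7.0)
    gene_baseline_range: tuple[float, float] = (20.0, 200.0)
    stage_wt_baseline: float = 0.4
    noise_sigma: float = 0.25
    zero_inflation: float = 0.0
    detection_threshold: float = 1.0
    pseudocount: float = 1.0
    # planted correlations and enrichment
    pair_r_targets: tuple[float, ...] = (
        0.98, -0.98, 0.96, -0.96, 0.99, 0.97, -0.97, 0.98,
    )
    gene_fold_scale: float = 1.0
    n_terms: int = 8
    planted_term: str = "membrane"
    planted_term_prob: float = 0.9

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.n_genes, self.n_known_ncrnas,
            self.n_truly_novel, self.n_gene_overlapping, self.n_utr_overlapping,
            self.n_known_duplicate, self.n_gene_extension, self.n_tml,
            self.n_down_decoys,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if any(abs(r) > 1 for r in self.pair_r_targets):
            raise ValueError("|r_target| must be <= 1")
        if len(self.stage_specific_counts) != len(TIME_POINTS):
            raise ValueError("stage_specific_counts needs one entry per time point")
        structured = self.n_tml + sum(self.stage_specific_counts) + self.n_down_decoys
        if structured > self.n_truly_novel:
            raise ValueError(
                "n_tml + stage-specific + down decoys exceeds n_truly_novel"
            )
        if len(self.pair_r_targets) > self.n_tml + sum(self.stage_specific_counts):
            raise ValueError("more correlated pairs than variance-bearing lncRNAs")
        if self.n_known_duplicate > 0 and not self.duplicate_end_offsets:
            raise ValueError("duplicate_end_offsets must be non-empty")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")

    @property
    def n_candidates(self) -> int:
        return (self.n_truly_novel + self.n_gene_overlapping + self.n_utr_overlapping
                + self.n_known_duplicate + self.n_gene_extension)


@dataclass
class GroundTruth:
    """Planted labels, consistent with the emitted files."""

    candidates: pd.DataFrame      # per-candidate category and expected labels
    pairs: pd.DataFrame           # planted (lncRNA, gene) correlations
    fold_log2: pd.DataFrame       # planted log2 fold per transcript x time point
    planted_term: str = ""

    def novel_ids(self) -> set[str]:
        f = self.candidates
        return set(f.loc[f["expected_verdict"] == "novel", "transcript_id"])

    def lncrna_ids(self) -> set[str]:
        f = self.candidates
        return set(f.loc[f["is_lncrna"], "transcript_id"])

    def tml_ids(self) -> set[str]:
        f = self.candidates
        return set(f.loc[f["is_tml"], "transcript_id"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: AnnotationSet
    genome: dict[str, str]
    candidates: list[TranscriptModel]
    sequences: dict[str, str]     # candidate spliced sequences
    expression: ExpressionMatrix
    term_map: TermMap
    truth: GroundTruth


class PlacementError(RuntimeError):
    pass


class _FreePool:
    """Bookkeeping of unoccupied intergenic intervals per chromosome."""

    def __init__(self):
        self.slots: list[tuple[str, int, int]] = []

    def add(self, chrom: str, start: int, end: int) -> None:
        if end - start > 0:
            self.slots.append((chrom, start, end))
            self.slots.sort()

    def take(self, length: int, clearance: int, rng: np.random.Generator,
             what: str = "feature") -> tuple[str, int, int]:
        need = length + 2 * clearance
        feasible = [i for i, (c, s, e) in enumerate(self.slots) if e - s >= need]
        if not feasible:
            raise PlacementError(
                f"cannot place {what} of {length} bp: no intergenic slot of "
                f">= {need} bp left; increase chrom_length"
            )
        idx = feasible[int(rng.integers(len(feasible)))]
        chrom, s, e = self.slots.pop(idx)
        offset = int(rng.integers(0, e - s - need + 1))
        start = s + clearance + offset
        end = start + length
        self.add(chrom, s, start - clearance)
        self.add(chrom, end + clearance, e)
        return chrom, start, end


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_strand(rng) -> str:
    return "+" if rng.integers(2) == 0 else "-"


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_annotation(config: SimulationConfig
                        ) -> tuple[AnnotationSet, dict[str, str]]:
    """Place non-overlapping genes (with UTR extents) and intergenic known
    ncRNAs; emit a random genome with ORFs planted inside the genes."""
    rng = _rng(config, 1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        c: "".join(np.array(list("ACGT"))[rng.integers(0, 4, config.chrom_length)])
        for c in chroms
    }

    genes: list[TranscriptModel] = []
    utr_extents: dict[str, tuple[int, int]] = {}
    pool = _FreePool()
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 1000
        for _ in range(n_here):
            start = cursor + config.min_gene_gap + int(
                rng.integers(0, config.gene_gap_jitter + 1)
            )
            length = int(rng.integers(*config.gene_length_range))
            end = start + length
            if end + config.utr3 + config.placement_margin > config.chrom_length - 1000:
                raise PlacementError(
                    f"gene packing infeasible on {chrom}; increase chrom_length"
                )
            gi += 1
            gid = f"gene_{gi:04d}"
            strand = _random_strand(rng)
            genes.append(TranscriptModel(
                gid, GenomicInterval(chrom, start, end, strand),
                source=Source.ANNOTATED_GENE,
            ))
            utr_extents[gid] = (
                (config.utr5, config.utr3) if strand == "+" else (config.utr3, config.utr5)
            )
            # intergenic free region between the previous footprint and this gene
            left_edge = start - max(utr_extents[gid][0], 0) - config.placement_margin
            pool.add(chrom, cursor, left_edge)
            cursor = end + utr_extents[gid][1] + config.placement_margin
        pool.add(chrom, cursor, config.chrom_length - 500)

    # plant one long ORF inside each gene (oriented on the gene strand)
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        bases = "ACGT"
        _NONSTOP_CODONS = [
            a + b + c for a in bases for b in bases for c in bases
            if a + b + c not in ("TAA", "TAG", "TGA")
        ]
    codons = np.array(_NONSTOP_CODONS)
    for gene in genes:
        glen = gene.length
        n_codons = max(((glen * 9 // 10) // 3) - 2, 2)
        body = "".join(codons[rng.integers(0, len(codons), n_codons)])
        orf = "ATG" + body + "TAA"
        offset = (glen - len(orf)) // 2
        piece = orf if gene.strand == "+" else _revcomp(orf)
        s = gene.interval.start + offset
        genome[gene.chrom] = (
            genome[gene.chrom][:s] + piece + genome[gene.chrom][s + len(piece):]
        )

    known: list[TranscriptModel] = []
    for i in range(config.n_known_ncrnas):
        length = int(rng.integers(*config.known_ncrna_length_range))
        chrom, start, end = pool.take(
            length, config.known_clearance, rng, what="known ncRNA"
        )
        known.append(TranscriptModel(
            f"sut_{i + 1:03d}", GenomicInterval(chrom, start, end, _random_strand(rng)),
            source=Source.KNOWN_NCRNA,
        ))

    annotation = AnnotationSet(genes=genes, known_ncrnas=known, utr_extents=utr_extents)
    # stash the remaining pool for candidate placement under the same seed
    annotation._free_pool = pool  # type: ignore[attr-defined]
    return annotation, genome


def _novel_length(config: SimulationConfig, rng) -> int:
    mu = np.log(config.novel_length_median)
    length = int(round(np.exp(rng.normal(mu, config.novel_length_sigma))))
    return int(np.clip(length, config.novel_length_min, config.novel_length_max))


def _expected_duplicate_verdict(d5: int, d3: int, config: SimulationConfig) -> str:
    thr = config.end_divergence_threshold
    if config.end_rule == "both":
        matched = abs(d5) <= thr and abs(d3) <= thr
    else:
        matched = abs(d5) <= thr or abs(d3) <= thr
    return "rejected_known_ncRNA_match" if matched else "novel"


def simulate_candidates(annotation: AnnotationSet, config: SimulationConfig
                        ) -> tuple[list[TranscriptModel], GroundTruth]:
    """Emit assembled-candidate transcript models in planted categories with
    their expected novelty verdicts."""
    rng = _rng(config, 2)
    pool: _FreePool = getattr(annotation, "_free_pool", None)
    if pool is None:
        raise ValueError("annotation must come from simulate_annotation")

    candidates: list[TranscriptModel] = []
    rows = []
    ci = 0

    def new_id() -> str:
        nonlocal ci
        ci += 1
        return f"cand_{ci:03d}"

    def add(interval: GenomicInterval, category: str, verdict: str,
            matched: str = "", d5=np.nan, d3=np.nan) -> TranscriptModel:
        t = TranscriptModel(new_id(), interval, source=Source.ASSEMBLED)
        candidates.append(t)
        rows.append({
            "transcript_id": t.id, "category": category,
            "expected_verdict": verdict, "matched_known": matched,
            "d5": d5, "d3": d3, "length": t.length,
            "is_lncrna": verdict == "novel" and t.length > 200,
        })
        return t

    # one truly-novel candidate per gene-bounded gap, so adjacency-based
    # ground truth (planted neighbor pairs) stays unambiguous
    used_gaps: set[tuple] = set()

    def flanking_genes(chrom: str, start: int, end: int) -> tuple:
        left = right = None
        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            if g.interval.end <= start and (left is None or g.interval.end > left[0]):
                left = (g.interval.end, g.id)
            if g.interval.start >= end and (right is None or g.interval.start < right[0]):
                right = (g.interval.start, g.id)
        return (chrom, left[1] if left else None, right[1] if right else None)

    for _ in range(config.n_truly_novel):
        length = _novel_length(config, rng)
        for _attempt in range(50):
            chrom, start, end = pool.take(
                length, config.placement_margin, rng, what="novel candidate"
            )
            gap = flanking_genes(chrom, start, end)
            if gap not in used_gaps:
                used_gaps.add(gap)
                break
        else:
            raise PlacementError(
                "could not find a fresh intergenic gap for a novel candidate; "
                "increase chrom_length or n_genes"
            )
        add(GenomicInterval(chrom, start, end, _random_strand(rng)),
            "truly_novel", "novel")

    # decoy categories anchored to distinct genes
    n_decoy_genes = (config.n_gene_overlapping + config.n_utr_overlapping
                     + config.n_gene_extension)
    if n_decoy_genes > len(annotation.genes):
        raise PlacementError("not enough genes to anchor decoy candidates")
    decoy_genes = list(rng.choice(len(annotation.genes), n_decoy_genes, replace=False))

    def pop_gene() -> TranscriptModel:
        return annotation.genes[int(decoy_genes.pop())]

    for _ in range(config.n_gene_overlapping):
        g = pop_gene()
        iv = GenomicInterval(g.chrom, g.interval.end - 300, g.interval.end + 100,
                             _random_strand(rng))
        add(iv, "gene_overlapping", "rejected_gene_overlap", matched=g.id)
    for _ in range(config.n_utr_overlapping):
        g = pop_gene()
        iv = GenomicInterval(g.chrom, g.interval.end + 5, g.interval.end + 205,
                             _random_strand(rng))
        add(iv, "utr_overlapping", "rejected_utr_overlap", matched=g.id)
    for _ in range(config.n_gene_extension):
        g = pop_gene()
        iv = GenomicInterval(g.chrom, g.interval.end, g.interval.end + 205,
                             _random_strand(rng))
        add(iv, "gene_extension", "rejected_utr_overlap", matched=g.id)

    if config.n_known_duplicate > len(annotation.known_ncrnas):
        raise PlacementError("not enough known ncRNAs for duplicate candidates")
    for j in range(config.n_known_duplicate):
        known = annotation.known_ncrnas[j]
        d5_mag, d3_mag = config.duplicate_end_offsets[
            j % len(config.duplicate_end_offsets)
        ]
        s5 = int(rng.integers(2)) * 2 - 1
        s3 = int(rng.integers(2)) * 2 - 1
        start = known.interval.start + s5 * d5_mag
        end = known.interval.end + s3 * d3_mag
        verdict = _expected_duplicate_verdict(d5_mag, d3_mag, config)
        add(GenomicInterval(known.chrom, start, end, known.strand),
            "known_ncRNA_duplicate", verdict,
            matched=known.id if verdict != "novel" else "",
            d5=d5_mag, d3=d3_mag)

    truth = GroundTruth(
        candidates=pd.DataFrame(rows),
        pairs=pd.DataFrame(columns=["lncrna_id", "gene_id", "side", "gap", "r_target"]),
        fold_log2=pd.DataFrame(),
        planted_term=config.planted_term,
    )
    return candidates, truth


def _mixed_partner_profile(fold: np.ndarray, r_target: float, scale: float,
                           rng) -> np.ndarray:
    """A profile whose sample correlation with ``fold`` over the time points
    is exactly r_target (shared-latent mixing in the centered subspace)."""
    fc = fold - fold.mean()
    norm = np.linalg.norm(fc)
    if norm == 0:
        raise ValueError("cannot correlate with a constant fold profile")
    u1 = fc / norm
    while True:
        z = rng.normal(size=len(fold))
        z -= z.mean()
        z -= (z @ u1) * u1
        zn = np.linalg.norm(z)
        if zn > 1e-9:
            u2 = z / zn
            break
    g = r_target * u1 + np.sqrt(max(0.0, 1 - r_target ** 2)) * u2
    return g * norm * scale


def _assign_fold_profiles(config: SimulationConfig, truth: GroundTruth,
                          candidates, annotation, rng
                          ) -> tuple[dict[str, np.ndarray], dict[str, float], pd.DataFrame]:
    """Planted log2 fold per transcript and wild-type baselines; returns the
    pairs table as well."""
    cand_frame = truth.candidates
    novel_ids = [
        r.transcript_id for r in cand_frame.itertuples() if r.category == "truly_novel"
    ]
    folds: dict[str, np.ndarray] = {}
    baselines: dict[str, float] = {}
    stage_sets: dict[str, frozenset[int]] = {}

    def lnc_baseline() -> float:
        lo, hi = config.lnc_baseline_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    has_down: set[str] = set()
    profile_class: dict[str, str] = {}
    idx = 0
    broad_ids = novel_ids[idx:idx + config.n_tml]
    idx += config.n_tml
    for tid in broad_ids:
        fold = np.zeros(len(TIME_POINTS))
        ups = rng.random(len(TIME_POINTS)) < config.tml_up_prob
        if not ups.any():
            ups[int(rng.integers(len(TIME_POINTS)))] = True
        fold[ups] = rng.uniform(*config.tml_up_log2_range, size=ups.sum())
        folds[tid] = fold
        baselines[tid] = lnc_baseline()
        stage_sets[tid] = frozenset(
            tp for tp, u in zip(TIME_POINTS, ups) if u
        )
        profile_class[tid] = "broad_tml"

    stage_ids = []
    for stage, count in zip(TIME_POINTS, config.stage_specific_counts):
        for _ in range(count):
            tid = novel_ids[idx]
            idx += 1
            fold = np.zeros(len(TIME_POINTS))
            fold[stage - 1] = config.stage_log2_fold
            folds[tid] = fold
            baselines[tid] = config.stage_wt_baseline
            stage_sets[tid] = frozenset({stage})
            stage_ids.append(tid)
            profile_class[tid] = "stage_specific"

    for _ in range(config.n_down_decoys):
        tid = novel_ids[idx]
        idx += 1
        fold = np.zeros(len(TIME_POINTS))
        up_tp = int(rng.integers(len(TIME_POINTS)))
        down_tp = int(rng.choice([t for t in range(len(TIME_POINTS)) if t != up_tp]))
        fold[up_tp] = rng.uniform(*config.tml_up_log2_range)
        fold[down_tp] = config.down_log2_fold
        folds[tid] = fold
        baselines[tid] = lnc_baseline()
        stage_sets[tid] = frozenset({up_tp + 1})
        has_down.add(tid)
        profile_class[tid] = "down_decoy"

    for tid in novel_ids[idx:]:   # flat remainder
        folds[tid] = np.zeros(len(TIME_POINTS))
        baselines[tid] = lnc_baseline()
        stage_sets[tid] = frozenset()
        profile_class[tid] = "flat"

    # decoy candidates and genes: flat unless a planted correlation partner
    for r in cand_frame.itertuples():
        if r.transcript_id not in folds:
            folds[r.transcript_id] = np.zeros(len(TIME_POINTS))
            baselines[r.transcript_id] = lnc_baseline()
    for gene in annotation.genes:
        folds[gene.id] = np.zeros(len(TIME_POINTS))
        lo, hi = config.gene_baseline_range
        baselines[gene.id] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    # planted neighbor correlations: assign pairs to variance-bearing lncRNAs.
    # A partner gene must be adjacent to exactly one variance-bearing lncRNA,
    # otherwise its planted profile could echo a second lncRNA's profile and
    # blur the pair-level ground truth.
    by_id = {t.id: t for t in candidates}
    eligible = broad_ids + stage_ids
    adjacency: dict[str, tuple] = {}
    gene_degree: dict[str, int] = {}
    for tid in eligible:
        adjacency[tid] = find_adjacent(by_id[tid], annotation)
        for p in adjacency[tid]:
            if p is not None:
                gene_degree[p.gene_id] = gene_degree.get(p.gene_id, 0) + 1
    pair_rows = []
    used_genes: set[str] = set()
    li = 0
    for r_target in config.pair_r_targets:
        while li < len(eligible):
            tid = eligible[li]
            li += 1
            left, right = adjacency[tid]
            options = [
                p for p in (left, right)
                if p and p.gene_id not in used_genes and gene_degree[p.gene_id] == 1
            ]
            if not options:
                continue
            pair = options[int(rng.integers(len(options)))]
            used_genes.add(pair.gene_id)
            folds[pair.gene_id] = _mixed_partner_profile(
                folds[tid], r_target, config.gene_fold_scale, rng
            )
            pair_rows.append({
                "lncrna_id": tid, "gene_id": pair.gene_id, "side": pair.side,
                "gap": pair.gap, "r_target": r_target,
            })
            break
        else:
            raise PlacementError("ran out of lncRNAs to host planted correlations")

    pairs = pd.DataFrame(
        pair_rows, columns=["lncrna_id", "gene_id", "side", "gap", "r_target"]
    )

    cand_frame = cand_frame.copy()
    cand_frame["is_tml"] = [
        bool(stage_sets.get(r.transcript_id))
        and r.transcript_id not in has_down
        and r.category == "truly_novel"
        for r in cand_frame.itertuples()
    ]
    cand_frame["stage_set"] = [
        "|".join(str(tp) for tp in sorted(stage_sets.get(r.transcript_id, frozenset())))
        for r in cand_frame.itertuples()
    ]
    cand_frame["profile_class"] = [
        profile_class.get(r.transcript_id, "decoy") for r in cand_frame.itertuples()
    ]
    truth.candidates = cand_frame
    return folds, baselines, pairs


def simulate_expression(candidates: list[TranscriptModel], annotation: AnnotationSet,
                        config: SimulationConfig, truth: GroundTruth
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """FPKM matrix for all candidates and genes under the planted fold
    structure: wt ~ baseline * lognormal, mut = baseline * 2^fold * lognormal,
    replicates independent."""
    rng = _rng(config, 3)
    folds, baselines, pairs = _assign_fold_profiles(
        config, truth, candidates, annotation, rng
    )
    records = []
    for tid in sorted(folds):
        fold = folds[tid]
        base = baselines[tid]
        for i, tp in enumerate(TIME_POINTS):
            for rep in REPLICATES:
                for genotype, level in (
                    ("wt", base), ("mut", base * 2.0 ** fold[i])
                ):
                    value = level * float(np.exp(rng.normal(0.0, config.noise_sigma))) \
                        if config.noise_sigma > 0 else level
                    if config.zero_inflation > 0 and rng.random() < config.zero_inflation:
                        value = 0.0
                    records.append((tid, tp, genotype, rep, value))
    expr = ExpressionMatrix.from_records(records)
    fold_frame = pd.DataFrame(
        {f"t{tp}": [folds[tid][i] for tid in sorted(folds)]
         for i, tp in enumerate(TIME_POINTS)},
        index=sorted(folds),
    )
    fold_frame.index.name = "transcript_id"
    truth.fold_log2 = fold_frame
    truth.pairs = pairs
    return expr, truth


def _make_term_map(annotation: AnnotationSet, truth: GroundTruth,
                   config: SimulationConfig, rng) -> TermMap:
    terms = {name: set() for name in TERM_NAMES[:config.n_terms]}
    names = list(terms)
    partner_genes = set(truth.pairs["gene_id"])
    for gene in annotation.genes:
        base = names[int(rng.integers(len(names)))]
        terms[base].add(gene.id)
        if gene.id in partner_genes and rng.random() < config.planted_term_prob:
            terms[config.planted_term].add(gene.id)
    universe = frozenset(g.id for g in annotation.genes)
    return TermMap(terms={t: frozenset(g) for t, g in terms.items()},
                   universe=universe)


def extract_candidate_sequences(candidates, genome, enforce_noncoding: set[str],
                                config: SimulationConfig, rng) -> dict[str, str]:
    """Strand-oriented candidate sequences from the genome; ids in
    ``enforce_noncoding`` are regenerated in place until they carry no ORF
    >= min_orf_nt (they model noncoding transcripts)."""
    sequences = {}
    for t in candidates:
        s, e = t.interval.start, t.interval.end
        raw = genome[t.chrom][s:e]
        seq = _revcomp(raw) if t.strand == "-" else raw
        if t.id in enforce_noncoding:
            attempts = 0
            while find_longest_orf(seq, frames=3)[0] >= config.min_orf_nt:
                attempts += 1
                if attempts > 200:
                    raise PlacementError(f"could not de-ORF candidate {t.id}")
                seq = "".join(
                    np.array(list("ACGT"))[rng.integers(0, 4, len(seq))]
                )
            raw = _revcomp(seq) if t.strand == "-" else seq
            genome[t.chrom] = genome[t.chrom][:s] + raw + genome[t.chrom][e:]
        sequences[t.id] = seq
    return sequences


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run the whole generator: annotation + genome, candidates, sequences,
    expression, term map, ground truth."""
    config = config or SimulationConfig()
    annotation, genome = simulate_annotation(config)
    candidates, truth = simulate_candidates(annotation, config)
    rng = _rng(config, 4)
    noncoding = {
        r.transcript_id for r in truth.candidates.itertuples()
        if r.category in ("truly_novel", "known_ncRNA_duplicate")
    }
    sequences = extract_candidate_sequences(
        candidates, genome, noncoding, config, rng
    )
    expr, truth = simulate_expression(candidates, annotation, config, truth)
    term_map = _make_term_map(annotation, truth, config, _rng(config, 5))
    return SimulatedDataset(
        config=config, annotation=annotation, genome=genome,
        candidates=candidates, sequences=sequences, expression=expr,
        term_map=term_map, truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, object]:
    """Emit the dataset in the exact file formats the io module reads, plus
    ground-truth manifests."""
    from pathlib import Path

    from . import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = dataset.annotation
    io_formats.write_transcripts_gtf(ann.genes, out / "genes.gtf", "simulated")
    io_formats.write_transcripts_gtf(ann.known_ncrnas, out / "known_ncrnas.gtf", "simulated")
    io_formats.write_transcripts_gtf(dataset.candidates, out / "candidates.gtf", "simulated")
    io_formats.write_fasta(dataset.genome, out / "genome.fa")
    io_formats.write_fasta(dataset.sequences, out / "transcripts.fa")
    io_formats.write_expression_tsv(dataset.expression, out / "expression.tsv")
    pd.DataFrame(
        [{"gene_id": gid, "utr5": u5, "utr3": u3}
         for gid, (u5, u3) in sorted(ann.utr_extents.items())]
    ).to_csv(out / "utr_extents.tsv", sep="\t", index=False)
    with open(out / "terms.tsv", "w") as fh:
        for term in sorted(dataset.term_map.terms):
            for gene in sorted(dataset.term_map.terms[term]):
                fh.write(f"{term}\t{gene}\n")
    dataset.truth.candidates.to_csv(out / "truth_candidates.tsv", sep="\t", index=False)
    dataset.truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
    dataset.truth.fold_log2.to_csv(out / "truth_folds.tsv", sep="\t")
    return {"out_dir": out}
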