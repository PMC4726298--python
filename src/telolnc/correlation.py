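"""Neighbor-gene and genome-wide co-expression analysis.

For every lncRNA the nearest annotated gene on each genomic side is its
adjacent gene; the lncRNA's differential-expression profile is correlated
with each neighbor's (Pearson r, two-sided p from the t transform with
n - 2 degrees of freedom).  Observations are the five per-time-point log2
ratios by default; a per-replicate mode (n = 10) is available for more
degrees of freedom at small time-course length.  Genome-wide, an
lncRNA x gene matrix of r values is ordered by average-linkage hierarchical
clustering on the 1 - r distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .models import AnnotationSet, ExpressionMatrix, REPLICATES, TIME_POINTS, TranscriptModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeighborPair:
    lncrna_id: str
    gene_id: str
    side: str      # "5p" (genomic left) or "3p" (genomic right)
    gap: int       # bp between nearest ends, >= 0


class ZeroVarianceError(ValueError):
    """Correlation is undefined when either vector is constant."""


def find_adjacent(lncrna: TranscriptModel, annotation: AnnotationSet
                  ) -> tuple[NeighborPair | None, NeighborPair | None]:
    """Nearest gene by end-to-end gap on each genomic side, strand-blind.

    Ties break by lower gene start, then lexicographic id.  A side with no
    gene (chromosome end) yields None.  The lncRNA must not overlap any gene
    (it has passed the novelty filter).
    """
    left_best = right_best = None  # (gap, gene.start, gene.id, gene)
    for gene in annotation.genes:
        if gene.chrom != lncrna.chrom:
            continue
        if lncrna.interval.overlap_length(gene.interval) > 0:
            raise ValueError(
                f"lncRNA {lncrna.id} overlaps gene {gene.id}; "
                "novelty filtering must precede adjacency"
            )
        if gene.interval.end <= lncrna.interval.start:
            key = (lncrna.interval.start - gene.interval.end, gene.interval.start, gene.id)
            if left_best is None or key < left_best[:3]:
                left_best = (*key, gene)
        elif gene.interval.start >= lncrna.interval.end:
            key = (gene.interval.start - lncrna.interval.end, gene.interval.start, gene.id)
            if right_best is None or key < right_best[:3]:
                right_best = (*key, gene)
    left = (
        NeighborPair(lncrna.id, left_best[3].id, "5p", left_best[0])
        if left_best else None
    )
    right = (
        NeighborPair(lncrna.id, right_best[3].id, "3p", right_best[0])
        if right_best else None
    )
    return left, right


def pearson_with_p(x, y) -> tuple[int, float, float, float]:
    """Pearson r with a two-sided p-value.

    Returns (n, r, r2, p); p comes from t = r*sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom.  For degenerate |r| = 1 the limiting value p = 0 is
    reported.  Raises ZeroVarianceError when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return n, r, r * r, float(res.pvalue)


def replicate_de_vectors(expr: ExpressionMatrix, transcript_id: str,
                         pseudocount: float = 1.0) -> np.ndarray:
    """Per-replicate log2((mut+c)/(wt+c)) over (time point, replicate):
    a length 2*T vector pairing replicate A with A and B with B."""
    out = []
    for tp in TIME_POINTS:
        mut = expr.values_for(transcript_id, tp, "mut")
        wt = expr.values_for(transcript_id, tp, "wt")
        if len(mut) != len(REPLICATES) or len(wt) != len(REPLICATES):
            raise KeyError(
                f"transcript {transcript_id}: incomplete replicates at time point {tp}"
            )
        out.extend(np.log2(mut + pseudocount) - np.log2(wt + pseudocount))
    return np.asarray(out)


def neighbor_correlation_table(profiles: dict, pairs: list[NeighborPair],
                               mode: str = "timepoints",
                               expr: ExpressionMatrix | None = None,
                               pseudocount: float = 1.0,
                               strong_band: tuple[float, float] = (0.79, 0.99),
                               alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each (lncRNA, neighbor gene) pair.

    mode "timepoints": observations are the five per-time-point DE values
    (n = 5, df = 3).  mode "replicates": per-replicate DE (n = 10) — requires
    ``expr``.  Pairs with a missing profile or zero variance are skipped with
    a log entry.  "strong" flags r2 inside ``strong_band``; "significant"
    flags raw p < alpha; q is the Benjamini-Hochberg adjustment across the
    tested pairs.
    """
    if mode not in ("timepoints", "replicates"):
        raise ValueError("mode must be 'timepoints' or 'replicates'")
    if mode == "replicates" and expr is None:
        raise ValueError("replicates mode requires the expression matrix")

    def vector(tid: str) -> np.ndarray | None:
        if mode == "timepoints":
            prof = profiles.get(tid)
            return None if prof is None else prof.de
        try:
            return replicate_de_vectors(expr, tid, pseudocount)
        except KeyError:
            return None

    rows = []
    for pair in pairs:
        x = vector(pair.lncrna_id)
        y = vector(pair.gene_id)
        if x is None or y is None:
            log.info("skipping pair (%s, %s): missing profile",
                     pair.lncrna_id, pair.gene_id)
            continue
        try:
            n, r, r2, p = pearson_with_p(x, y)
        except ZeroVarianceError:
            log.info("skipping pair (%s, %s): zero variance",
                     pair.lncrna_id, pair.gene_id)
            continue
        rows.append({
            "lncrna_id": pair.lncrna_id,
            "gene_id": pair.gene_id,
            "side": pair.side,
            "gap": pair.gap,
            "n": n,
            "r": r,
            "r2": r2,
            "p": p,
            "sign": "positive" if r >= 0 else "negative",
            "strong": strong_band[0] <= r2 <= strong_band[1],
            "significant": p < alpha,
        })
    frame = pd.DataFrame(
        rows,
        columns=["lncrna_id", "gene_id", "side", "gap", "n", "r", "r2", "p",
                 "sign", "strong", "significant"],
    )
    if len(frame):
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    else:
        frame["q"] = pd.Series(dtype=float)
    frame = frame.sort_values(["lncrna_id", "side"]).reset_index(drop=True)
    return frame


def timepoint_scatter_table(profiles: dict, pairs: list[NeighborPair]) -> pd.DataFrame:
    """Long-format (lncRNA DE, neighbor DE) pairs per time point — the 2D
    scatter companion to the across-time-points fit."""
    rows = []
    for pair in pairs:
        lp = profiles.get(pair.lncrna_id)
        gp = profiles.get(pair.gene_id)
        if lp is None or gp is None:
            continue
        for i, tp in enumerate(TIME_POINTS):
            rows.append({
                "lncrna_id": pair.lncrna_id,
                "gene_id": pair.gene_id,
                "time_point": tp,
                "lncrna_de": lp.de[i],
                "gene_de": gp.de[i],
            })
    return pd.DataFrame(
        rows, columns=["lncrna_id", "gene_id", "time_point", "lncrna_de", "gene_de"]
    )


def _cluster_order(vectors: np.ndarray, ids: list[str]) -> list[str]:
    """Leaf order from average-linkage clustering on the 1 - r distance
    between profile vectors; inputs are pre-sorted by id for determinism."""
    if len(ids) < 2:
        return list(ids)
    corr = np.corrcoef(vectors)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    return [ids[i] for i in leaves_list(linkage)]


def genome_wide_matrix(lnc_profiles: dict, gene_profiles: dict
                       ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """lncRNA x gene Pearson-r matrix with clustered row/column orders.

    Zero-variance profiles are dropped with a log entry.  Requires >= 2
    lncRNAs and >= 2 genes with valid profiles.
    """
    def usable(profiles: dict) -> dict[str, np.ndarray]:
        out = {}
        for tid in sorted(profiles):
            de = profiles[tid].de
            if np.ptp(de) == 0:
                log.info("dropping zero-variance profile %s", tid)
                continue
            out[tid] = np.asarray(de, dtype=float)
        return out

    lnc = usable(lnc_profiles)
    genes = usable(gene_profiles)
    if len(lnc) < 2 or len(genes) < 2:
        raise ValueError("need >= 2 lncRNAs and >= 2 genes with non-constant profiles")

    lnc_ids, gene_ids = list(lnc), list(genes)
    lnc_mat = np.vstack([lnc[i] for i in lnc_ids])
    gene_mat = np.vstack([genes[i] for i in gene_ids])

    def standardize(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=1, keepdims=True)
        return m / np.linalg.norm(m, axis=1, keepdims=True)

    r = standardize(lnc_mat) @ standardize(gene_mat).T
    r = np.clip(r, -1.0, 1.0)
    matrix = pd.DataFrame(r, index=lnc_ids, columns=gene_ids)
    row_order = _cluster_order(lnc_mat, lnc_ids)
    col_order = _cluster_order(gene_mat, gene_ids)
    return matrix, row_order, col_order
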