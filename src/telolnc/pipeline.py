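"""End-to-end orchestration: simulate -> filter -> coding -> classify ->
correlate -> enrich, with one validated config, per-stage logging and a
machine-readable JSON report aggregating the headline counts."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coding, correlation, enrichment, expression, io_formats, novelty
from .models import Source
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys are rejected at load time."""

    seed: int = 0
    out_dir: str = "results"
    # input paths (all optional when the simulate stage is enabled)
    transcripts_gtf: str | None = None
    genes_gtf: str | None = None
    known_ncrnas_gtf: str | None = None
    utr_extents_tsv: str | None = None
    expression_tsv: str | None = None
    transcripts_fasta: str | None = None
    terms_tsv: str | None = None
    external_scores_tsv: str | None = None
    # stage toggles
    simulate: bool = True
    run_filter: bool = True
    run_coding: bool = True
    run_classify: bool = True
    run_correlate: bool = True
    run_enrich: bool = True
    # decision parameters
    end_divergence_threshold: int = 50
    strand_aware: bool = False
    end_rule: str = "both"
    min_lncrna_length: int = 200
    min_orf_nt: int = 300
    pseudocount: float = 1.0
    fold_threshold: float = 2.0
    detection_threshold: float = 1.0
    correlation_mode: str = "timepoints"
    strong_band: tuple[float, float] = (0.79, 0.99)
    alpha: float = 0.05
    senescence_stages: tuple[int, ...] = (2, 3)
    survivor_stages: tuple[int, ...] = (5,)
    # overrides forwarded to SimulationConfig (seed is taken from above)
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        def check(cond: bool, key: str, bound: str) -> None:
            if not cond:
                raise ValueError(f"config key '{key}' out of range: {bound}")

        check(self.end_divergence_threshold >= 0, "end_divergence_threshold", ">= 0")
        check(self.min_lncrna_length >= 0, "min_lncrna_length", ">= 0")
        check(self.pseudocount >= 0, "pseudocount", ">= 0")
        check(self.fold_threshold > 0, "fold_threshold", "> 0")
        check(self.detection_threshold >= 0, "detection_threshold", ">= 0")
        check(0 < self.alpha < 1, "alpha", "in (0, 1)")
        check(self.end_rule in ("both", "either"), "end_rule", "'both' or 'either'")
        check(self.correlation_mode in ("timepoints", "replicates"),
              "correlation_mode", "'timepoints' or 'replicates'")
        self.strong_band = tuple(float(v) for v in self.strong_band)
        check(0 <= self.strong_band[0] <= self.strong_band[1] <= 1,
              "strong_band", "0 <= lo <= hi <= 1")
        self.senescence_stages = tuple(int(v) for v in self.senescence_stages)
        self.survivor_stages = tuple(int(v) for v in self.survivor_stages)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strong_band"] = list(self.strong_band)
        d["senescence_stages"] = list(self.senescence_stages)
        d["survivor_stages"] = list(self.survivor_stages)
        return d


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (empty file -> all defaults), apply overrides,
    reject unknown keys and out-of-range values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("strong_band", "senescence_stages", "survivor_stages"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim_kwargs = dict(config.simulation)
        sim_kwargs["seed"] = config.seed
        ds = simulate_dataset(SimulationConfig(**sim_kwargs))
        return ds.candidates, ds.annotation, ds.expression, ds.sequences, ds.term_map
    if not config.transcripts_gtf or not config.genes_gtf:
        raise ValueError("transcripts_gtf and genes_gtf are required when "
                         "the simulate stage is disabled")
    candidates = io_formats.read_transcripts_gtf(config.transcripts_gtf, Source.ASSEMBLED)
    annotation = io_formats.read_annotation(
        config.genes_gtf, config.known_ncrnas_gtf, config.utr_extents_tsv
    )
    expr = (io_formats.read_expression_tsv(config.expression_tsv)
            if config.expression_tsv else None)
    sequences = None
    if config.transcripts_fasta:
        sequences = io_formats.read_fasta(config.transcripts_fasta)
    term_map = (enrichment.read_term_map(config.terms_tsv)
                if config.terms_tsv else None)
    return candidates, annotation, expr, sequences, term_map


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    On a stage failure a FAILED marker naming the stage is written next to
    any partial outputs and a PipelineStageError is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "stages": [],
        "counts": {},
        "skipped_stages": [],
    }
    tables: dict[str, pd.DataFrame] = {}
    current_stage = "load_inputs"
    try:
        candidates, annotation, expr, sequences, term_map = _load_inputs(config)
        report["stages"].append({"stage": "load_inputs",
                                 "n_candidates": len(candidates),
                                 "n_genes": len(annotation.genes),
                                 "n_known_ncrnas": len(annotation.known_ncrnas)})
        report["counts"]["candidates_in"] = len(candidates)
        tables["candidates"] = pd.DataFrame([
            {"transcript_id": t.id, "chrom": t.chrom, "start": t.interval.start,
             "end": t.interval.end, "strand": t.strand, "length": t.length}
            for t in candidates
        ])

        # ---- novelty filter -------------------------------------------------
        current_stage = "filter"
        if config.run_filter:
            params = novelty.NoveltyParams(
                end_divergence_threshold=config.end_divergence_threshold,
                strand_aware=config.strand_aware,
                end_rule=config.end_rule,
            )
            decisions = novelty.classify_novelty(candidates, annotation, params)
            by_verdict: dict[str, int] = {}
            for d in decisions:
                by_verdict[d.verdict.value] = by_verdict.get(d.verdict.value, 0) + 1
            novel_ids = {d.transcript_id for d in decisions
                         if d.verdict is novelty.Verdict.NOVEL}
            tables["novelty"] = pd.DataFrame([
                {"transcript_id": d.transcript_id, "verdict": d.verdict.value,
                 "matched_id": d.matched_id or "", "d5": d.d5, "d3": d.d3}
                for d in decisions
            ])
            report["counts"].update({
                "novel": len(novel_ids),
                **{k: v for k, v in sorted(by_verdict.items()) if k != "novel"},
            })
            report["stages"].append({"stage": "filter", "params": {
                "end_divergence_threshold": config.end_divergence_threshold,
                "strand_aware": config.strand_aware, "end_rule": config.end_rule,
            }, "verdicts": by_verdict})
        else:
            novel_ids = {t.id for t in candidates}
            report["skipped_stages"].append("filter")
            report["counts"]["novel"] = len(novel_ids)
        novel = [t for t in candidates if t.id in novel_ids]

        # ---- coding potential + length gate --------------------------------
        current_stage = "coding"
        assessments = None
        if config.run_coding:
            if config.external_scores_tsv:
                assessments = coding.load_external_scores(config.external_scores_tsv)
            elif sequences is not None:
                cparams = coding.CodingParams(min_orf_nt=config.min_orf_nt,
                                              orf_norm_nt=config.min_orf_nt)
                assessments = coding.assess_sequences(
                    {t.id: sequences[t.id] for t in novel if t.id in sequences},
                    cparams,
                )
            if assessments is not None:
                tables["coding"] = pd.DataFrame([
                    {"transcript_id": a.transcript_id, "orf_length": a.orf_length,
                     "orf_coverage": a.orf_coverage, "score": a.score,
                     "verdict": a.verdict}
                    for a in sorted(assessments.values(), key=lambda a: a.transcript_id)
                ])
            lnc_ids = coding.apply_lncrna_gates(
                novel, assessments, config.min_lncrna_length
            )
            report["stages"].append({
                "stage": "coding",
                "mode": "external" if config.external_scores_tsv
                        else ("sequence" if sequences is not None else "length-only"),
                "n_retained": len(lnc_ids),
            })
        else:
            lnc_ids = [t.id for t in novel]
            report["skipped_stages"].append("coding")
        lncrnas = [t for t in novel if t.id in set(lnc_ids)]
        report["counts"]["lncrnas"] = len(lncrnas)

        # ---- differential expression / TML / stage sets --------------------
        current_stage = "classify"
        lnc_profiles: dict = {}
        calls = []
        if config.run_classify and expr is not None:
            have_expr = set(expr.transcripts())
            lnc_profiles = expression.profiles_for(
                expr, [t.id for t in lncrnas if t.id in have_expr],
                config.pseudocount, config.detection_threshold,
            )
            calls = [expression.call_regulation(p, config.fold_threshold)
                     for p in lnc_profiles.values()]
            summary = expression.stage_partition(
                calls, config.senescence_stages, config.survivor_stages
            )
            stats = expression.summary_stats(lncrnas, lnc_profiles)
            tables["de_matrix"] = expression.de_table(lnc_profiles)
            tables["calls"] = expression.calls_table(calls)
            report["counts"].update({
                "differential": sum(1 for c in calls if c.is_differential),
                "tml": sum(1 for c in calls if c.is_tml),
                "upregulated_anywhere": summary.upregulated_anywhere,
                "up_multi_timepoint": summary.multi_timepoint,
                "senescence_exclusive": summary.senescence_exclusive,
                "survivor_specific": summary.survivor_specific,
                "all_timepoints": summary.all_timepoints,
            })
            report["summary_stats"] = stats
            report["stage_summary"] = expression.stage_summary_dict(summary)
            report["stages"].append({"stage": "classify",
                                     "n_profiles": len(lnc_profiles)})
        else:
            report["skipped_stages"].append("classify")

        # ---- neighbor + genome-wide correlation ----------------------------
        current_stage = "correlate"
        if config.run_correlate and expr is not None and lnc_profiles:
            pairs = []
            for t in lncrnas:
                try:
                    left, right = correlation.find_adjacent(t, annotation)
                except ValueError:
                    log.info("skipping adjacency for %s (overlaps a gene)", t.id)
                    continue
                pairs.extend(p for p in (left, right) if p is not None)
            have_expr = set(expr.transcripts())
            gene_profiles = expression.profiles_for(
                expr, [g.id for g in annotation.genes if g.id in have_expr],
                config.pseudocount, config.detection_threshold,
            )
            all_profiles = {**lnc_profiles, **gene_profiles}
            corr = correlation.neighbor_correlation_table(
                all_profiles, pairs, mode=config.correlation_mode, expr=expr,
                pseudocount=config.pseudocount, strong_band=config.strong_band,
                alpha=config.alpha,
            )
            tables["correlation"] = corr
            tables["correlation_scatter"] = correlation.timepoint_scatter_table(
                all_profiles, pairs
            )
            report["counts"].update({
                "neighbor_pairs": len(corr),
                "strong_pairs": int(corr["strong"].sum()) if len(corr) else 0,
                "significant_pairs": int(corr["significant"].sum()) if len(corr) else 0,
                "fdr_significant_pairs": int((corr["q"] < config.alpha).sum())
                if len(corr) else 0,
            })
            if len(lnc_profiles) >= 2 and len(gene_profiles) >= 2:
                matrix, row_order, col_order = correlation.genome_wide_matrix(
                    lnc_profiles, gene_profiles
                )
                ordered = matrix.loc[row_order, col_order]
                ordered.index.name = "lncrna_id"
                tables["genome_wide_r"] = ordered.reset_index()
            report["stages"].append({"stage": "correlate",
                                     "mode": config.correlation_mode,
                                     "n_pairs": len(corr)})
            sig_genes = sorted(set(corr.loc[corr["significant"], "gene_id"])) \
                if len(corr) else []
        else:
            sig_genes = []
            report["skipped_stages"].append("correlate")

        # ---- enrichment -----------------------------------------------------
        current_stage = "enrich"
        if config.run_enrich and term_map is not None and sig_genes:
            # universe guard: genes with an expression profile
            if expr is not None:
                have_expr = set(expr.transcripts())
                universe = frozenset(
                    g.id for g in annotation.genes if g.id in have_expr
                ) & term_map.universe
                term_map = enrichment.TermMap(
                    terms={t: g & universe for t, g in term_map.terms.items()},
                    universe=universe,
                )
            result = enrichment.enrich(sig_genes, term_map, config.alpha)
            tables["enrichment"] = result
            report["counts"]["enriched_terms"] = int(result["significant"].sum())
            report["top_terms"] = result.head(3)["term"].tolist()
            report["stages"].append({"stage": "enrich",
                                     "n_query_genes": len(sig_genes)})
        else:
            report["skipped_stages"].append("enrich")

        # ---- outputs --------------------------------------------------------
        current_stage = "write_results"
        bed_scores = {}
        for c in calls:
            bed_scores[c.transcript_id] = float(np.max(np.abs(c.de)))
        paths = io_formats.write_results(tables, out_dir, lncrnas, bed_scores)
        report["outputs"] = {k: str(v) for k, v in sorted(paths.items())}
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {current_stage}\ncause: {exc}\n")
        raise PipelineStageError(current_stage, exc) from exc

    report_json = json.dumps(report, indent=2, sort_keys=True)
    (out_dir / "report.json").write_text(report_json + "\n")
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report
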