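"""Time-course differential expression, two-fold regulation calls, TML
classification and the stage-set partition.

The differential value at each time point is
``de[t] = log2((mean_mut FPKM + c) / (mean_wt FPKM + c))`` with replicate
means taken before the ratio and pseudocount ``c`` (default 1 FPKM) keeping
the ratio finite for transcripts undetectable in wild type.  A transcript is
up at a time point when de >= +1 (two-fold), down when de <= -1.  A TML
(telomerase-mutant lncRNA) is up in at least one time point and down in none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, TIME_POINT_LABELS, TIME_POINTS


@dataclass
class DifferentialProfile:
    transcript_id: str
    de: np.ndarray            # log2 ratios, one per time point
    detected: np.ndarray      # mutant mean FPKM >= detection threshold
    mut_means: np.ndarray
    wt_means: np.ndarray


@dataclass
class RegulationCall:
    transcript_id: str
    calls: list[str]          # per time point: "up" | "down" | "unchanged"
    de: np.ndarray
    is_differential: bool = False
    is_tml: bool = False
    up_timepoints: frozenset[int] = field(default_factory=frozenset)


def differential_profile(expr: ExpressionMatrix, transcript_id: str,
                         pseudocount: float = 1.0,
                         detection_threshold: float = 1.0) -> DifferentialProfile:
    """Per-time-point log2(mut/wt) profile from replicate-mean FPKM."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    means = expr.replicate_means(transcript_id)
    mut = means["mut"].to_numpy(dtype=float)
    wt = means["wt"].to_numpy(dtype=float)
    if pseudocount == 0 and (wt == 0).any():
        raise ValueError(
            f"transcript {transcript_id}: wild-type mean FPKM is 0 at some "
            "time point; use a positive pseudocount"
        )
    de = np.log2(mut + pseudocount) - np.log2(wt + pseudocount)
    return DifferentialProfile(
        transcript_id=transcript_id,
        de=de,
        detected=mut >= detection_threshold,
        mut_means=mut,
        wt_means=wt,
    )


def call_regulation(profile: DifferentialProfile, fold_threshold: float = 2.0) -> RegulationCall:
    """Threshold the profile into up/down/unchanged calls; up iff
    de >= log2(fold_threshold), down iff de <= -log2(fold_threshold)."""
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be > 0")
    cut = math.log2(fold_threshold)
    calls = []
    for v in profile.de:
        if v >= cut:
            calls.append("up")
        elif v <= -cut:
            calls.append("down")
        else:
            calls.append("unchanged")
    up_tps = frozenset(tp for tp, c in zip(TIME_POINTS, calls) if c == "up")
    call = RegulationCall(
        transcript_id=profile.transcript_id,
        calls=calls,
        de=profile.de,
        is_differential=any(c != "unchanged" for c in calls),
        up_timepoints=up_tps,
    )
    call.is_tml = classify_tml(call)
    return call


def classify_tml(call: RegulationCall) -> bool:
    """Up relative to wild type at >= 1 time point, down at none."""
    return ("up" in call.calls) and ("down" not in call.calls)


@dataclass
class StageSummary:
    """Stage-set partition of upregulated transcripts.

    senescence_stages / survivor_stage are configurable groupings of the five
    time points (defaults: early+late senescence; the final survivor stage).
    """

    memberships: dict[str, frozenset[int]]
    upregulated_anywhere: int
    multi_timepoint: int
    senescence_exclusive: int
    survivor_specific: int
    all_timepoints: int
    per_timepoint_counts: dict[int, int]


def stage_partition(calls: list[RegulationCall],
                    senescence_stages: tuple[int, ...] = (2, 3),
                    survivor_stages: tuple[int, ...] = (5,)) -> StageSummary:
    sen = frozenset(senescence_stages)
    surv = frozenset(survivor_stages)
    memberships = {c.transcript_id: c.up_timepoints for c in calls if c.up_timepoints}
    n_any = len(memberships)
    n_multi = sum(1 for m in memberships.values() if len(m) > 1)
    n_sen = sum(1 for m in memberships.values() if m and m <= sen)
    n_surv = sum(1 for m in memberships.values() if m == surv)
    n_all = sum(1 for m in memberships.values() if m == frozenset(TIME_POINTS))
    per_tp = {
        tp: sum(1 for m in memberships.values() if tp in m) for tp in TIME_POINTS
    }
    return StageSummary(
        memberships=memberships,
        upregulated_anywhere=n_any,
        multi_timepoint=n_multi,
        senescence_exclusive=n_sen,
        survivor_specific=n_surv,
        all_timepoints=n_all,
        per_timepoint_counts=per_tp,
    )


def profiles_for(expr: ExpressionMatrix, transcript_ids: list[str],
                 pseudocount: float = 1.0,
                 detection_threshold: float = 1.0) -> dict[str, DifferentialProfile]:
    return {
        tid: differential_profile(expr, tid, pseudocount, detection_threshold)
        for tid in transcript_ids
    }


def summary_stats(candidates, profiles: dict[str, DifferentialProfile]) -> dict:
    """Median candidate length and median of per-candidate median mutant FPKM
    across detected time points (transcripts never detected contribute
    nothing to the FPKM median)."""
    if not candidates:
        return {}
    lengths = [t.length for t in candidates]
    per_candidate_fpkm = []
    for t in candidates:
        prof = profiles.get(t.id)
        if prof is None or not prof.detected.any():
            continue
        per_candidate_fpkm.append(float(np.median(prof.mut_means[prof.detected])))
    return {
        "n_candidates": len(candidates),
        "median_length_nt": float(np.median(lengths)),
        "median_fpkm": float(np.median(per_candidate_fpkm)) if per_candidate_fpkm else float("nan"),
    }


def de_table(profiles: dict[str, DifferentialProfile]) -> pd.DataFrame:
    rows = [
        {"transcript_id": tid, **{f"de_t{tp}": prof.de[i] for i, tp in enumerate(TIME_POINTS)}}
        for tid, prof in sorted(profiles.items())
    ]
    return pd.DataFrame(rows)


def calls_table(calls: list[RegulationCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            **{f"call_t{tp}": c.calls[i] for i, tp in enumerate(TIME_POINTS)},
            "is_differential": c.is_differential,
            "is_tml": c.is_tml,
        }
        for c in sorted(calls, key=lambda c: c.transcript_id)
    ]
    return pd.DataFrame(rows)


def stage_summary_dict(summary: StageSummary) -> dict:
    return {
        "upregulated_anywhere": summary.upregulated_anywhere,
        "multi_timepoint": summary.multi_timepoint,
        "senescence_exclusive": summary.senescence_exclusive,
        "survivor_specific": summary.survivor_specific,
        "all_timepoints": summary.all_timepoints,
        "per_timepoint": {
            TIME_POINT_LABELS[tp]: n for tp, n in summary.per_timepoint_counts.items()
        },
    }
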