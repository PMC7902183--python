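"""End-to-end pipeline: simulate -> filter -> score -> group -> fit.

Chains the package's stages exactly as they would run on real visit data:
selection rules with audit, normative z-scoring against the HIV-negative
reference, last-visit quantile grouping, and one mixed-model trajectory fit
per outcome, collected into the study-style report table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_filters import FilterAudit, apply_filters
from .scoring import (CAT_Z_COMPONENTS, DEFAULT_DIRECTIONS, ReferenceNorms,
                      assign_groups, build_norms, global_scores, zscore_frame)
from .simulate import CohortParams, TruthRecord, generate_cohort
from .trajectory import ModelSpec, TrajectoryFit, build_report, fit_trajectory

__all__ = ["PipelineResult", "score_and_group", "run_pipeline",
            "DEFAULT_ANALYSIS_OUTCOMES"]

#: outcome columns fitted by default: raw CATs and MoCA, z-scored cognitive
#: measures, and the three global composites
DEFAULT_ANALYSIS_OUTCOMES = (
    "gap_ms", "hint_srt", "tdt_srt", "moca",
    "z_tova_rt", "z_tova_exg_mu", "z_tova_acs",
    "z_cs_groton_mps", "z_cs_groton_err", "z_cs_ocl_acc",
    "z_cs_oneback_rt", "z_cs_cpal_acc",
    "global_executive", "global_speed", "global_cat",
)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    kept: pd.DataFrame
    audit: FilterAudit
    norms: ReferenceNorms
    scored: pd.DataFrame
    groups: pd.DataFrame
    fits: dict[str, TrajectoryFit]
    report: pd.DataFrame
    truth: TruthRecord | None = None


def score_and_group(
    kept: pd.DataFrame,
    reference_visit_rule: str = "last",
    quantile_scope: str = "entire_cohort",
) -> tuple[pd.DataFrame, pd.DataFrame, ReferenceNorms]:
    """Z-score a filtered cohort, form composites, and assign study groups.

    Returns ``(scored, groups, norms)``: the visit table with ``z_*`` and
    global composite columns plus the assigned ``group`` label merged onto
    every visit, and the one-row-per-subject group table.
    """
    variables = [v for v in DEFAULT_DIRECTIONS if v in kept.columns]
    norms = build_norms(kept, variables, reference_visit_rule)
    scored = zscore_frame(kept, norms, variables)
    scored = global_scores(scored)

    last_idx = scored.groupby("subject_id")["visit_time"].idxmax()
    last = scored.loc[last_idx].copy()
    last["combo_cat_score"] = last[
        [f"z_{v}" for v in CAT_Z_COMPONENTS]
    ].mean(axis=1, skipna=False)
    groups = assign_groups(
        last[["subject_id", "hiv_status", "combo_cat_score", "visit_time"]],
        quantile_scope=quantile_scope,
    )
    scored = scored.merge(groups[["subject_id", "group"]], on="subject_id",
                          how="left")
    if "age_at_last_visit" not in scored.columns:
        age_last = scored.groupby("subject_id").apply(
            lambda s: s.loc[s["visit_time"].idxmax(), "age_at_visit"]
        )
        scored["age_at_last_visit"] = scored["subject_id"].map(age_last)
    return scored, groups, norms


def run_pipeline(
    params: CohortParams | None = None,
    seed: int = 0,
    outcomes: tuple[str, ...] = DEFAULT_ANALYSIS_OUTCOMES,
    cohort: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full chain on a synthetic (or supplied) cohort table."""
    truth = None
    if cohort is None:
        cohort, truth = generate_cohort(params, seed)
    kept, audit = apply_filters(cohort)
    scored, groups, norms = score_and_group(kept)
    analysed = scored[scored["group"].isin(
        ("HIV-negative", "HIV-positive", "TopCATs", "BottomCATs"))]
    fits: dict[str, TrajectoryFit] = {}
    for outcome in outcomes:
        if outcome not in analysed.columns:
            continue
        fits[outcome] = fit_trajectory(analysed, ModelSpec(outcome=outcome))
    report = build_report(fits)
    return PipelineResult(cohort, kept, audit, norms, scored, groups, fits,
                          report, truth)
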