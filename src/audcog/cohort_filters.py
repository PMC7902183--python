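"""Data-selection rules for the longitudinal cohort, with an audit trail.

Four rules are applied in a fixed order to a long-format visit table:

1. visits beyond the follow-up horizon (3.5 years) are dropped, so that a
   few long-followed subjects cannot leverage the trajectory models;
2. subjects left with fewer than four visits are excluded;
3. subjects with abnormal hearing sensitivity (> 25 dB HL at 0.5–4 kHz in
   either ear at any retained visit) or abnormal middle-ear function
   (tympanogram type outside {A, As, Ad}, peak pressure outside
   [−100, +50] daPa, or static admittance outside [0.3, 1.7] mmho) are
   excluded;
4. subjects with a positive history of ear drainage, concussion, noise or
   chemical exposure, neurological disease, mental illness, ototoxic
   antibiotics, or chemotherapy are excluded.

Because the horizon truncation runs first, a subject with four visits of
which one lies beyond the horizon is excluded; the audit attributes each
excluded subject to the first rule responsible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AUDIO_FREQS_HZ",
    "EARS",
    "HISTORY_FLAGS",
    "FilterAudit",
    "compute_pta",
    "add_pta",
    "apply_filters",
    "toy_filter_fixture",
]

AUDIO_FREQS_HZ = (500, 1000, 2000, 4000)
EARS = ("left", "right")
HISTORY_FLAGS = (
    "hx_ear_drainage",
    "hx_concussion",
    "hx_noise_or_chemical_exposure",
    "hx_neurological_disease",
    "hx_mental_illness",
    "hx_ototoxic_antibiotics",
    "hx_chemotherapy",
)
NORMAL_TYMP_TYPES = ("A", "As", "Ad")

DEFAULT_HORIZON_DAYS = 1278  # 3.5 years at 365.25 days/year
DEFAULT_MIN_VISITS = 4
HEARING_LIMIT_DB_HL = 25.0
TYMP_PRESSURE_DAPA = (-100.0, 50.0)
TYMP_ADMITTANCE_MMHO = (0.3, 1.7)


def threshold_columns() -> list[str]:
    return [f"thr_{ear}_{f}" for ear in EARS for f in AUDIO_FREQS_HZ]


def compute_pta(thresholds) -> float:
    """Pure tone average: mean of the 0.5/1/2/4 kHz thresholds for one ear.

    A missing frequency yields a missing PTA.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (4,):
        raise ValueError("expected four thresholds (0.5, 1, 2, 4 kHz)")
    if np.any(~np.isfinite(t)):
        return float("nan")
    return float(np.mean(t))


def add_pta(df: pd.DataFrame) -> pd.DataFrame:
    """Add per-ear ``pta_left`` / ``pta_right`` columns (NaN-propagating)."""
    out = df.copy()
    for ear in EARS:
        cols = [f"thr_{ear}_{f}" for f in AUDIO_FREQS_HZ]
        out[f"pta_{ear}"] = df[cols].mean(axis=1, skipna=False)
    return out


@dataclass
class FilterAudit:
    """Per-rule exclusion counts; retained + excluded = input subjects."""

    n_input_subjects: int = 0
    n_retained_subjects: int = 0
    visits_dropped_beyond_horizon: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)  # subject -> rule

    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_input_subjects": self.n_input_subjects,
                "n_retained_subjects": self.n_retained_subjects,
                "visits_dropped_beyond_horizon": self.visits_dropped_beyond_horizon,
                "excluded": self.excluded,
                "reasons": self.reasons,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


_RULES = (
    "horizon_truncation",
    "min_visits",
    "hearing_or_middle_ear",
    "missing_tympanometry",
    "medical_history",
)


def _tymp_abnormal(sub: pd.DataFrame) -> str | None:
    """Middle-ear / hearing screen on a subject's retained visits."""
    thr = sub[threshold_columns()]
    if thr.isna().any().any() or (thr > HEARING_LIMIT_DB_HL).any().any():
        # a missing audiometric threshold cannot certify normal hearing
        return "hearing_or_middle_ear"
    tymp = sub[["tymp_type", "tymp_pressure_dapa", "tymp_admittance_mmho"]]
    if tymp.isna().any().any():
        return "missing_tympanometry"
    if (~sub["tymp_type"].isin(NORMAL_TYMP_TYPES)).any():
        return "hearing_or_middle_ear"
    lo, hi = TYMP_PRESSURE_DAPA
    if ((sub["tymp_pressure_dapa"] < lo) | (sub["tymp_pressure_dapa"] > hi)).any():
        return "hearing_or_middle_ear"
    lo, hi = TYMP_ADMITTANCE_MMHO
    if ((sub["tymp_admittance_mmho"] < lo) | (sub["tymp_admittance_mmho"] > hi)).any():
        return "hearing_or_middle_ear"
    return None


def apply_filters(
    cohort: pd.DataFrame,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    min_visits: int = DEFAULT_MIN_VISITS,
    history_scope: str = "any_visit",
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the four selection rules in order; return (kept, audit).

    ``history_scope`` selects whether medical-history flags are assessed over
    every visit (default) or at baseline only.  Visits must be sorted by
    ``visit_time`` within subject.  Idempotent: re-filtering a filtered
    cohort changes nothing.
    """
    if history_scope not in ("any_visit", "baseline"):
        raise ValueError("history_scope: any_visit|baseline")
    audit = FilterAudit(excluded={r: 0 for r in _RULES})
    if cohort.empty:
        return cohort.copy(), audit
    grp_times = cohort.groupby("subject_id", sort=False)["visit_time"]
    if not grp_times.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("visits must be sorted by visit_time within subject")

    audit.n_input_subjects = cohort["subject_id"].nunique()
    n_before = cohort.groupby("subject_id")["visit_time"].size()

    # rule 1: horizon truncation (visit-level)
    within = cohort[cohort["visit_time"] <= horizon_days].copy()
    audit.visits_dropped_beyond_horizon = len(cohort) - len(within)
    n_after = within.groupby("subject_id")["visit_time"].size().reindex(
        n_before.index, fill_value=0
    )

    # rule 2: visit-count requirement (subject-level); subjects pushed under
    # the minimum by the truncation are attributed to the horizon rule
    for sid in n_before.index:
        if n_after[sid] < min_visits:
            rule = (
                "horizon_truncation"
                if n_before[sid] >= min_visits
                else "min_visits"
            )
            audit.excluded[rule] += 1
            audit.reasons[str(sid)] = rule
    keep_ids = [s for s in n_before.index if str(s) not in audit.reasons]
    within = within[within["subject_id"].isin(keep_ids)]

    # rule 3: hearing sensitivity and middle-ear function, any retained visit
    for sid, sub in within.groupby("subject_id", sort=False):
        reason = _tymp_abnormal(sub)
        if reason is not None:
            audit.excluded[reason] += 1
            audit.reasons[str(sid)] = reason
    within = within[~within["subject_id"].astype(str).isin(audit.reasons)]

    # rule 4: medical-history flags
    for sid, sub in within.groupby("subject_id", sort=False):
        flags = sub[list(HISTORY_FLAGS)]
        if history_scope == "baseline":
            flags = flags.iloc[[0]]
        if flags.fillna(False).any().any():
            audit.excluded["medical_history"] += 1
            audit.reasons[str(sid)] = "medical_history"
    kept = within[~within["subject_id"].astype(str).isin(audit.reasons)].copy()

    audit.n_retained_subjects = kept["subject_id"].nunique()
    return kept.reset_index(drop=True), audit


def toy_filter_fixture() -> pd.DataFrame:
    """Six-subject cohort exercising one rule each, plus two clean subjects.

    * F1 — four visits, the last beyond the horizon (excluded by truncation);
    * F2 — three visits only (excluded by the visit-count rule);
    * F3 — one 30 dB HL audiometric threshold (excluded by the hearing rule);
    * F4 — a concussion history flag (excluded by the history rule);
    * K1, K2 — clean, retained.
    """
    rows = []
    visit_plans = {
        "F1": [0, 182, 364, 1350],
        "F2": [0, 182, 364],
        "F3": [0, 182, 364, 546],
        "F4": [0, 182, 364, 546],
        "K1": [0, 182, 364, 546, 728],
        "K2": [0, 182, 364, 546],
    }
    for sid, times in visit_plans.items():
        for j, t in enumerate(times):
            row = {
                "subject_id": sid,
                "hiv_status": "positive" if sid != "K2" else "negative",
                "visit_time": t,
                "age_at_visit": 40.0 + t / 365.25,
                "tymp_type": "A",
                "tymp_pressure_dapa": -10.0,
                "tymp_admittance_mmho": 0.9,
            }
            for col in threshold_columns():
                row[col] = 10.0
            for flag in HISTORY_FLAGS:
                row[flag] = False
            if sid == "F3" and j == 1:
                row["thr_right_2000"] = 30.0
            if sid == "F4" and j == 2:
                row["hx_concussion"] = True
            rows.append(row)
    return pd.DataFrame(rows)
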