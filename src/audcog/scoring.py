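"""Normative z-scoring, the combination CAT score, quantile group
assignment, and the three global composite scores.

The HIV-negative subjects serve as the normative reference: every central
auditory and cognitive variable is standardized against their mean and SD,
with a sign flip for variables where lower raw values mean better
performance (thresholds, SRTs, response times, error counts), so that a
higher z is always better.  HIV-positive subjects are then split on the
unweighted mean of the three CAT z-scores at their last retained visit:
those at or below the entire cohort's 0.20 quantile form "BottomCATs",
those at or above the 0.80 quantile form "TopCATs", and the rest remain
"HIV-positive".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CAT_Z_COMPONENTS",
    "DEFAULT_DIRECTIONS",
    "EXECUTIVE_COMPONENTS",
    "SPEED_COMPONENTS",
    "GROUPS",
    "ReferenceNorms",
    "build_norms",
    "zscore",
    "zscore_frame",
    "combination_cat_score",
    "assign_groups",
    "global_scores",
]

GROUPS = ("HIV-negative", "HIV-positive", "TopCATs", "BottomCATs")

#: raw-variable performance directions; lower_better variables are
#: sign-flipped after standardization
DEFAULT_DIRECTIONS: dict[str, str] = {
    "gap_ms": "lower_better",
    "hint_srt": "lower_better",
    "tdt_srt": "lower_better",
    "moca": "higher_better",
    "tova_rt": "lower_better",
    "tova_exg_mu": "lower_better",
    "tova_acs": "higher_better",
    "cs_groton_mps": "higher_better",
    "cs_groton_err": "lower_better",
    "cs_ocl_acc": "higher_better",
    "cs_oneback_rt": "lower_better",
    "cs_cpal_acc": "higher_better",
}

CAT_Z_COMPONENTS = ("gap_ms", "hint_srt", "tdt_srt")
#: Cogstate subtests except the One Back Test
EXECUTIVE_COMPONENTS = ("cs_groton_mps", "cs_groton_err", "cs_ocl_acc",
                        "cs_cpal_acc")
#: TOVA speed measures plus the One Back Test; the attention comparison
#: score enters no composite and is analyzed standalone
SPEED_COMPONENTS = ("tova_rt", "tova_exg_mu", "cs_oneback_rt")


@dataclass
class ReferenceNorms:
    """Per-variable mean/SD from the HIV-negative reference sample."""

    mean: dict[str, float]
    sd: dict[str, float]
    direction: dict[str, str]
    reference_visit_rule: str = "last"
    unnormable: list[str] = field(default_factory=list)

    def variables(self) -> list[str]:
        return list(self.mean)


def _reference_rows(
    cohort: pd.DataFrame, rule: str
) -> pd.DataFrame:
    neg = cohort[cohort["hiv_status"] == "negative"]
    take = {"last": "idxmax", "baseline": "idxmin"}[rule]
    idx = neg.groupby("subject_id")["visit_time"].agg(take)
    return neg.loc[idx]


def build_norms(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] | list[str] | None = None,
    reference_visit_rule: str = "last",
    directions: dict[str, str] | None = None,
) -> ReferenceNorms:
    """Mean/SD per variable over HIV-negative subjects' reference visits.

    The reference visit defaults to each HIV-negative subject's last
    retained visit, matching the visit used for group assignment; a
    ``baseline`` rule is available.  Constant variables are flagged
    un-normable rather than silently dividing by zero.
    """
    if reference_visit_rule not in ("last", "baseline"):
        raise ValueError("reference_visit_rule: last|baseline")
    variables = list(variables or DEFAULT_DIRECTIONS)
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    ref = _reference_rows(cohort, reference_visit_rule)
    if ref["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 HIV-negative subjects to build norms")
    norms = ReferenceNorms({}, {}, {}, reference_visit_rule)
    for var in variables:
        vals = ref[var].dropna().to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else 0.0
        if sd <= 0:
            norms.unnormable.append(var)
            continue
        norms.mean[var] = float(np.mean(vals))
        norms.sd[var] = sd
        norms.direction[var] = directions.get(var, "higher_better")
    return norms


def zscore(value: float, norms: ReferenceNorms, variable: str) -> float:
    """Direction-harmonized z-score of one value (higher z = better)."""
    if variable in norms.unnormable or variable not in norms.mean:
        raise ValueError(f"variable {variable!r} is not normable")
    z = (value - norms.mean[variable]) / norms.sd[variable]
    if norms.direction[variable] == "lower_better":
        z = -z
    return z


def zscore_frame(
    df: pd.DataFrame, norms: ReferenceNorms,
    variables: list[str] | None = None, prefix: str = "z_",
) -> pd.DataFrame:
    """Add ``z_<var>`` columns for every normable variable (NaN propagates)."""
    out = df.copy()
    for var in variables or norms.variables():
        sign = -1.0 if norms.direction[var] == "lower_better" else 1.0
        out[prefix + var] = sign * (df[var] - norms.mean[var]) / norms.sd[var]
    return out


def combination_cat_score(z_gap: float, z_hint: float, z_tdt: float) -> float:
    """Unweighted mean of the three CAT z-scores; NaN if any is missing."""
    vals = np.array([z_gap, z_hint, z_tdt], dtype=float)
    if np.any(~np.isfinite(vals)):
        return float("nan")
    return float(np.mean(vals))


def assign_groups(
    last_visit: pd.DataFrame,
    quantile_scope: str = "entire_cohort",
    q_low: float = 0.20,
    q_high: float = 0.80,
) -> pd.DataFrame:
    """Assign the four study groups from last-visit combination CAT scores.

    ``last_visit`` needs one row per subject with columns
    (subject_id, hiv_status, combo_cat_score, visit_time).  Cut-points are
    the empirical 0.20/0.80 quantiles (linear interpolation) over the whole
    cohort's scores by default (``quantile_scope="hiv_positive"`` restricts
    them to HIV-positive subjects).  HIV-positive subjects at or below the
    low cut become BottomCATs, at or above the high cut TopCATs; HIV-negative
    subjects keep their serostatus label.  Subjects lacking a combination
    score are returned with group ``"ungrouped"`` and never enter the
    cut-points.
    """
    if quantile_scope not in ("entire_cohort", "hiv_positive"):
        raise ValueError("quantile_scope: entire_cohort|hiv_positive")
    df = last_visit.copy()
    if df["subject_id"].duplicated().any():
        raise ValueError("one row per subject required")
    scored = df[np.isfinite(df["combo_cat_score"].astype(float))]
    if len(scored) < 10:
        raise ValueError("refusing to group fewer than 10 scored subjects")
    pool = scored if quantile_scope == "entire_cohort" else scored[
        scored["hiv_status"] == "positive"
    ]
    lo, hi = np.quantile(pool["combo_cat_score"].to_numpy(float),
                         [q_low, q_high])
    if lo == hi:
        warnings.warn("degenerate combination-score distribution: "
                      "quantile cut-points coincide", stacklevel=2)

    def label(row) -> str:
        if not np.isfinite(row["combo_cat_score"]):
            return "ungrouped"
        if row["hiv_status"] == "negative":
            return "HIV-negative"
        if row["combo_cat_score"] <= lo:
            return "BottomCATs"
        if row["combo_cat_score"] >= hi:
            return "TopCATs"
        return "HIV-positive"

    out = df[["subject_id", "hiv_status", "combo_cat_score"]].copy()
    out["group"] = df.apply(label, axis=1)
    out["last_visit_time"] = df["visit_time"].to_numpy()
    out.attrs["cut_points"] = (float(lo), float(hi))
    return out.reset_index(drop=True)


def global_scores(
    zdf: pd.DataFrame, max_missing_frac: float = 0.5, prefix: str = "z_"
) -> pd.DataFrame:
    """Per-visit global executive, speed and CAT composite scores.

    Each composite is the mean of its direction-harmonized component
    z-scores; a composite with more than ``max_missing_frac`` of its
    components missing is itself missing.
    """
    out = zdf.copy()
    comps = {
        "global_executive": EXECUTIVE_COMPONENTS,
        "global_speed": SPEED_COMPONENTS,
        "global_cat": CAT_Z_COMPONENTS,
    }
    for name, components in comps.items():
        cols = [prefix + c for c in components]
        block = out[cols]
        frac_missing = block.isna().mean(axis=1)
        vals = block.mean(axis=1)
        vals[frac_missing > max_missing_frac] = np.nan
        out[name] = vals
    return out
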