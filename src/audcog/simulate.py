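"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the trajectory analysis assumes: four
latent groups (HIV-negative, HIV-positive, TopCATs, BottomCATs) of sizes
90/164/53/75, six-monthly visits with jitter and geometric dropout over a
3.5-year horizon, a positive learning effect in most groups with a
flat-to-declining BottomCATs subgroup, cross-sectional age effects,
correlated per-subject random intercepts and time slopes, and Gaussian
residuals.  Central-auditory outcomes can either be drawn directly from the
generative trajectory equation or produced by actually running the adaptive
test simulators against per-subject virtual listeners whose latent
thresholds follow those trajectories.

Every generated cohort is accompanied by a :class:`TruthRecord` holding the
latent groups, random effects and generating coefficients, so that recovery
can be tested end to end.  All randomness flows from a single master seed
split into named streams (ages, visits, outcomes, listeners).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adaptive_tests as at
from .cohort_filters import HISTORY_FLAGS, threshold_columns
from .listeners import PsychometricListener, make_gap_listener
from .scoring import DEFAULT_DIRECTIONS, GROUPS

__all__ = ["OutcomeSpec", "CohortParams", "TruthRecord",
           "generate_visits", "generate_outcomes", "generate_cohort",
           "generate_cat_raw"]


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative coefficients for one outcome, in its raw units.

    ``slope`` maps group -> units/day; random-effect SDs are the subject
    intercept SD (units) and slope SD (units/day) with correlation
    ``re_corr``; ``age_coef`` is units per year of age (centred at 40).
    """

    name: str
    intercept: float
    slope: dict[str, float]
    group_offset: dict[str, float]
    age_coef: float
    re_sd_intercept: float
    re_sd_slope: float
    re_corr: float
    resid_sd: float
    direction: str = "higher_better"

    def __post_init__(self) -> None:
        if self.re_sd_intercept < 0 or self.re_sd_slope < 0 or self.resid_sd < 0:
            raise ValueError("SDs must be nonnegative")
        if not -1.0 < self.re_corr < 1.0:
            raise ValueError("re_corr must be in (-1, 1)")


def _z_outcome(
    name: str,
    intercept: float,
    scale: float,
    z_offsets: dict[str, float],
    z_learning: float = 4e-4,
    z_bottom_slope: float = -1e-4,
    z_top_learning: float = 4.5e-4,
    z_age_per_year: float = -0.02,
    z_re_sd_intercept: float = 0.8,
    z_re_sd_slope: float = 5e-4,
    re_corr: float = -0.2,
    z_resid_sd: float = 0.5,
) -> OutcomeSpec:
    """Build an OutcomeSpec from effect sizes on the performance-z scale.

    A positive z-slope always means improvement; the sign flip for
    lower-is-better raw variables (thresholds, SRTs, response times, error
    counts) is applied here so raw units keep their natural direction.
    """
    direction = DEFAULT_DIRECTIONS[name]
    s = scale if direction == "higher_better" else -scale
    z_slopes = {
        "HIV-negative": z_learning,
        "HIV-positive": z_learning,
        "TopCATs": z_top_learning,
        "BottomCATs": z_bottom_slope,
    }
    return OutcomeSpec(
        name=name,
        intercept=intercept,
        slope={g: z * s for g, z in z_slopes.items()},
        group_offset={g: z * s for g, z in z_offsets.items()},
        age_coef=z_age_per_year * s,
        re_sd_intercept=z_re_sd_intercept * scale,
        re_sd_slope=z_re_sd_slope * scale,
        re_corr=re_corr,
        resid_sd=z_resid_sd * scale,
        direction=direction,
    )


#: baseline separation of the latent groups on the performance-z scale;
#: CAT variables separate TopCATs/BottomCATs by well over one reference SD
#: so that last-visit quantile grouping can recover the latent labels
_CAT_OFFSETS = {"HIV-negative": 0.2, "HIV-positive": 0.0,
                "TopCATs": 1.3, "BottomCATs": -1.3}
_COG_OFFSETS = {"HIV-negative": 0.2, "HIV-positive": 0.0,
                "TopCATs": 0.3, "BottomCATs": -0.4}


def default_outcomes() -> dict[str, OutcomeSpec]:
    """Default generative settings for the twelve visit-level outcomes."""
    specs = [
        _z_outcome("gap_ms", 6.0, 1.5, _CAT_OFFSETS),
        _z_outcome("hint_srt", -3.0, 1.2, _CAT_OFFSETS),
        _z_outcome("tdt_srt", -9.0, 1.5, _CAT_OFFSETS),
        _z_outcome("moca", 27.0, 2.5, _COG_OFFSETS),
        _z_outcome("tova_rt", 420.0, 45.0, _COG_OFFSETS),
        _z_outcome("tova_exg_mu", 350.0, 40.0, _COG_OFFSETS),
        _z_outcome("tova_acs", 0.0, 1.5, _COG_OFFSETS),
        _z_outcome("cs_groton_mps", 0.55, 0.15, _COG_OFFSETS),
        _z_outcome("cs_groton_err", 55.0, 12.0, _COG_OFFSETS),
        _z_outcome("cs_ocl_acc", 0.85, 0.08, _COG_OFFSETS),
        _z_outcome("cs_oneback_rt", 750.0, 60.0, _COG_OFFSETS),
        _z_outcome("cs_cpal_acc", 0.80, 0.10, _COG_OFFSETS),
    ]
    return {s.name: s for s in specs}


@dataclass
class CohortParams:
    """Study-design parameters of the synthetic cohort.

    Group sizes and age distributions mirror the demographic table of the
    cohort being emulated (90/164/53/75 subjects); visits fall every ~182
    days with Gaussian jitter, truncated at the 3.5-year horizon, with a
    constant per-visit dropout hazard.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "HIV-negative": 90, "HIV-positive": 164,
        "TopCATs": 53, "BottomCATs": 75,
    })
    age_mean_sd: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "HIV-negative": (25.9, 11.8), "HIV-positive": (40.8, 13.6),
        "TopCATs": (38.1, 12.8), "BottomCATs": (42.1, 8.4),
    })
    age_range: tuple[float, float] = (18.0, 70.0)
    visit_interval_days: float = 182.0
    visit_jitter_sd_days: float = 14.0
    min_interval_days: float = 90.0
    horizon_days: float = 1278.0
    dropout_hazard: float = 0.06
    outcomes: dict[str, OutcomeSpec] = field(default_factory=default_outcomes)
    #: psychometric slopes of the virtual listeners used in adaptive-CAT mode
    listener_slopes: dict[str, float] = field(default_factory=lambda: {
        "gap": 6.0, "hint": 1.5, "tdt": 0.8,
    })

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_hazard <= 1.0:
            raise ValueError("dropout_hazard must be in [0, 1]")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth persisted alongside a generated cohort."""

    true_group: dict[str, str]
    age: dict[str, float]
    random_effects: dict[str, dict[str, tuple[float, float]]]  # sid -> outcome -> (b0, b1)
    coefficients: dict[str, dict]
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "true_group": self.true_group,
                "age": self.age,
                "random_effects": self.random_effects,
                "coefficients": self.coefficients,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("ages", "visits", "outcomes", "listeners", "clinical")
    return {n: np.random.default_rng(s)
            for n, s in zip(names, root.spawn(len(names)))}


def generate_visits(
    params: CohortParams, rng: np.random.Generator, n_subjects: int
) -> list[np.ndarray]:
    """Visit-day schedules: first visit at day 0, then ~6-month intervals.

    Each subsequent visit happens only if the subject survives a geometric
    dropout draw and the jittered time still lies within the horizon; every
    subject keeps at least the baseline visit.
    """
    schedules = []
    for _ in range(n_subjects):
        times = [0.0]
        while True:
            if rng.random() < params.dropout_hazard:
                break
            jitter = (rng.normal(0.0, params.visit_jitter_sd_days)
                      if params.visit_jitter_sd_days > 0 else 0.0)
            step = max(params.visit_interval_days + jitter,
                       params.min_interval_days)
            nxt = times[-1] + step
            if nxt > params.horizon_days:
                break
            times.append(round(nxt))
        schedules.append(np.asarray(times, dtype=float))
    return schedules


def expected_visits(params: CohortParams) -> float:
    """Closed-form mean visit count with zero jitter (geometric dropout)."""
    k_max = int(params.horizon_days // params.visit_interval_days) + 1
    q = 1.0 - params.dropout_hazard
    return float(sum(q**k for k in range(k_max)))


def generate_outcomes(
    subjects: pd.DataFrame,
    schedules: list[np.ndarray],
    params: CohortParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, dict[str, tuple[float, float]]]]:
    """Draw every outcome from the generative trajectory equation.

    ``subjects`` has one row per subject with (subject_id, true_group, age).
    Returns the long visit table and the per-subject random effects.
    """
    rows = []
    re_record: dict[str, dict[str, tuple[float, float]]] = {}
    for (_, subj), times in zip(subjects.iterrows(), schedules):
        sid, grp, age0 = subj["subject_id"], subj["true_group"], subj["age"]
        age_last = age0 + times[-1] / 365.25
        re_record[sid] = {}
        draws: dict[str, np.ndarray] = {}
        for name, spec in params.outcomes.items():
            cov = np.array([
                [spec.re_sd_intercept**2,
                 spec.re_corr * spec.re_sd_intercept * spec.re_sd_slope],
                [spec.re_corr * spec.re_sd_intercept * spec.re_sd_slope,
                 spec.re_sd_slope**2],
            ])
            b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
            re_record[sid][name] = (float(b0), float(b1))
            mean = (spec.intercept + spec.group_offset[grp]
                    + spec.age_coef * (age_last - 40.0) + b0)
            slope = spec.slope[grp] + b1
            eps = rng.normal(0.0, spec.resid_sd, len(times))
            draws[name] = mean + slope * times + eps
        for j, t in enumerate(times):
            row = {
                "subject_id": sid,
                "hiv_status": "negative" if grp == "HIV-negative" else "positive",
                "true_group": grp,
                "visit_time": float(t),
                "visit_number": j,
                "age_at_visit": age0 + t / 365.25,
                "age_at_last_visit": age_last,
            }
            for name in params.outcomes:
                row[name] = float(draws[name][j])
            rows.append(row)
    return pd.DataFrame(rows), re_record


def _clinical_columns(
    df: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Normal-range audiometry, tympanometry and clean history flags.

    Defaults keep every subject inside the selection rules, so the filter
    stage is exercised without shrinking the designed group sizes; abnormal
    subjects can be injected by editing the returned columns.
    """
    out = df.copy()
    n = len(out)
    for col in threshold_columns():
        out[col] = np.clip(rng.normal(7.0, 4.0, n), -10.0, 24.0).round(0)
    out["tymp_type"] = "A"
    out["tymp_pressure_dapa"] = np.clip(rng.normal(-10.0, 25.0, n),
                                        -95.0, 45.0).round(0)
    out["tymp_admittance_mmho"] = np.clip(rng.normal(0.9, 0.25, n),
                                          0.35, 1.65).round(2)
    for flag in HISTORY_FLAGS:
        out[flag] = False
    return out


def generate_cohort(
    params: CohortParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a full synthetic cohort table plus its ground truth."""
    params = params or CohortParams()
    streams = _streams(seed)
    subj_rows = []
    i = 0
    for grp in GROUPS:
        mean, sd = params.age_mean_sd[grp]
        for _ in range(params.group_sizes.get(grp, 0)):
            age = float(np.clip(streams["ages"].normal(mean, sd),
                                *params.age_range))
            subj_rows.append({"subject_id": f"S{i:04d}", "true_group": grp,
                              "age": age})
            i += 1
    subjects = pd.DataFrame(subj_rows)
    schedules = generate_visits(params, streams["visits"], len(subjects))
    cohort, re_record = generate_outcomes(subjects, schedules, params,
                                          streams["outcomes"])
    cohort = _clinical_columns(cohort, streams["clinical"])
    truth = TruthRecord(
        true_group=dict(zip(subjects["subject_id"], subjects["true_group"])),
        age=dict(zip(subjects["subject_id"], subjects["age"])),
        random_effects=re_record,
        coefficients={n: asdict(s) for n, s in params.outcomes.items()},
        seed=seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Raw CAT scores via the adaptive-test simulators
# ---------------------------------------------------------------------------


def generate_cat_raw(
    cohort: pd.DataFrame,
    params: CohortParams | None = None,
    seed: int = 0,
    mode: str = "stochastic",
) -> pd.DataFrame:
    """Replace the directly simulated CAT columns with staircase estimates.

    Each subject-visit's latent CAT values (``gap_ms``, ``hint_srt``,
    ``tdt_srt``) become the thresholds of virtual listeners; the adaptive
    procedures are then actually run and their track estimates written back.
    With ``mode="deterministic_step"`` the listeners are ideal step-function
    observers and the estimates land within one step of the latent values.
    Non-converged tracks yield a missing score.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    slopes = params.listener_slopes
    out = cohort.copy()
    gap_est, hint_est, tdt_est = [], [], []
    for _, row in cohort.iterrows():
        gap_l = make_gap_listener(max(float(row["gap_ms"]), 1.0),
                                  slope_per_octave=slopes["gap"], mode=mode)
        tr = at.run_gap_staircase(gap_l, at.GapConfig(), rng)
        gap_est.append(tr.estimate if tr.converged else math.nan)

        hint_l = PsychometricListener(float(row["hint_srt"]),
                                      slope=slopes["hint"], mode=mode)
        srts = [
            at.run_hint_condition(hint_l, at.HintConfig(), cond, rng).estimate
            for cond in ("noise_front", "noise_right", "noise_left")
        ]
        hint_est.append(at.hint_composite(*srts))

        tdt_l = PsychometricListener(float(row["tdt_srt"]),
                                     slope=slopes["tdt"], guess_rate=0.1,
                                     mode=mode)
        tr = at.run_tdt(tdt_l, at.TdtConfig(), rng)
        tdt_est.append(tr.estimate if tr.converged else math.nan)
    out["gap_ms"] = gap_est
    out["hint_srt"] = hint_est
    out["tdt_srt"] = tdt_est
    return out
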