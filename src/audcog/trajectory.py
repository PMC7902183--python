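"""Linear mixed-effects trajectory analysis of longitudinal outcomes.

For one outcome y observed at visit j of subject i, the model is

    y_ij = b0 + b_g 1[group_i=g] + b_a age_i + b_t t_ij
           + b_tg (t_ij x group_i) + b_ag (age_i x group_i)
           + u0_i + u1_i t_ij + e_ij

with time t in days from each subject's first visit, age fixed at the
subject's age at their last visit, subject random intercepts and time
slopes with a free 2x2 covariance, and independent residuals.  The
HIV-positive group is the reference: its time slope is b_t and every other
group's slope is b_t plus its time-by-group interaction.  Inference uses
large-sample Wald z statistics on the (restricted) maximum-likelihood fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["ModelSpec", "TrajectoryFit", "fit_trajectory",
           "test_interaction", "build_report", "read_report"]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome column, grouping, and estimation options."""

    outcome: str
    reference_group: str = "HIV-positive"
    group_col: str = "group"
    time_col: str = "visit_time"
    age_col: str = "age_at_last_visit"
    subject_col: str = "subject_id"
    random_effects: str = "intercept_slope"  # intercept_slope|intercept|none
    reml: bool = True
    #: days per internal model time unit; fitting on a years-like scale keeps
    #: the random-slope variance well conditioned, slopes are reported per day
    time_scale: float = 365.25

    def __post_init__(self) -> None:
        if self.random_effects not in ("intercept_slope", "intercept", "none"):
            raise ValueError("random_effects: intercept_slope|intercept|none")


@dataclass
class TrajectoryFit:
    """Fixed effects, interaction tests and random-effect variances."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    group_slopes: dict[str, float]        # outcome units per day
    group_slope_se: dict[str, float]
    random_effect_cov: pd.DataFrame | None
    resid_var: float
    converged: bool
    singular_fallback: bool
    n_subjects: int
    n_obs: int
    loglik: float
    groups: tuple[str, ...] = ()

    def interaction(self, term: str, group: str):
        return test_interaction(self, term, group)


def _design(df: pd.DataFrame, spec: ModelSpec):
    """Fixed-effects design with explicit, readable column names."""
    groups = [g for g in pd.unique(df[spec.group_col]) if g == g]
    if spec.reference_group not in groups:
        raise ValueError(
            f"reference group {spec.reference_group!r} absent from data"
        )
    nonref = [g for g in sorted(map(str, groups)) if g != spec.reference_group]
    t = df[spec.time_col].to_numpy(float) / spec.time_scale
    age = df[spec.age_col].to_numpy(float)
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    for g in nonref:
        X[f"group[{g}]"] = (df[spec.group_col].astype(str) == g).astype(float)
    X["age"] = age
    X["time"] = t
    for g in nonref:
        X[f"time:group[{g}]"] = t * X[f"group[{g}]"]
    for g in nonref:
        X[f"age:group[{g}]"] = age * X[f"group[{g}]"]
    return X, nonref


def fit_trajectory(df: pd.DataFrame, spec: ModelSpec) -> TrajectoryFit:
    """Fit the trajectory model for one outcome.

    Rows with a missing outcome are dropped.  A singular random-effects
    covariance triggers an automatic refit with a random intercept only
    (``singular_fallback=True``); outright non-convergence is flagged.
    With ``random_effects="none"`` the model degenerates to ordinary least
    squares on the same fixed-effects design, which serves as the
    closed-form anchor for the mixed fit.
    """
    cols = [spec.outcome, spec.group_col, spec.time_col, spec.age_col,
            spec.subject_col]
    data = df[cols].dropna(subset=[spec.outcome, spec.age_col]).copy()
    y = data[spec.outcome].to_numpy(float)
    X, nonref = _design(data, spec)
    subjects = data[spec.subject_col].to_numpy()

    if spec.random_effects == "none":
        import statsmodels.api as sm

        res = sm.OLS(y, X).fit()
        cov = pd.DataFrame(res.cov_params(), index=X.columns,
                           columns=X.columns)
        return _collect(spec, res.params, res.bse, cov, nonref,
                        None, float(res.mse_resid), True, False,
                        len(np.unique(subjects)), len(y), float(res.llf))

    def _mixed(re_formula_cols: list[str]):
        exog_re = X[re_formula_cols]
        model = MixedLM(y, X, groups=subjects, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for methods in (["lbfgs", "powell"], ["cg"], ["nm"]):
                try:
                    return model.fit(reml=spec.reml, method=methods)
                except np.linalg.LinAlgError:
                    continue  # singular Hessian at this optimum path
        return None

    re_cols = (["Intercept", "time"]
               if spec.random_effects == "intercept_slope" else ["Intercept"])
    res = _mixed(re_cols)
    singular = False
    if res is not None and len(re_cols) == 2:
        cov_re = np.asarray(res.cov_re)
        eig = np.linalg.eigvalsh(cov_re)
        if not res.converged or eig.min() <= 1e-12 * max(eig.max(), 1e-300):
            res2 = _mixed(["Intercept"])
            if res2 is not None and res2.converged:
                res, singular, re_cols = res2, True, ["Intercept"]
    elif res is None and len(re_cols) == 2:
        res = _mixed(["Intercept"])
        if res is not None:
            singular, re_cols = True, ["Intercept"]
    if res is None:
        raise RuntimeError(
            f"mixed model for {spec.outcome!r} failed to fit under every "
            "optimizer; no estimates available"
        )
    converged = bool(res.converged)
    params = pd.Series(np.asarray(res.fe_params), index=X.columns)
    bse = pd.Series(np.asarray(res.bse_fe), index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params())[: len(X.columns),
                                                    : len(X.columns)],
                       index=X.columns, columns=X.columns)
    cov_re = pd.DataFrame(np.asarray(res.cov_re),
                          index=re_cols, columns=re_cols)
    return _collect(spec, params, bse, cov, nonref, cov_re,
                    float(res.scale), converged, singular,
                    len(np.unique(subjects)), len(y), float(res.llf))


def _collect(spec, params, bse, cov, nonref, cov_re, resid_var, converged,
             singular, n_subj, n_obs, llf) -> TrajectoryFit:
    params = pd.Series(np.asarray(params), index=cov.index)
    bse = pd.Series(np.asarray(bse), index=cov.index)
    slopes = {spec.reference_group: params["time"] / spec.time_scale}
    slope_se = {spec.reference_group: bse["time"] / spec.time_scale}
    for g in nonref:
        k = f"time:group[{g}]"
        slopes[g] = (params["time"] + params[k]) / spec.time_scale
        var = cov.loc["time", "time"] + cov.loc[k, k] + 2 * cov.loc["time", k]
        slope_se[g] = float(np.sqrt(max(var, 0.0))) / spec.time_scale
    return TrajectoryFit(
        spec=spec, params=params, bse=bse, cov_params=cov,
        group_slopes=slopes, group_slope_se=slope_se,
        random_effect_cov=cov_re, resid_var=resid_var,
        converged=converged, singular_fallback=singular,
        n_subjects=n_subj, n_obs=n_obs, loglik=llf,
        groups=tuple([spec.reference_group] + nonref),
    )


def test_interaction(
    fit: TrajectoryFit, term: str, group: str
) -> tuple[float, float, float]:
    """Wald test of a time-by-group or age-by-group contrast vs reference.

    Returns ``(estimate, se, p)``; the estimate for the time term is in
    outcome units per day.  Querying the reference group is an error: its
    interaction is the contrast baseline, not a parameter.
    """
    if term not in ("time_by_group", "age_by_group"):
        raise ValueError("term: time_by_group|age_by_group")
    if group == fit.spec.reference_group:
        raise ValueError("the reference group has no interaction contrast")
    stem = "time" if term == "time_by_group" else "age"
    key = f"{stem}:group[{group}]"
    if key not in fit.params.index:
        raise ValueError(f"unknown group {group!r}")
    est, se = float(fit.params[key]), float(fit.bse[key])
    if stem == "time":
        est, se = est / fit.spec.time_scale, se / fit.spec.time_scale
    p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else float("nan")
    return est, se, float(p)


REPORT_GROUPS = ("HIV-positive", "TopCATs", "BottomCATs")


def build_report(
    fits: dict[str, TrajectoryFit],
    report_groups: tuple[str, ...] = REPORT_GROUPS,
    slope_scale: float = 1e-4,
) -> pd.DataFrame:
    """Report table: per-group time slopes and interaction p-values.

    One row per outcome; slopes are rendered in units of ``slope_scale``
    per day (default 1e-4/day) and the reference group's interaction cells
    carry the literal label ``"Ref"``.  A Benjamini-Hochberg adjusted
    column for the BottomCATs time-by-group p-values across outcomes is
    appended as a clearly-labelled extension of the per-outcome report.
    """
    rows = []
    for outcome, fit in fits.items():
        if fit is None or not fit.converged:
            rows.append({"outcome": outcome, "converged": False})
            continue
        row: dict[str, object] = {"outcome": outcome, "converged": True}
        for g in report_groups:
            row[f"time_slope_x1e4[{g}]"] = fit.group_slopes[g] / slope_scale
        for term, tag in (("age_by_group", "age_x_group_p"),
                          ("time_by_group", "time_x_group_p")):
            for g in report_groups:
                if g == fit.spec.reference_group:
                    row[f"{tag}[{g}]"] = "Ref"
                else:
                    _, _, p = test_interaction(fit, term, g)
                    row[f"{tag}[{g}]"] = p
        rows.append(row)
    report = pd.DataFrame(rows)
    pcol = "time_x_group_p[BottomCATs]"
    if pcol in report.columns:
        mask = report[pcol].apply(
            lambda v: isinstance(v, float) and np.isfinite(v)
        )
        if mask.any():
            adj = multipletests(report.loc[mask, pcol].astype(float),
                                method="fdr_bh")[1]
            report.loc[mask, "bh_extension_" + pcol] = adj
    return report


def read_report(path) -> pd.DataFrame:
    """Re-parse a report CSV, keeping ``"Ref"`` cells and numeric p-values."""
    df = pd.read_csv(path)

    def conv(v):
        if isinstance(v, str) and v != "Ref":
            try:
                return float(v)
            except ValueError:
                return v
        return v

    for col in df.columns:
        if "_p[" in col:
            df[col] = df[col].map(conv)
    return df
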