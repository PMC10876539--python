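"""Balance diagnostics and primary / subgroup treatment-effect estimation.

The primary outcome is each patient's average daily adherence fraction over
follow-up, on the 0-100 percentage scale.  The arm effect is estimated by
linear regression of that patient-level summary on arm, the two
stratification indicators, and the pre-specified adjustment covariates, with
heteroskedasticity-robust (HC3 sandwich) standard errors.  For a one-summary-
per-patient outcome this coincides with an identity-link GEE with
independent working correlation; an optional daily-record fit with an
exchangeable working correlation is provided for raw event logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trial import TrialLog

#: Default adjustment set: the covariates reported as imbalanced at baseline
#: (education, partner status, number of medications); stratification
#: indicators are always included.
DEFAULT_COVARIATES = ("education", "married_partnered", "n_medications")

IMBALANCE_THRESHOLD = 0.1


def standardized_difference(kind, arm1, arm2) -> float:
    """Absolute standardized difference between two arm summaries.

    ``kind="binary"``: arms given as proportions in [0, 1] or ``(events, n)``
    counts; returns |p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2).
    ``kind="continuous"``: arms given as ``(mean, sd)``; returns
    |m1 - m2| / sqrt((s1^2 + s2^2) / 2).
    """
    if kind == "binary":
        def prop(arm) -> float:
            if np.isscalar(arm):
                p = float(arm)
            else:
                x, n = arm
                p = float(x) / float(n)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion out of [0, 1]: {p}")
            return p

        p1, p2 = prop(arm1), prop(arm2)
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
        if pooled == 0.0:
            if p1 == p2:
                return 0.0
            raise ValueError("standardized difference undefined: zero pooled variance with unequal proportions")
        return abs(p1 - p2) / np.sqrt(pooled)
    if kind == "continuous":
        (m1, s1), (m2, s2) = arm1, arm2
        if s1 < 0 or s2 < 0:
            raise ValueError("standard deviations must be nonnegative")
        pooled = (s1**2 + s2**2) / 2.0
        if pooled == 0.0:
            if m1 == m2:
                return 0.0
            raise ValueError("standardized difference undefined: zero pooled variance with unequal means")
        return abs(m1 - m2) / np.sqrt(pooled)
    raise ValueError(f"kind must be 'binary' or 'continuous', got {kind!r}")


@dataclass
class EffectEstimate:
    """Arm effect in adherence percentage points with 95% interval."""

    point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjusted_for: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("confidence interval must bracket the point estimate")


def balance_table(log: TrialLog) -> pd.DataFrame:
    """Per-covariate absolute standardized differences between arms."""
    df = log.cohort.merge(log.assignments, on="patient_id")
    a1 = df[df["arm"] == "intervention"]
    a2 = df[df["arm"] == "control"]
    rows = []

    def add_binary(name: str, mask1: pd.Series, mask2: pd.Series) -> None:
        d = standardized_difference(
            "binary", (mask1.sum(), len(a1)), (mask2.sum(), len(a2))
        )
        rows.append({"covariate": name, "kind": "binary", "std_diff": d,
                     "imbalanced": d > IMBALANCE_THRESHOLD})

    add_binary("female", a1["sex"] == "female", a2["sex"] == "female")
    for level in ("white", "black", "other"):
        add_binary(f"race_{level}", a1["race_ethnicity"] == level, a2["race_ethnicity"] == level)
    for level in ("hs_or_below", "some_college", "postgrad"):
        add_binary(f"education_{level}", a1["education"] == level, a2["education"] == level)
    add_binary("married_partnered", a1["married_partnered"], a2["married_partnered"])
    add_binary("hba1c_ge9", a1["baseline_hba1c"] >= 9, a2["baseline_hba1c"] >= 9)
    add_binary("years_on_meds_4plus", a1["years_on_meds"] == ">=4", a2["years_on_meds"] == ">=4")
    add_binary("multiple_medications", a1["n_medications"] >= 2, a2["n_medications"] >= 2)
    add_binary("missed_gt1", a1["baseline_missed_doses"] == ">1", a2["baseline_missed_doses"] == ">1")
    add_binary("automaticity", a1["automaticity"], a2["automaticity"])
    add_binary("activation", a1["activation"], a2["activation"])
    for name in ("age", "baseline_hba1c"):
        d = standardized_difference(
            "continuous", (a1[name].mean(), a1[name].std(ddof=1)),
            (a2[name].mean(), a2[name].std(ddof=1)),
        )
        rows.append({"covariate": name, "kind": "continuous", "std_diff": d,
                     "imbalanced": d > IMBALANCE_THRESHOLD})
    return pd.DataFrame(rows)


def patient_outcomes(log: TrialLog) -> pd.DataFrame:
    """Patient-level analysis table: mean adherence (0-100), arm, covariates."""
    means = (
        log.adherence.groupby("patient_id")["fraction_taken"].mean().mul(100.0)
        .rename("mean_adherence")
    )
    df = log.assignments.merge(means, on="patient_id").merge(log.cohort, on="patient_id")
    df["treat"] = (df["arm"] == "intervention").astype(float)
    df["missed_gt1"] = (df["baseline_missed_doses"] == ">1").astype(float)
    df["hba1c_ge9"] = (df["baseline_hba1c"] >= 9.0).astype(float)
    return df


def _encode_covariates(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "education":
            cols["edu_some_college"] = (df["education"] == "some_college").astype(float).to_numpy()
            cols["edu_postgrad"] = (df["education"] == "postgrad").astype(float).to_numpy()
        elif cov == "race_ethnicity":
            cols["race_black"] = (df["race_ethnicity"] == "black").astype(float).to_numpy()
            cols["race_other"] = (df["race_ethnicity"] == "other").astype(float).to_numpy()
        elif cov == "sex":
            cols["female"] = (df["sex"] == "female").astype(float).to_numpy()
        elif cov == "years_on_meds":
            cols["years_4plus"] = (df["years_on_meds"] == ">=4").astype(float).to_numpy()
        elif cov not in df.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        else:
            cols[cov] = df[cov].astype(float).to_numpy()
    return pd.DataFrame(cols, index=df.index)


def _drop_collinear(X: pd.DataFrame, protected: Sequence[str]) -> pd.DataFrame:
    keep: list[str] = []
    dropped: list[str] = []
    for col in X.columns:
        trial_cols = keep + [col]
        if np.linalg.matrix_rank(X[trial_cols].to_numpy()) == len(trial_cols):
            keep.append(col)
        elif col in protected:
            raise ValueError(f"design-critical column {col!r} is collinear")
        else:
            dropped.append(col)
    if dropped:
        warnings.warn(f"dropped collinear covariates: {dropped}", stacklevel=3)
    return X[keep]


def fit_arm_effect(
    patient_df: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cov_type: str = "HC3",
) -> EffectEstimate:
    """Robust-SE linear fit of patient-level mean adherence on arm.

    ``patient_df`` needs columns ``mean_adherence`` (0-100), ``treat`` (0/1),
    ``missed_gt1``, ``hba1c_ge9``, plus whatever ``covariates`` reference.
    """
    if patient_df["treat"].nunique() < 2:
        raise ValueError("both arms must be present to estimate an arm effect")
    X = pd.DataFrame({"intercept": np.ones(len(patient_df)),
                      "treat": patient_df["treat"].to_numpy()},
                     index=patient_df.index)
    X["missed_gt1"] = patient_df["missed_gt1"].to_numpy()
    X["hba1c_ge9"] = patient_df["hba1c_ge9"].to_numpy()
    X = pd.concat([X, _encode_covariates(patient_df, covariates)], axis=1)
    X = _drop_collinear(X, protected=("intercept", "treat"))
    y = patient_df["mean_adherence"].to_numpy()
    res = sm.OLS(y, X).fit(cov_type=cov_type)
    ci = res.conf_int().loc["treat"]
    return EffectEstimate(
        point=float(res.params["treat"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues["treat"]),
        n_used=int(res.nobs),
        adjusted_for=[c for c in X.columns if c not in ("intercept", "treat")],
    )


def estimate_primary(
    log: TrialLog,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    daily: bool = False,
) -> EffectEstimate:
    """Primary arm-effect estimate in adherence percentage points.

    ``daily=True`` fits the daily records with an exchangeable working
    correlation (GEE) instead of the patient-level summary regression; point
    estimates agree for balanced panels.
    """
    df = patient_outcomes(log)
    if not daily:
        return fit_arm_effect(df, covariates)
    rec = log.adherence.dropna(subset=["fraction_taken"]).merge(
        df.drop(columns=["mean_adherence"]), on="patient_id"
    )
    X = pd.DataFrame({"intercept": np.ones(len(rec)), "treat": rec["treat"].to_numpy()},
                     index=rec.index)
    X["missed_gt1"] = rec["missed_gt1"].to_numpy()
    X["hba1c_ge9"] = rec["hba1c_ge9"].to_numpy()
    X = pd.concat([X, _encode_covariates(rec, covariates)], axis=1)
    X = _drop_collinear(X, protected=("intercept", "treat"))
    y = rec["fraction_taken"].to_numpy() * 100.0
    model = sm.GEE(y, X, groups=rec["patient_id"],
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit()
    ci = res.conf_int().loc["treat"]
    return EffectEstimate(
        point=float(res.params["treat"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues["treat"]),
        n_used=int(rec["patient_id"].nunique()),
        adjusted_for=[c for c in X.columns if c not in ("intercept", "treat")],
    )


def subgroup_effects(
    log: TrialLog,
    subgroup_definitions: Mapping[str, Callable[[pd.DataFrame], pd.Series]],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Within-subgroup effects plus an arm-by-subgroup interaction p-value.

    Each definition maps the patient-level table to a boolean membership
    series; the complement subgroup is analyzed too.  Subgroups empty in
    either arm are skipped with a warning.
    """
    df = patient_outcomes(log)
    rows = []
    for name, definition in subgroup_definitions.items():
        member = definition(df).astype(bool)
        for label, mask in ((f"{name}", member), (f"not_{name}", ~member)):
            sub = df[mask]
            if sub.empty or sub["treat"].nunique() < 2:
                warnings.warn(f"subgroup {label!r} empty in one arm; skipped")
                continue
            try:
                est = fit_arm_effect(sub, covariates)
            except ValueError as err:
                warnings.warn(f"subgroup {label!r} skipped: {err}")
                continue
            rows.append({"subgroup": label, "point": est.point, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "p_value": est.p_value, "n": est.n_used,
                         "interaction_p": np.nan})
        # interaction test from the pooled model
        X = pd.DataFrame({
            "intercept": np.ones(len(df)),
            "treat": df["treat"].to_numpy(),
            "member": member.astype(float).to_numpy(),
            "treat_x_member": (df["treat"] * member).to_numpy(),
            "missed_gt1": df["missed_gt1"].to_numpy(),
            "hba1c_ge9": df["hba1c_ge9"].to_numpy(),
        }, index=df.index)
        X = pd.concat([X, _encode_covariates(df, covariates)], axis=1)
        try:
            X = _drop_collinear(X, protected=("intercept", "treat", "treat_x_member"))
            res = sm.OLS(df["mean_adherence"].to_numpy(), X).fit(cov_type="HC3")
            p_int = float(res.pvalues["treat_x_member"])
        except ValueError as err:
            warnings.warn(f"interaction test for {name!r} undefined: {err}")
            p_int = np.nan
        for row in rows:
            if row["subgroup"] in (name, f"not_{name}") and np.isnan(row["interaction_p"]):
                row["interaction_p"] = p_int
    return pd.DataFrame(rows)
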