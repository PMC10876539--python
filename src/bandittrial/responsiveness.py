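"""Algorithm-performance diagnostics and responsiveness heterogeneity analyses.

Covers the message-arm analyses: the daily adjusted-R-squared learning
trajectory, factor-day adherence summaries, prior-day/same-day sequence
stratification, per-factor optimal-adherence (relative-risk) regressions,
k-means responsiveness phenotyping, and cluster-membership modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .catalog import FACTOR_NAMES, N_FACTORS
from .trial import TrialLog

_IDX = {name: i for i, name in enumerate(FACTOR_NAMES)}

#: Mapping factor indicator -> messages-frame column & truthy level.
_FACTOR_COLUMNS = {
    "framing_positive": ("framing", "positive"),
    "framing_negative": ("framing", "negative"),
    "history": ("history", True),
    "social": ("social", True),
    "content_informational": ("content", "informational"),
    "reflective": ("reflective", True),
}


def factor_indicator_frame(messages: pd.DataFrame) -> pd.DataFrame:
    """Messages with six 0/1 factor indicator columns appended."""
    out = messages.copy()
    for name, (col, level) in _FACTOR_COLUMNS.items():
        out[name] = (messages[col] == level).astype(float)
    return out


def _merged_daily(log: TrialLog) -> pd.DataFrame:
    """Intervention patient-days: factor indicators joined to adherence."""
    msgs = factor_indicator_frame(log.messages)
    return msgs.merge(log.adherence, on=["patient_id", "study_day"], how="left")


# ---------------------------------------------------------------------------
# Daily adjusted R^2 trajectory
# ---------------------------------------------------------------------------

#: p = 6 factor indicators enter the day-level regression (framing
#: contributes two dummies against the neutral reference).
_P = N_FACTORS
MIN_DAILY_OBS = max(5, _P + 2)


def daily_adjusted_r2(log: TrialLog) -> pd.DataFrame:
    """Per-day adjusted R^2 of adherence on the six factor indicators.

    For each study day, ordinary least squares of the adherence fraction on
    the factor indicators across patients; adjusted R^2 =
    1 - (1 - R^2)(n - 1)/(n - p - 1) with p = 6.  Days with fewer than
    max(5, p + 2) observed patients are skipped.  A day whose outcomes have
    zero variance is reported as 0 with a degenerate flag.
    """
    daily = _merged_daily(log).dropna(subset=["fraction_taken"])
    rows = []
    for day, grp in daily.groupby("study_day"):
        n = len(grp)
        if n < MIN_DAILY_OBS:
            continue
        y = grp["fraction_taken"].to_numpy()
        if np.allclose(y, y[0]):
            rows.append({"study_day": int(day), "n_observations": n,
                         "adjusted_r2": 0.0, "degenerate": True})
            continue
        X = np.column_stack([np.ones(n)] + [grp[f].to_numpy() for f in FACTOR_NAMES])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - _P - 1)
        rows.append({"study_day": int(day), "n_observations": n,
                     "adjusted_r2": float(adj), "degenerate": False})
    return pd.DataFrame(rows, columns=["study_day", "n_observations", "adjusted_r2", "degenerate"])


# ---------------------------------------------------------------------------
# Factor-day and sequence summaries
# ---------------------------------------------------------------------------

def factor_day_table(log: TrialLog) -> pd.DataFrame:
    """Mean (SD) adherence, on the 0-100 scale, on factor send-days and the day after.

    The next-day column pairs each factor-on day t with adherence at t + 1;
    send-days on the final study day contribute no next-day observation.
    """
    daily = _merged_daily(log)
    next_adh = log.adherence.copy()
    next_adh["study_day"] -= 1  # align day t+1 adherence onto day t rows
    daily = daily.merge(
        next_adh.rename(columns={"fraction_taken": "fraction_next_day"}),
        on=["patient_id", "study_day"], how="left",
    )
    rows = []
    for f in FACTOR_NAMES:
        on = daily[daily[f] == 1.0]
        same = on["fraction_taken"].dropna() * 100.0
        nxt = on["fraction_next_day"].dropna() * 100.0
        rows.append({
            "factor": f,
            "n_send_days": int(len(on)),
            "same_day_mean": same.mean() if len(same) else np.nan,
            "same_day_sd": same.std(ddof=1) if len(same) > 1 else np.nan,
            "next_day_mean": nxt.mean() if len(nxt) else np.nan,
            "next_day_sd": nxt.std(ddof=1) if len(nxt) > 1 else np.nan,
            "empty": len(on) == 0,
        })
    return pd.DataFrame(rows)


def sequence_table(log: TrialLog) -> pd.DataFrame:
    """Mean adherence stratified by prior-day x same-day factor inclusion.

    Study day 1 is excluded (no prior day).  Strata with no qualifying
    patient-days are reported as missing, never as zero.
    """
    daily = _merged_daily(log).sort_values(["patient_id", "study_day"])
    prior = daily.copy()
    prior["study_day"] += 1
    merged = daily.merge(
        prior[["patient_id", "study_day", *FACTOR_NAMES]],
        on=["patient_id", "study_day"], suffixes=("", "_prior"), how="inner",
    )
    rows = []
    for f in FACTOR_NAMES:
        for prior_on in (0.0, 1.0):
            for today_on in (0.0, 1.0):
                cell = merged[(merged[f"{f}_prior"] == prior_on) & (merged[f] == today_on)]
                vals = cell["fraction_taken"].dropna()
                rows.append({
                    "factor": f,
                    "prior_day": bool(prior_on),
                    "same_day": bool(today_on),
                    "n": int(len(vals)),
                    "mean_adherence": vals.mean() * 100.0 if len(vals) else np.nan,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optimal-adherence relative-risk models
# ---------------------------------------------------------------------------

#: Risk-ratio bands used for reporting (mirrors a three-color legend).
def classify_rr(rr: float) -> str:
    if rr >= 1.50:
        return "strong_positive"
    if rr > 1.0:
        return "positive"
    if rr < 1.0:
        return "negative"
    return "null"


def _baseline_design(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline-covariate design block shared by the responsiveness models."""
    return pd.DataFrame({
        "age_std": (cohort["age"].astype(float) - 60.0) / 10.0,
        "female": (cohort["sex"] == "female").astype(float),
        "race_black": (cohort["race_ethnicity"] == "black").astype(float),
        "race_other": (cohort["race_ethnicity"] == "other").astype(float),
        "edu_some_college": (cohort["education"] == "some_college").astype(float),
        "edu_postgrad": (cohort["education"] == "postgrad").astype(float),
        "married_partnered": cohort["married_partnered"].astype(float),
        "n_medications_c": cohort["n_medications"].astype(float) - 1.0,
        "insulin_use": cohort["insulin_use"].astype(float),
        "activation": cohort["activation"].astype(float),
        "employment": cohort["employment"].astype(float),
        "hba1c_c": cohort["baseline_hba1c"].astype(float) - 9.0,
    }, index=cohort.index)


def optimal_adherence_model(
    log: TrialLog,
    factor: str,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Relative risks of optimal next-day adherence after sending ``factor``.

    Among intervention patient-days on which ``factor`` was included, fits a
    log-link binomial regression of 1{next-day adherence fraction == 1} on
    baseline covariates (unadjusted for patient-level clustering, as is
    conventional at this sample size).  If the log-binomial fit fails to
    converge, falls back to a modified-Poisson fit with robust standard
    errors and flags it.  ``covariates`` optionally overrides the default
    baseline design with a per-patient frame indexed by patient id.  Returns
    per-covariate RRs with 95% CIs and band classification.
    """
    if factor not in _IDX:
        raise ValueError(f"unknown factor {factor!r}")
    daily = _merged_daily(log)
    nxt = log.adherence.copy()
    nxt["study_day"] -= 1
    daily = daily.merge(
        nxt.rename(columns={"fraction_taken": "fraction_next_day"}),
        on=["patient_id", "study_day"], how="left",
    )
    sub = daily[(daily[factor] == 1.0) & daily["fraction_next_day"].notna()]
    if sub.empty:
        raise ValueError(f"factor {factor!r} contributes no next-day outcomes")
    y = (sub["fraction_next_day"] == 1.0).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("degenerate model: next-day optimal adherence is constant")
    if covariates is None:
        covariates = _baseline_design(log.cohort.set_index("patient_id"))
    design = covariates.loc[sub["patient_id"]].reset_index(drop=True)
    X = sm.add_constant(design, prepend=True)

    fallback = False
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Log()))
        res = model.fit(maxiter=200)
        if not res.converged or np.any(~np.isfinite(res.bse)):
            raise RuntimeError("log-binomial fit did not converge")
    except Exception:
        fallback = True
        model = sm.GLM(y, X, family=sm.families.Poisson())
        res = model.fit(cov_type="HC1")

    ci = res.conf_int()
    rows = []
    for name in X.columns:
        if name == "const":
            continue
        rr = float(np.exp(res.params[name]))
        rows.append({
            "covariate": name,
            "rr": rr,
            "ci_low": float(np.exp(ci.loc[name, 0])),
            "ci_high": float(np.exp(ci.loc[name, 1])),
            "band": classify_rr(rr),
            "modified_poisson": fallback,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Responsiveness matrix and k-means phenotyping
# ---------------------------------------------------------------------------

MIN_CELL_OBS = 25  # cells with fewer factor-on days are mean-imputed


def build_response_matrix(log: TrialLog, min_obs: int = MIN_CELL_OBS):
    """Per-patient mean adherence conditional on each factor's presence.

    Returns ``(response, counts, imputed)``: patients x six-factor frames of
    conditional means (same-day adherence on factor-on days), observation
    counts, and a boolean mask of cells that fell below ``min_obs`` and were
    replaced by the column mean of the adequately observed cells.
    """
    daily = _merged_daily(log).dropna(subset=["fraction_taken"])
    pids = sorted(daily["patient_id"].unique())
    response = pd.DataFrame(index=pids, columns=FACTOR_NAMES, dtype=float)
    counts = pd.DataFrame(0, index=pids, columns=FACTOR_NAMES, dtype=int)
    for f in FACTOR_NAMES:
        on = daily[daily[f] == 1.0]
        grp = on.groupby("patient_id")["fraction_taken"]
        response[f] = grp.mean()
        counts[f] = grp.size().reindex(pids).fillna(0).astype(int)
    imputed = counts < min_obs
    for f in FACTOR_NAMES:
        ok = response.loc[~imputed[f], f]
        col_mean = ok.mean() if len(ok) else daily["fraction_taken"].mean()
        response.loc[imputed[f], f] = col_mean
    return response, counts, imputed


@dataclass
class ClusterResult:
    """A k-means partition of the message-arm patients."""

    assignments: pd.Series       # patient_id -> cluster id 1..k (1 = largest)
    centroids: np.ndarray        # in the preprocessed feature space
    sizes: pd.Series             # cluster id -> member count
    inertia: float


def cluster_patients(
    response: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    center_rows: bool = True,
    standardize: bool = True,
    n_init: int = 50,
) -> ClusterResult:
    """K-means phenotyping of the responsiveness matrix.

    Rows are centered by default (each patient's overall adherence level is
    removed so clusters reflect differential responsiveness, not baseline
    adherence) and columns standardized; 50 restarts keep the best
    within-cluster sum of squares.  Cluster ids are relabeled in decreasing
    size order, so cluster 1 is always the largest (the natural referent).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(response):
        raise ValueError(f"k={k} exceeds the number of patients ({len(response)})")
    X = response.to_numpy(dtype=float)
    if center_rows:
        X = X - X.mean(axis=1, keepdims=True)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order = pd.Series(raw).value_counts(sort=True).index  # descending size
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[r] for r in raw], index=response.index, name="cluster")
    sizes = labels.value_counts().sort_index()
    centroids = np.array([km.cluster_centers_[old] for old in order])
    return ClusterResult(assignments=labels, centroids=centroids,
                         sizes=sizes, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Cluster-membership models
# ---------------------------------------------------------------------------

SEPARATION_SENTINEL = "too small to compute"

#: Default binary baseline contrasts examined for cluster membership.
def default_membership_contrasts(cohort: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "age_ge65": (cohort["age"].astype(float) >= 65).astype(int),
        "female": (cohort["sex"] == "female").astype(int),
        "white": (cohort["race_ethnicity"] == "white").astype(int),
        "married_partnered": cohort["married_partnered"].astype(int),
        "hba1c_lt9": (cohort["baseline_hba1c"] < 9.0).astype(int),
        "years_on_meds_4plus": (cohort["years_on_meds"] == ">=4").astype(int),
        "single_medication": (cohort["n_medications"] == 1).astype(int),
        "missed_gt1": (cohort["baseline_missed_doses"] == ">1").astype(int),
    }, index=cohort.index)


def cluster_membership_model(
    clusters: ClusterResult,
    cohort: Optional[pd.DataFrame] = None,
    contrasts: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Bivariate multinomial logistic models of cluster membership.

    One baseline characteristic at a time, with the largest cluster as the
    referent outcome; returns the odds ratio (95% CI) of membership in each
    non-referent cluster per characteristic.  Contingency cells of zero make
    the MLE diverge; such contrasts are reported with the
    "too small to compute" sentinel instead of a numeric OR.
    """
    sizes = clusters.sizes
    if len(sizes) < 2 or (sizes < 1).any():
        raise ValueError("need >= 2 clusters with >= 1 member each")
    referent = int(sizes.idxmax())
    if contrasts is None:
        if cohort is None:
            raise ValueError("either a cohort or explicit contrasts are required")
        cohort_idx = cohort.set_index("patient_id").loc[clusters.assignments.index]
        contrasts = default_membership_contrasts(cohort_idx)
    else:
        contrasts = contrasts.loc[clusters.assignments.index]
    labels = clusters.assignments
    # recode: referent -> 0, others keep order
    non_ref = [c for c in sorted(sizes.index) if c != referent]
    code = {referent: 0, **{c: i + 1 for i, c in enumerate(non_ref)}}
    y = labels.map(code).to_numpy()

    rows = []
    for name in contrasts.columns:
        x = contrasts[name].to_numpy(dtype=float)
        # detect separation from the contingency table before fitting
        bad: dict[int, bool] = {}
        for c in non_ref:
            cells = [
                ((labels == c) & (x == 1)).sum(), ((labels == c) & (x == 0)).sum(),
                ((labels == referent) & (x == 1)).sum(), ((labels == referent) & (x == 0)).sum(),
            ]
            bad[c] = any(v == 0 for v in cells)
        fit = None
        if not all(bad.values()):
            X = sm.add_constant(x, prepend=True)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # near-separation noise; checked below
                    fit = sm.MNLogit(y, X).fit(disp=False, maxiter=200)
            except Exception:
                fit = None
        for c in non_ref:
            j = code[c] - 1
            if bad[c] or fit is None or not np.all(np.isfinite(fit.bse[:, j])):
                rows.append({"covariate": name, "cluster": c, "referent": referent,
                             "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "note": SEPARATION_SENTINEL})
                continue
            beta = float(fit.params[1, j])
            se = float(fit.bse[1, j])
            rows.append({"covariate": name, "cluster": c, "referent": referent,
                         "odds_ratio": float(np.exp(beta)),
                         "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                         "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                         "note": ""})
    return pd.DataFrame(rows)
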