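"""Replicate simulation studies validating the pipeline's operating characteristics.

These are the package's calibration and learning diagnostics: type-I error of
the primary analysis under a null generator, power under the trial's design
assumptions, selection drift of the bandit toward a planted factor, the
daily adjusted-R-squared learning signature, and planted-cluster recovery.
Each study is seedable and sized to run on a laptop; both the test suite and
``scripts/acceptance.py`` call into this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import FACTOR_NAMES
from .config import BanditParams, SimulatorParams, TrialConfig
from .outcomes import estimate_primary, fit_arm_effect, standardized_difference
from .responsiveness import build_response_matrix, cluster_patients, daily_adjusted_r2, factor_indicator_frame
from .trial import run_trial

#: Published baseline-balance rows (events, n) per arm whose binary
#: standardized differences the implementation reproduces exactly at 2 dp.
#: These printed counts are inputs, not outputs, of the package.
TABLE1_BINARY_ROWS: dict[str, tuple[tuple[int, int], tuple[int, int], float]] = {
    "female_sex": ((12, 29), (14, 31), 0.08),
    "white_race": ((17, 29), (18, 31), 0.01),
    "black_race": ((6, 29), (8, 31), 0.12),
    "hs_education_or_below": ((7, 29), (5, 31), 0.20),
    "married_partnered": ((13, 29), (17, 31), 0.20),
    "multiple_medications": ((9, 29), (6, 31), 0.27),
    "physicians_3plus": ((19, 29), (16, 31), 0.29),
    "nonadherent_baseline": ((12, 29), (14, 31), 0.08),
}


def table1_standardized_differences() -> pd.DataFrame:
    """Recompute the published binary balance rows from their printed counts."""
    rows = []
    for name, (arm1, arm2, published) in TABLE1_BINARY_ROWS.items():
        computed = standardized_difference("binary", arm1, arm2)
        rows.append({"covariate": name, "computed": computed,
                     "computed_2dp": round(computed, 2), "published": published})
    return pd.DataFrame(rows)


def _null_config(seed: int) -> TrialConfig:
    return TrialConfig(
        seed=seed,
        policy="random",
        simulator=SimulatorParams(effect_scale=0.0, carryover_scale=0.0),
    )


def null_type1_study(n_reps: int = 500, base_seed: int = 0) -> dict[str, float]:
    """Type-I calibration: share of null trials whose 95% CI excludes zero.

    Null trials use the behaviorally null generator (all planted effects
    zero), under which message decisions are independent of adherence, so the
    non-adaptive policy fast path is distributionally equivalent for the
    arm contrast.
    """
    excluded = 0
    points = []
    for r in range(n_reps):
        est = estimate_primary(run_trial(_null_config(base_seed + r)))
        excluded += (est.ci_low > 0.0) or (est.ci_high < 0.0)
        points.append(est.point)
    return {
        "exclusion_rate": excluded / n_reps,
        "mean_point": float(np.mean(points)),
        "n_reps": n_reps,
    }


def analytic_power(delta: float = 10.0, sd: float = 12.5, n_per_arm: int = 30,
                   alpha: float = 0.05) -> float:
    """Exact two-sample t-test power (noncentral t) — the design oracle."""
    df = 2 * n_per_arm - 2
    ncp = delta / (sd * np.sqrt(2.0 / n_per_arm))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_study(n_reps: int = 500, base_seed: int = 7, delta: float = 10.0,
                sd: float = 12.5, n_per_arm: int = 30) -> dict[str, float]:
    """Rejection rate of the primary analysis under the design assumptions.

    Patient-level outcomes are drawn directly at the design's effect size and
    standard deviation (a planted ``delta``-point arm difference with
    patient-level SD ``sd``), then analyzed with the primary-model fit.
    """
    rng = np.random.default_rng(base_seed)
    n = 2 * n_per_arm
    rejections = 0
    for _ in range(n_reps):
        df = pd.DataFrame({
            "treat": np.repeat([1.0, 0.0], [n_per_arm, n_per_arm]),
            "missed_gt1": (rng.random(n) < 26 / 60).astype(float),
            "hba1c_ge9": (rng.random(n) < 26 / 60).astype(float),
        })
        df["mean_adherence"] = 70.0 + delta * df["treat"] + rng.normal(0.0, sd, n)
        rejections += fit_arm_effect(df, covariates=()).p_value < 0.05
    return {
        "rejection_rate": rejections / n_reps,
        "analytic_power": analytic_power(delta, sd, n_per_arm),
        "n_reps": n_reps,
    }


@dataclass
class DriftStudy:
    """Per-seed early/late selection frequencies for every factor."""

    early: pd.DataFrame  # seeds x factors, days 1-30
    late: pd.DataFrame   # seeds x factors, days 121-180

    def gains(self, factor: str) -> np.ndarray:
        return (self.late[factor] - self.early[factor]).to_numpy()

    def one_sided_p(self, factor: str) -> float:
        g = self.gains(factor)
        return float(stats.ttest_1samp(g, 0.0, alternative="greater").pvalue)


def selection_drift_study(
    n_seeds: int = 20, base_seed: int = 0, planted_factor: str | None = "history",
    effect_scale: float = 0.8,
) -> DriftStudy:
    """Bandit selection frequencies early (days 1-30) vs late (days 121-180).

    With ``planted_factor`` set, that factor alone carries a positive effect
    (``effect_scale`` log-odds) for every patient; with ``None`` the
    generator is behaviorally null.
    """
    early_rows, late_rows = [], []
    for s in range(n_seeds):
        if planted_factor is None:
            sim = SimulatorParams(effect_scale=0.0, carryover_scale=0.0)
        else:
            sim = SimulatorParams(single_factor=planted_factor, effect_scale=effect_scale)
        log = run_trial(TrialConfig(seed=base_seed + s, simulator=sim))
        m = factor_indicator_frame(log.messages)
        early_rows.append(m[m.study_day <= 30][list(FACTOR_NAMES)].mean())
        late_rows.append(m[(m.study_day >= 121) & (m.study_day <= 180)][list(FACTOR_NAMES)].mean())
    return DriftStudy(early=pd.DataFrame(early_rows), late=pd.DataFrame(late_rows))


def r2_learning_study(
    n_seeds: int = 20, base_seed: int = 0, null: bool = False
) -> pd.DataFrame:
    """Mean daily adjusted R^2 in days 31-60 vs days 150-180 per seed."""
    rows = []
    for s in range(n_seeds):
        sim = SimulatorParams(effect_scale=0.0, carryover_scale=0.0) if null else SimulatorParams()
        log = run_trial(TrialConfig(seed=base_seed + s, simulator=sim))
        r2 = daily_adjusted_r2(log)
        early = r2[(r2.study_day >= 31) & (r2.study_day <= 60)]["adjusted_r2"].mean()
        late = r2[(r2.study_day >= 150) & (r2.study_day <= 180)]["adjusted_r2"].mean()
        rows.append({"seed": base_seed + s, "early": early, "late": late,
                     "rose": late > early})
    return pd.DataFrame(rows)


def cluster_recovery_study(
    n_seeds: int = 20, base_seed: int = 0, effect_scale: float = 0.8,
    n_patients: int = 58, follow_up_days: int = 180,
) -> np.ndarray:
    """Adjusted Rand index of k-means recovery of the planted phenotypes.

    Simulates non-adaptive message-arm logs (about ``n_patients / 2``
    message-arm patients), builds the conditional-response matrix, clusters
    with k = 3, and scores the partition against the planted labels.
    """
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for s in range(n_seeds):
        cfg = TrialConfig(
            n_patients=n_patients, follow_up_days=follow_up_days, policy="random",
            seed=base_seed + s, simulator=SimulatorParams(effect_scale=effect_scale),
        )
        log = run_trial(cfg)
        response, _, _ = build_response_matrix(log)
        result = cluster_patients(response, k=3, seed=base_seed + s)
        truth = [log.profiles[p].cluster_label for p in response.index]
        aris.append(adjusted_rand_score(truth, result.assignments.to_numpy()))
    return np.array(aris)


def default_trial_summary(seed: int = 0) -> dict[str, float]:
    """One full default trial: arm means and the adjusted primary effect."""
    log = run_trial(TrialConfig(seed=seed))
    arm_means = (
        log.adherence.merge(log.assignments, on="patient_id")
        .groupby("arm")["fraction_taken"].mean()
    )
    est = estimate_primary(log)
    return {
        "intervention_mean_pct": float(arm_means["intervention"] * 100.0),
        "control_mean_pct": float(arm_means["control"] * 100.0),
        "effect_pp": est.point,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_value": est.p_value,
        "n": est.n_used,
    }
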