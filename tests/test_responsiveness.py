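import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bandittrial.catalog import FACTOR_NAMES
from bandittrial.responsiveness import (
    ClusterResult,
    MIN_DAILY_OBS,
    SEPARATION_SENTINEL,
    build_response_matrix,
    classify_rr,
    cluster_membership_model,
    cluster_patients,
    daily_adjusted_r2,
    factor_day_table,
    optimal_adherence_model,
    sequence_table,
)
from bandittrial.trial import TrialLog

HIST = FACTOR_NAMES.index("history")


def make_log(indicator_rows, fractions, cohort=None):
    """Build a minimal TrialLog from (patient, day, 6-indicators) rows."""
    msg_rows = []
    adh_rows = []
    for (pid, day, ind), frac in zip(indicator_rows, fractions):
        pos, neg, hist, soc, info, refl = ind
        msg_rows.append({
            "patient_id": pid, "study_day": day,
            "framing": "positive" if pos else "negative" if neg else "neutral",
            "history": bool(hist), "social": bool(soc),
            "content": "informational" if info else "reminder",
            "reflective": bool(refl), "template_id": "T",
        })
        adh_rows.append({"patient_id": pid, "study_day": day, "fraction_taken": frac})
    return TrialLog(
        cohort=cohort if cohort is not None else pd.DataFrame(),
        profiles={},
        assignments=pd.DataFrame(),
        messages=pd.DataFrame(msg_rows),
        adherence=pd.DataFrame(adh_rows),
        rewards=pd.DataFrame(columns=["patient_id", "decision_day", "reward"]),
    )


class TestDailyAdjustedR2:
    def test_exactly_determined_day_reaches_one(self):
        rows, fracs = [], []
        rng = np.random.default_rng(0)
        for i in range(12):
            ind = rng.integers(0, 2, 6)
            ind[1] = 0 if ind[0] else ind[1]
            rows.append((f"P{i:03d}", 1, ind))
            fracs.append(0.1 + 0.08 * ind[HIST] + 0.05 * ind[4] + 0.03 * ind[5]
                         + 0.02 * ind[0] + 0.01 * ind[3])
        out = daily_adjusted_r2(make_log(rows, fracs))
        assert out.iloc[0]["adjusted_r2"] == pytest.approx(1.0)

    def test_small_days_absent(self):
        rows = [(f"P{i}", 1, np.zeros(6)) for i in range(MIN_DAILY_OBS - 1)]
        out = daily_adjusted_r2(make_log(rows, [0.5] * len(rows)))
        assert out.empty

    def test_four_observation_day_absent(self):
        rows = [(f"P{i}", 1, np.zeros(6)) for i in range(4)]
        assert daily_adjusted_r2(make_log(rows, [0.1, 0.5, 0.9, 1.0])).empty

    def test_matches_independent_normal_equations(self):
        rng = np.random.default_rng(3)
        rows, fracs = [], []
        for i in range(10):
            ind = rng.integers(0, 2, 6)
            ind[1] = 0 if ind[0] else ind[1]
            rows.append((f"P{i:03d}", 1, ind))
            fracs.append(float(rng.random()))
        out = daily_adjusted_r2(make_log(rows, fracs))

        X = np.column_stack([np.ones(10)] + [
            [float(ind[j]) for _, _, ind in rows] for j in range(6)
        ])
        y = np.array(fracs)
        beta = np.linalg.pinv(X.T @ X) @ X.T @ y
        ss_res = float(((y - X @ beta) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        adj = 1 - (1 - (1 - ss_res / ss_tot)) * (10 - 1) / (10 - 6 - 1)
        assert out.iloc[0]["adjusted_r2"] == pytest.approx(adj)

    def test_zero_variance_day_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        rows = [(f"P{i}", 1, rng.integers(0, 2, 6)) for i in range(9)]
        out = daily_adjusted_r2(make_log(rows, [0.5] * 9))
        assert out.iloc[0]["adjusted_r2"] == 0.0
        assert bool(out.iloc[0]["degenerate"])

    def test_never_exceeds_one(self, random_trial):
        out = daily_adjusted_r2(random_trial)
        assert (out["adjusted_r2"] <= 1.0).all()


class TestFactorDayTable:
    def test_hand_arithmetic_fixture(self):
        hist_on = np.zeros(6); hist_on[HIST] = 1
        rows = [
            ("P1", 1, hist_on), ("P1", 2, np.zeros(6)), ("P1", 3, hist_on),
            ("P2", 1, np.zeros(6)), ("P2", 2, hist_on), ("P2", 3, np.zeros(6)),
        ]
        fracs = [1.0, 0.5, 0.0, 0.25, 0.75, 1.0]
        table = factor_day_table(make_log(rows, fracs)).set_index("factor")
        row = table.loc["history"]
        # same-day: days (P1,1)=1.0, (P1,3)=0.0, (P2,2)=0.75
        assert row["same_day_mean"] == pytest.approx(100 * np.mean([1.0, 0.0, 0.75]))
        # next-day: (P1,2)=0.5 after (P1,1); (P2,3)=1.0 after (P2,2);
        # (P1,3) has no successor -> excluded
        assert row["next_day_mean"] == pytest.approx(100 * np.mean([0.5, 1.0]))

    def test_final_day_has_no_next_day_contribution(self):
        hist_on = np.zeros(6); hist_on[HIST] = 1
        log = make_log([("P1", 5, hist_on)], [1.0])
        row = factor_day_table(log).set_index("factor").loc["history"]
        assert row["same_day_mean"] == pytest.approx(100.0)
        assert np.isnan(row["next_day_mean"])

    def test_never_sent_factor_flagged_empty(self):
        log = make_log([("P1", 1, np.zeros(6))], [1.0])
        table = factor_day_table(log).set_index("factor")
        assert bool(table.loc["history", "empty"])


class TestSequenceTable:
    def test_exact_strata_reproduction(self):
        on = np.zeros(6); on[HIST] = 1
        rows = [
            ("P1", 1, on), ("P1", 2, on), ("P1", 3, np.zeros(6)), ("P1", 4, on),
        ]
        fracs = [0.2, 0.8, 0.6, 0.4]
        table = sequence_table(make_log(rows, fracs))
        t = table[table.factor == "history"].set_index(["prior_day", "same_day"])
        # day 1 excluded; day 2 = (on, on) -> 0.8; day 3 = (on, off) -> 0.6;
        # day 4 = (off, on) -> 0.4
        assert t.loc[(True, True), "mean_adherence"] == pytest.approx(80.0)
        assert t.loc[(True, False), "mean_adherence"] == pytest.approx(60.0)
        assert t.loc[(False, True), "mean_adherence"] == pytest.approx(40.0)
        assert np.isnan(t.loc[(False, False), "mean_adherence"])
        assert t.loc[(False, False), "n"] == 0

    def test_single_day_log_all_strata_empty(self):
        log = make_log([("P1", 1, np.zeros(6))], [1.0])
        table = sequence_table(log)
        assert table["mean_adherence"].isna().all()

    def test_planted_carryover_orders_on_on_above_off_on(self, random_trial):
        table = sequence_table(random_trial)
        t = table[table.factor == "history"].set_index(["prior_day", "same_day"])
        assert (
            t.loc[(True, True), "mean_adherence"] > t.loc[(False, True), "mean_adherence"]
        )


class TestOptimalAdherenceModel:
    def _two_by_two_log(self):
        on = np.zeros(6); on[HIST] = 1
        rows, fracs = [], []
        # patient A (x=1): 20 history-days, 12 optimal next days
        # patient B (x=0): 20 history-days, 5 optimal next days
        day = 1
        for pid, n_opt in (("PA", 12), ("PB", 5)):
            for i in range(20):
                rows.append((pid, day, on))
                rows.append((pid, day + 1, np.zeros(6)))
                fracs.extend([1.0, 1.0 if i < n_opt else 0.5])
                day += 2
        cov = pd.DataFrame({"x": [1.0, 0.0]}, index=["PA", "PB"])
        return make_log(rows, fracs), cov

    def test_rr_matches_closed_form_risk_ratio(self):
        log, cov = self._two_by_two_log()
        out = optimal_adherence_model(log, "history", covariates=cov)
        rr = out.set_index("covariate").loc["x", "rr"]
        assert rr == pytest.approx((12 / 20) / (5 / 20), rel=1e-4)

    def test_all_optimal_outcomes_degenerate(self):
        on = np.zeros(6); on[HIST] = 1
        rows = [("P1", d, on) for d in range(1, 12)]
        log = make_log(rows, [1.0] * 11)
        with pytest.raises(ValueError, match="degenerate"):
            optimal_adherence_model(log, "history", covariates=pd.DataFrame({"x": [1.0]}, index=["P1"]))

    def test_unknown_factor_rejected(self, random_trial):
        with pytest.raises(ValueError, match="unknown factor"):
            optimal_adherence_model(random_trial, "frequency")

    def test_null_covariates_bracket_unity(self, random_trial):
        out = optimal_adherence_model(random_trial, "history")
        # race is independent of outcome in the generator: RR near 1
        rr = out.set_index("covariate").loc["race_black", "rr"]
        assert 0.5 < rr < 2.0

    def test_band_classification(self):
        assert classify_rr(1.7) == "strong_positive"
        assert classify_rr(1.2) == "positive"
        assert classify_rr(0.8) == "negative"


class TestResponseMatrixAndClustering:
    def test_low_count_cells_mean_imputed(self):
        on = np.zeros(6); on[HIST] = 1
        rows, fracs = [], []
        for d in range(1, 31):  # patient A: 30 history days of perfect adherence
            rows.append(("PA", d, on)); fracs.append(1.0)
        for d in range(1, 11):  # patient B: only 10 history days
            rows.append(("PB", d, on)); fracs.append(0.0)
        response, counts, imputed = build_response_matrix(make_log(rows, fracs), min_obs=25)
        assert not imputed.loc["PA", "history"]
        assert imputed.loc["PB", "history"]
        # imputed value is the column mean over adequately observed cells
        assert response.loc["PB", "history"] == pytest.approx(1.0)

    def test_well_separated_planted_profiles_fully_recovered(self):
        rng = np.random.default_rng(0)
        centers = {
            0: np.array([0.5, 0.5, 0.9, 0.5, 0.5, 0.5]),
            1: np.array([0.5, 0.5, 0.9, 0.9, 0.5, 0.5]),
            2: np.array([0.7, 0.7, 0.7, 0.7, 0.7, 0.7]),
        }
        truth = [0] * 9 + [1] * 4 + [2] * 16
        X = np.stack([centers[t] + rng.normal(0, 0.005, 6) for t in truth])
        response = pd.DataFrame(X, columns=FACTOR_NAMES,
                                index=[f"P{i:03d}" for i in range(29)])
        result = cluster_patients(response, k=3, seed=1)
        assert adjusted_rand_score(truth, result.assignments.to_numpy()) == 1.0
        assert sorted(result.sizes.tolist(), reverse=True) == [16, 9, 4]
        assert result.sizes.idxmax() == 1  # largest cluster labeled 1

    def test_k_one_places_everyone_together(self):
        response = pd.DataFrame(np.random.default_rng(1).random((8, 6)), columns=FACTOR_NAMES)
        result = cluster_patients(response, k=1, seed=0)
        assert (result.assignments == 1).all()

    def test_patient_order_invariance(self):
        rng = np.random.default_rng(2)
        response = pd.DataFrame(rng.random((20, 6)), columns=FACTOR_NAMES,
                                index=[f"P{i:03d}" for i in range(20)])
        a = cluster_patients(response, k=3, seed=4)
        perm = rng.permutation(20)
        b = cluster_patients(response.iloc[perm], k=3, seed=4)
        joined = pd.concat([a.assignments.rename("a"), b.assignments.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_k_exceeding_patients_rejected(self):
        response = pd.DataFrame(np.zeros((3, 6)), columns=FACTOR_NAMES)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_patients(response, k=5)


def _clusters(labels):
    ids = [f"P{i:03d}" for i in range(len(labels))]
    s = pd.Series(labels, index=ids, name="cluster")
    return ClusterResult(assignments=s, centroids=np.zeros((len(set(labels)), 6)),
                         sizes=s.value_counts().sort_index(), inertia=0.0)


class TestClusterMembership:
    def test_odds_ratios_match_contingency_closed_form(self):
        labels = [1] * 10 + [2] * 8 + [3] * 6   # referent = cluster 1 (largest)
        x = [1] * 4 + [0] * 6 + [1] * 6 + [0] * 2 + [1] * 2 + [0] * 4
        contrasts = pd.DataFrame({"x": x}, index=[f"P{i:03d}" for i in range(24)])
        out = cluster_membership_model(_clusters(labels), contrasts=contrasts)
        out = out.set_index("cluster")
        # OR(cluster 2) = (6*6)/(2*4); OR(cluster 3) = (2*6)/(4*4)
        assert out.loc[2, "odds_ratio"] == pytest.approx(4.5, rel=1e-3)
        assert out.loc[3, "odds_ratio"] == pytest.approx(0.75, rel=1e-3)
        assert (out["referent"] == 1).all()

    def test_constant_covariate_gives_sentinel(self):
        labels = [1] * 6 + [2] * 4
        contrasts = pd.DataFrame({"x": [1] * 10}, index=[f"P{i:03d}" for i in range(10)])
        out = cluster_membership_model(_clusters(labels), contrasts=contrasts)
        assert (out["note"] == SEPARATION_SENTINEL).all()

    def test_perfect_separation_gives_sentinel_not_number(self):
        labels = [1] * 6 + [2] * 4
        x = [0] * 6 + [1] * 4  # covariate perfectly identifies cluster 2
        contrasts = pd.DataFrame({"x": x}, index=[f"P{i:03d}" for i in range(10)])
        out = cluster_membership_model(_clusters(labels), contrasts=contrasts)
        assert out.iloc[0]["note"] == SEPARATION_SENTINEL
        assert np.isnan(out.iloc[0]["odds_ratio"])

    def test_empty_referent_rejected(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_membership_model(_clusters([1] * 5), contrasts=pd.DataFrame({"x": [1] * 5}))

    def test_full_pipeline_on_simulated_trial(self, random_trial):
        response, counts, imputed = build_response_matrix(random_trial)
        result = cluster_patients(response, k=3, seed=0)
        out = cluster_membership_model(result, cohort=random_trial.cohort)
        assert {"covariate", "cluster", "odds_ratio", "note"} <= set(out.columns)
        numeric = out[out["note"] == ""]
        assert (numeric["ci_low"] <= numeric["odds_ratio"]).all()
        assert (numeric["odds_ratio"] <= numeric["ci_high"]).all()
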