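import numpy as np
import pytest

from bandittrial.bandit import (
    FEATURE_NAMES,
    BanditState,
    ContextFeatures,
    decide,
    decision_probabilities,
    feature_importance,
    featurize,
    predict_reward,
    update,
)
from bandittrial.catalog import FACTOR_NAMES, FactorVector, Framing

HIST = FACTOR_NAMES.index("history")
SOC = FACTOR_NAMES.index("social")

PATIENT = {
    "age": 70.0,
    "sex": "female",
    "race_ethnicity": "black",
    "education": "postgrad",
    "married_partnered": True,
    "n_medications": 2,
    "insulin_use": False,
    "activation": True,
    "employment": False,
    "baseline_hba1c": 9.8,
    "class_metformin": True,
    "class_sulfonylurea": False,
    "class_sglt2": False,
}


class TestFeaturize:
    def test_hand_built_expected_vector(self):
        ctx = featurize(PATIENT, days_since_factor=[3, 60, 0, 15, 1, 7], taken_already=True)
        expected = np.array([
            1.0,            # intercept
            1.0,            # (70 - 60) / 10
            0.5,            # female
            0.5,            # race black
            -0.5,           # race other
            -0.5,           # edu some college
            0.5,            # edu postgrad
            0.5,            # married
            0.5,            # n_medications - 1.5
            -0.5,           # insulin
            0.5,            # activation
            -0.5,           # employment
            0.8,            # hba1c - 9
            0.5, -0.5, -0.5,  # therapeutic classes
            3 / 30 - 0.5,   # days since positive framing
            0.5,            # capped at 30 -> 1.0, centered
            -0.5,           # sent today-adjacent: 0 days
            0.0,            # 15/30 - 0.5
            1 / 30 - 0.5,
            7 / 30 - 0.5,
            0.5,            # taken already
        ])
        np.testing.assert_allclose(ctx.vector, expected)
        assert ctx.names == FEATURE_NAMES

    def test_identical_patients_identical_encodings(self):
        a = featurize(PATIENT, [1] * 6, False)
        b = featurize(dict(PATIENT), [1] * 6, False)
        np.testing.assert_array_equal(a.vector, b.vector)

    def test_missing_baseline_field_rejected(self):
        broken = {k: v for k, v in PATIENT.items() if k != "activation"}
        with pytest.raises(ValueError, match="activation"):
            featurize(broken, [1] * 6, False)

    def test_negative_days_since_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            featurize(PATIENT, [-1, 0, 0, 0, 0, 0], False)


def tiny_state(**kw) -> BanditState:
    return BanditState(feature_names=("intercept", "a", "b"), **kw)


def tiny_ctx(x=(1.0, 2.0, -1.0)) -> ContextFeatures:
    return ContextFeatures(names=("intercept", "a", "b"), vector=np.array(x))


class TestDecide:
    def test_greedy_includes_positive_advantage(self):
        st = tiny_state(epsilon=0.0)
        st.w_factor[HIST, 0] = 0.2  # advantage 0.2 via intercept
        d = decide(st, tiny_ctx(), np.random.default_rng(0))
        assert d.history is True
        assert d.social is False  # zero advantage excludes

    def test_full_exploration_frequencies(self, rng):
        st = BanditState(epsilon=1.0)
        ctx = featurize(PATIENT, [1] * 6, False)
        draws = [decide(st, ctx, rng) for _ in range(10_000)]
        hist_rate = np.mean([d.history for d in draws])
        assert hist_rate == pytest.approx(0.5, abs=0.02)
        framings = np.array([d.framing.value for d in draws])
        # both-include ties resolve to neutral: 50 / 25 / 25
        assert np.mean(framings == "neutral") == pytest.approx(0.50, abs=0.02)
        assert np.mean(framings == "positive") == pytest.approx(0.25, abs=0.02)
        assert np.mean(framings == "negative") == pytest.approx(0.25, abs=0.02)

    def test_framing_never_both_levels(self, rng):
        st = BanditState(epsilon=0.7)
        st.w_factor[0, 0] = 0.4
        st.w_factor[1, 0] = 0.4
        ctx = featurize(PATIENT, [2] * 6, False)
        for _ in range(500):
            d = decide(st, ctx, rng)
            assert not (d.framing is Framing.positive and d.framing is Framing.negative)


class TestPredictReward:
    def test_zero_weights_prior_mean(self):
        st = tiny_state()
        assert predict_reward(st, tiny_ctx(), FactorVector(history=True)) == 0.5

    def test_hand_computed_dot_product(self):
        st = tiny_state()
        st.w_base[:] = [0.05, 0.02, 0.01]
        st.w_factor[HIST] = [0.1, -0.05, 0.0]
        st.w_factor[SOC] = [0.03, 0.0, 0.02]
        st.w_pair[HIST, SOC] = 0.04
        x = (1.0, 2.0, -1.0)
        d = FactorVector(history=True, social=True)
        expected = 0.5
        expected += 0.05 * 1 + 0.02 * 2 + 0.01 * -1          # base
        expected += 0.1 * 1 + -0.05 * 2 + 0.0 * -1           # history block
        expected += 0.03 * 1 + 0.0 * 2 + 0.02 * -1           # social block
        expected += 0.04                                      # pair
        assert predict_reward(st, tiny_ctx(x), d) == pytest.approx(expected)

    def test_interaction_contribution_is_linear(self):
        st = tiny_state()
        st.w_factor[HIST] = [0.02, 0.01, 0.0]
        d = FactorVector(history=True)
        base = st.score(tiny_ctx(), d)
        st.w_factor[HIST] *= 2
        assert st.score(tiny_ctx(), d) == pytest.approx(2 * base)

    def test_clipped_to_unit_interval(self):
        st = tiny_state()
        st.w_base[0] = 5.0
        assert predict_reward(st, tiny_ctx(), FactorVector()) == 1.0
        st.w_base[0] = -5.0
        assert predict_reward(st, tiny_ctx(), FactorVector()) == 0.0


class TestUpdate:
    def test_zero_learning_rate_noop(self):
        st = tiny_state(learning_rate=0.0)
        before = (st.w_base.copy(), st.w_factor.copy(), st.w_pair.copy())
        update(st, tiny_ctx(), FactorVector(history=True), reward=1.0)
        np.testing.assert_array_equal(st.w_base, before[0])
        np.testing.assert_array_equal(st.w_factor, before[1])
        np.testing.assert_array_equal(st.w_pair, before[2])
        assert st.update_count == 1

    def test_hand_computed_normalized_step(self):
        # independent arithmetic oracle for the documented update rule
        st = tiny_state(epsilon=0.2, learning_rate=0.5, ips_cap=10.0)
        st.w_base[:] = [0.1, 0.0, 0.0]
        x = np.array([1.0, 2.0, -1.0])
        d = FactorVector(history=True, social=True)
        update(st, tiny_ctx(), d, reward=1.0)

        # by hand: advantages are 0 for both included flags -> greedy action is
        # "exclude", so each realized include had probability eps/2 = 0.1,
        # ips weight min(1/0.1, 10) = 10.  score = w_base.x = 0.1.
        e = (0.5 + 0.1) - 1.0
        x2 = 1.0 + 4.0 + 1.0
        gain = x2 + (10 + 10) * x2 + 1  # base + two factor blocks + one pair
        s = 0.5 * e / gain
        np.testing.assert_allclose(st.w_base, np.array([0.1, 0.0, 0.0]) - s * x)
        np.testing.assert_allclose(st.w_factor[HIST], -s * 10 * x)
        np.testing.assert_allclose(st.w_factor[SOC], -s * 10 * x)
        assert st.w_pair[HIST, SOC] == pytest.approx(-s)
        assert st.w_factor[0].sum() == 0.0  # untouched blocks stay zero

    def test_repeated_event_converges_monotonically(self):
        st = BanditState(epsilon=0.2, learning_rate=0.05)
        ctx = featurize(PATIENT, [1] * 6, False)
        d = FactorVector(history=True)
        preds = []
        for _ in range(500):
            update(st, ctx, d, reward=1.0)
            preds.append(predict_reward(st, ctx, d))
        assert preds[-1] > 0.95
        burned = preds[50:]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(burned, burned[1:]))

    def test_reward_range_enforced(self):
        st = tiny_state()
        with pytest.raises(ValueError, match="reward"):
            update(st, tiny_ctx(), FactorVector(), reward=1.2)
        with pytest.raises(ValueError, match="reward"):
            update(st, tiny_ctx(), FactorVector(), reward=float("nan"))

    def test_decision_probabilities_match_epsilon_greedy(self):
        st = tiny_state(epsilon=0.4)
        st.w_factor[HIST, 0] = 1.0
        probs = decision_probabilities(st, tiny_ctx(), FactorVector(history=True))
        assert probs[HIST] == pytest.approx(1 - 0.2)  # matches greedy include
        assert probs[SOC] == pytest.approx(1 - 0.2)   # matches greedy exclude


class TestFeatureImportance:
    def test_requires_trained_state(self):
        with pytest.raises(ValueError, match="update"):
            feature_importance(BanditState(), top_k=5)

    def test_ranked_descending_with_planted_dominant_interaction(self):
        st = BanditState()
        st.update_count = 1
        st.w_factor[HIST, FEATURE_NAMES.index("hba1c_c")] = 10.0
        st.w_base[1] = 1.0
        st.w_pair[HIST, SOC] = -2.0
        top = feature_importance(st, top_k=20)
        assert len(top) == 20
        assert top[0][0] == "history x hba1c_c"
        mags = [m for _, m in top]
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_zero_state_all_zero_magnitudes(self):
        st = BanditState()
        st.update_count = 3
        assert all(m == 0.0 for _, m in feature_importance(st, top_k=10))
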