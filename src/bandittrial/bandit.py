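"""Per-factor contextual-bandit personalization engine.

One shared linear model scores daily message compositions.  Each of the six
binary inclusion decisions (positive framing, negative framing, history,
social, informational content, reflective question) is taken epsilon-greedily
on its own predicted-reward advantage; the model is trained online with
inverse-propensity-weighted stochastic gradient steps on the squared error
between predicted and observed reward (next-day pill-bottle adherence in
[0, 1]).

The predicted reward for context ``x`` and decision vector ``d`` is

    r_hat = clip( 0.5 + w_base . x + sum_f d_f (v_f . x) + sum_{f<g} d_f d_g c_fg , 0, 1)

where ``x`` includes an intercept, so the untrained model predicts the prior
mean 0.5 for every message.  The ``v_f . x`` blocks are the factor-by-context
interactions (the intercept component of ``v_f`` is the factor main effect)
and ``c_fg`` are factor-by-factor interactions.  The design follows the
simplest published contextual-bandit recipe consistent with deciding each
message aspect separately; the deployed commercial personalization system it
stands in for does not disclose its internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import json
import numpy as np

from .catalog import FACTOR_NAMES, N_FACTORS, FactorVector

#: Days-since saturation: never-sent factors and long gaps cap at this value
#: before scaling, keeping the feature bounded and monotone.
DAYS_SINCE_CAP = 30.0

#: Deterministic context encoding, one name per component.
FEATURE_NAMES: tuple[str, ...] = (
    "intercept",
    "age_std",              # (age - 60) / 10
    "female",
    "race_black",
    "race_other",
    "edu_some_college",
    "edu_postgrad",
    "married_partnered",
    "n_medications_c",      # n_medications - 1
    "insulin_use",
    "activation",
    "employment",
    "hba1c_c",              # baseline HbA1c - 9
    "class_metformin",
    "class_sulfonylurea",
    "class_sglt2",
    "days_since_framing_positive",
    "days_since_framing_negative",
    "days_since_history",
    "days_since_social",
    "days_since_content_informational",
    "days_since_reflective",
    "taken_already",
)
N_CONTEXT = len(FEATURE_NAMES)

_BASELINE_FIELDS = (
    "age",
    "sex",
    "race_ethnicity",
    "education",
    "married_partnered",
    "n_medications",
    "insulin_use",
    "activation",
    "employment",
    "baseline_hba1c",
    "class_metformin",
    "class_sulfonylurea",
    "class_sglt2",
)


@dataclass(frozen=True)
class ContextFeatures:
    """A named, fixed-length encoding of one decision context."""

    names: tuple[str, ...]
    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=float))
        if len(self.names) != self.vector.shape[0]:
            raise ValueError("feature names and vector length differ")


def featurize(
    patient: Mapping[str, object],
    days_since_factor: Sequence[float],
    taken_already: bool,
) -> ContextFeatures:
    """Encode the daily decision context for one patient.

    ``days_since_factor`` holds, per factor indicator, the number of days
    since that factor was last included; for a never-sent factor the caller
    passes the current day index (days since study start).  Values are capped
    at 30, scaled to [0, 1], then centered.

    All binary and bounded components are centered at 0.5 (and the continuous
    components at cohort-typical values), which decorrelates the intercept
    from the covariate directions and greatly improves the conditioning of
    the online least-squares updates: factor-by-covariate interaction weights
    then learn differential response directly rather than through a shared
    offset.
    """
    for f in _BASELINE_FIELDS:
        if f not in patient or patient[f] is None:
            raise ValueError(f"missing baseline field: {f!r}")
    ds = np.asarray(days_since_factor, dtype=float)
    if ds.shape != (N_FACTORS,):
        raise ValueError("days_since_factor must have one entry per factor indicator")
    if (ds < 0).any():
        raise ValueError("days_since_factor entries must be nonnegative")

    edu = str(patient["education"])
    race = str(patient["race_ethnicity"])
    vec = np.array(
        [
            1.0,
            (float(patient["age"]) - 60.0) / 10.0,
            (1.0 if str(patient["sex"]) == "female" else 0.0) - 0.5,
            (1.0 if race == "black" else 0.0) - 0.5,
            (1.0 if race == "other" else 0.0) - 0.5,
            (1.0 if edu == "some_college" else 0.0) - 0.5,
            (1.0 if edu == "postgrad" else 0.0) - 0.5,
            float(bool(patient["married_partnered"])) - 0.5,
            float(int(patient["n_medications"])) - 1.5,
            float(bool(patient["insulin_use"])) - 0.5,
            float(bool(patient["activation"])) - 0.5,
            float(bool(patient["employment"])) - 0.5,
            float(patient["baseline_hba1c"]) - 9.0,
            float(bool(patient["class_metformin"])) - 0.5,
            float(bool(patient["class_sulfonylurea"])) - 0.5,
            float(bool(patient["class_sglt2"])) - 0.5,
            *(np.minimum(ds, DAYS_SINCE_CAP) / DAYS_SINCE_CAP - 0.5),
            float(bool(taken_already)) - 0.5,
        ]
    )
    return ContextFeatures(names=FEATURE_NAMES, vector=vec)


_FPOS, _FNEG = 0, 1  # indices of the framing indicators in FACTOR_NAMES


@dataclass
class BanditState:
    """Weights and hyperparameters of the online learner."""

    feature_names: tuple[str, ...] = FEATURE_NAMES
    epsilon: float = 0.2
    epsilon_decay: float = 0.0
    epsilon_floor: float = 0.02
    learning_rate: float = 0.02
    ips_cap: float = 10.0
    update_count: int = 0
    w_base: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_factor: np.ndarray = field(default=None)  # type: ignore[assignment]
    w_pair: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        if self.w_base is None:
            self.w_base = np.zeros(d)
        if self.w_factor is None:
            self.w_factor = np.zeros((N_FACTORS, d))
        if self.w_pair is None:
            self.w_pair = np.zeros((N_FACTORS, N_FACTORS))
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")

    # -- scoring ----------------------------------------------------------
    def _check(self, context: ContextFeatures) -> np.ndarray:
        if context.names != self.feature_names:
            raise ValueError("context encoding does not match this state")
        return context.vector

    def score(self, context: ContextFeatures, decision: FactorVector) -> float:
        """Linear score (uncentered, unclipped)."""
        x = self._check(context)
        d = decision.indicators()
        s = float(self.w_base @ x) + float(d @ (self.w_factor @ x))
        iu = np.triu_indices(N_FACTORS, k=1)
        s += float((np.outer(d, d)[iu] * self.w_pair[iu]).sum())
        return s

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "epsilon": self.epsilon,
                "epsilon_decay": self.epsilon_decay,
                "epsilon_floor": self.epsilon_floor,
                "learning_rate": self.learning_rate,
                "ips_cap": self.ips_cap,
                "update_count": self.update_count,
                "w_base": self.w_base.tolist(),
                "w_factor": self.w_factor.tolist(),
                "w_pair": self.w_pair.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "BanditState":
        d = json.loads(payload)
        return cls(
            feature_names=tuple(d["feature_names"]),
            epsilon=d["epsilon"],
            epsilon_decay=d["epsilon_decay"],
            epsilon_floor=d["epsilon_floor"],
            learning_rate=d["learning_rate"],
            ips_cap=d["ips_cap"],
            update_count=d["update_count"],
            w_base=np.array(d["w_base"]),
            w_factor=np.array(d["w_factor"]),
            w_pair=np.array(d["w_pair"]),
        )


def predict_reward(
    state: BanditState, context: ContextFeatures, decision: FactorVector
) -> float:
    """Predicted reward for a (context, decision) pair, clipped to [0, 1]."""
    return float(np.clip(0.5 + state.score(context, decision), 0.0, 1.0))


def _deltas(state: BanditState, x: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Include-vs-exclude advantage of each factor given the other flags."""
    cross = (state.w_pair + state.w_pair.T) @ d  # uses upper triangle both ways
    return state.w_factor @ x + cross


def decide(
    state: BanditState, context: ContextFeatures, rng: np.random.Generator
) -> FactorVector:
    """Epsilon-greedy per-factor decision with framing resolution.

    Factors are decided in :data:`~bandittrial.catalog.FACTOR_NAMES` order;
    each flag is greedy on its predicted-reward advantage given the flags
    already decided (include iff advantage > 0; ties exclude), replaced by a
    fair coin with probability epsilon.  If both framing learners vote to
    include, the one with the higher advantage wins; an exact tie resolves to
    neutral framing.
    """
    x = state._check(context)
    d = np.zeros(N_FACTORS)
    for f in range(N_FACTORS):
        adv = float(state.w_factor[f] @ x)
        for g in range(f):
            adv += d[g] * float(state.w_pair[min(f, g), max(f, g)])
        greedy = adv > 0.0
        if rng.random() < state.epsilon:
            d[f] = float(rng.integers(2))
        else:
            d[f] = float(greedy)
    if d[_FPOS] and d[_FNEG]:
        others = d.copy()
        others[_FPOS] = others[_FNEG] = 0.0
        adv = _deltas(state, x, others)
        if adv[_FPOS] > adv[_FNEG]:
            d[_FNEG] = 0.0
        elif adv[_FNEG] > adv[_FPOS]:
            d[_FPOS] = 0.0
        else:
            d[_FPOS] = d[_FNEG] = 0.0
    return FactorVector.from_indicators(d)


def decision_probabilities(
    state: BanditState, context: ContextFeatures, decision: FactorVector
) -> np.ndarray:
    """Probability each flag of ``decision`` had under the epsilon-greedy pass.

    Replays the sequential pass (greedy advantage given the earlier flags of
    the realized decision): a flag matching its greedy action has probability
    1 - epsilon/2, otherwise epsilon/2.  Framing resolution is not folded in,
    which makes this a policy-probability approximation used only for
    importance weighting (weights are capped anyway).
    """
    x = state._check(context)
    d = decision.indicators()
    probs = np.empty(N_FACTORS)
    for f in range(N_FACTORS):
        adv = float(state.w_factor[f] @ x)
        for g in range(f):
            adv += d[g] * float(state.w_pair[min(f, g), max(f, g)])
        greedy = float(adv > 0.0)
        probs[f] = 1.0 - state.epsilon / 2.0 if d[f] == greedy else state.epsilon / 2.0
    return probs


def update(
    state: BanditState,
    context: ContextFeatures,
    decision: FactorVector,
    reward: float,
) -> BanditState:
    """One normalized, IPS-weighted gradient step toward the observed reward.

    With prediction error ``e = (0.5 + score) - reward`` (unclipped score, so
    the gradient never saturates), per-factor importance weights
    ``i_f = min(1 / p_f, ips_cap)`` (``p_f`` the policy probability of the
    realized flag, so rarely taken actions learn faster), and the update
    gain ``G = |x|^2 + sum_{f included} i_f |x|^2 + #included pairs``, the
    step ``s = learning_rate * e / G`` is applied as

    * ``w_base -= s * x``
    * ``v_f    -= s * i_f * x``  for each included factor f
    * ``c_fg   -= s``            for each included pair f < g

    so each event moves the prediction exactly ``learning_rate * e`` toward
    the reward — a normalized LMS step that is stable for any learning rate
    below 1 regardless of the context scale.  Missing rewards must be
    handled by the caller (no update).  Epsilon decays linearly per update
    when ``epsilon_decay > 0``, floored at ``epsilon_floor``.
    """
    if reward is None or np.isnan(reward) or not 0.0 <= reward <= 1.0:
        raise ValueError(f"reward must be in [0, 1], got {reward!r}")
    x = state._check(context)
    d = decision.indicators()
    e = (0.5 + state.score(context, decision)) - reward
    probs = decision_probabilities(state, context, decision)
    ips = np.minimum(1.0 / probs, state.ips_cap)
    x2 = float(x @ x)
    n_pairs = 0
    for f in range(N_FACTORS):
        for g in range(f + 1, N_FACTORS):
            if d[f] and d[g]:
                n_pairs += 1
    gain = x2 + float((d * ips).sum()) * x2 + n_pairs
    s = state.learning_rate * e / gain
    state.w_base -= s * x
    for f in range(N_FACTORS):
        if d[f]:
            state.w_factor[f] -= s * ips[f] * x
    for f in range(N_FACTORS):
        for g in range(f + 1, N_FACTORS):
            if d[f] and d[g]:
                state.w_pair[f, g] -= s
    state.update_count += 1
    if state.epsilon_decay > 0:
        state.epsilon = max(state.epsilon_floor, state.epsilon - state.epsilon_decay)
    return state


def feature_importance(state: BanditState, top_k: int = 20) -> list[tuple[str, float]]:
    """Model weights ranked by absolute magnitude (descending).

    Names base-context weights by feature, factor-context interaction weights
    as ``"<factor> x <feature>"`` (the intercept component is the factor main
    effect), and factor-factor interactions as ``"<factor> x <factor>"``.
    """
    if state.update_count < 1:
        raise ValueError("feature importance requires a state with at least one update")
    entries: list[tuple[str, float]] = []
    for name, w in zip(state.feature_names, state.w_base):
        entries.append((name, abs(float(w))))
    for f, factor in enumerate(FACTOR_NAMES):
        for name, w in zip(state.feature_names, state.w_factor[f]):
            label = factor if name == "intercept" else f"{factor} x {name}"
            entries.append((label, abs(float(w))))
    for f in range(N_FACTORS):
        for g in range(f + 1, N_FACTORS):
            entries.append(
                (f"{FACTOR_NAMES[f]} x {FACTOR_NAMES[g]}", abs(float(state.w_pair[f, g])))
            )
    entries.sort(key=lambda t: -t[1])
    return entries[: min(top_k, len(entries))]
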