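"""Trial harness: stratified block randomization and the daily trial loop.

The in-silico trial mirrors a two-arm adherence study: patients are
randomized 1:1 within four strata (self-reported missed doses <=1 / >1
crossed with baseline HbA1c < 9 / >= 9) using permuted blocks; intervention
patients then receive one composed text message per day for the follow-up
period, chosen either by the contextual bandit or by a uniform random policy,
while control patients receive no messages.  Yesterday's pill-bottle
adherence is fed back to the learner as the delayed reward for yesterday's
decision; disconnected (missing) days produce no update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .bandit import BanditState, decide, featurize, update
from .catalog import FACTOR_NAMES, N_FACTORS, Catalog, FactorVector, build_catalog, select_template
from .cohort import (
    LatentProfile,
    assign_profiles,
    generate_cohort,
    random_factor_matrix,
    simulate_day,
)
from .config import TrialConfig

_IDX = {name: i for i, name in enumerate(FACTOR_NAMES)}

MESSAGE_COLUMNS = [
    "patient_id",
    "study_day",
    "framing",
    "history",
    "social",
    "content",
    "reflective",
    "template_id",
]


@dataclass
class TrialLog:
    """Event streams and inputs of one simulated trial."""

    cohort: pd.DataFrame
    profiles: dict[str, LatentProfile]
    assignments: pd.DataFrame  # patient_id, arm, stratum
    messages: pd.DataFrame     # MESSAGE_COLUMNS
    adherence: pd.DataFrame    # patient_id, study_day, fraction_taken (NaN = missing)
    rewards: pd.DataFrame      # patient_id, decision_day, reward (NaN = missing)
    config: Optional[TrialConfig] = None
    final_state: Optional[BanditState] = None

    def intervention_ids(self) -> list[str]:
        return list(self.assignments.loc[self.assignments["arm"] == "intervention", "patient_id"])

    def control_ids(self) -> list[str]:
        return list(self.assignments.loc[self.assignments["arm"] == "control", "patient_id"])


def patient_stratum(row: pd.Series) -> str:
    missed = ">1" if str(row["baseline_missed_doses"]) == ">1" else "<=1"
    hba1c = ">=9" if float(row["baseline_hba1c"]) >= 9.0 else "<9"
    return f"missed{missed}|hba1c{hba1c}"


def block_randomize(
    cohort: pd.DataFrame, block_size: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Permuted-block 1:1 assignment within the four design strata.

    Within each stratum, assignments come from successive random permutations
    of a half-intervention/half-control block, so any prefix is within
    ``block_size / 2`` of perfect balance.  Deterministic given the seed.
    """
    if block_size % 2:
        raise ValueError(f"block_size must be even, got {block_size}")
    rng = np.random.default_rng(seed)
    strata = cohort.apply(patient_stratum, axis=1)
    arm = pd.Series(index=cohort.index, dtype=object)
    half = block_size // 2
    for stratum in sorted(strata.unique()):
        idx = cohort.index[strata == stratum]
        assigned: list[str] = []
        while len(assigned) < len(idx):
            block = ["intervention"] * half + ["control"] * half
            order = rng.permutation(block_size)
            assigned.extend(block[i] for i in order)
        arm.loc[idx] = assigned[: len(idx)]
    return pd.DataFrame(
        {
            "patient_id": cohort["patient_id"].to_numpy(),
            "arm": arm.to_numpy(),
            "stratum": strata.to_numpy(),
        }
    )


def _factor_vector_row(fv: FactorVector) -> dict[str, object]:
    return {
        "framing": fv.framing.value,
        "history": bool(fv.history),
        "social": bool(fv.social),
        "content": fv.content.value,
        "reflective": bool(fv.reflective),
    }


def _sustained_gaps(
    patient_ids: list[str], cfg: TrialConfig, rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    """Optionally plant one long disconnection window (start_day, end_day) per patient."""
    sim = cfg.simulator
    gaps: dict[str, tuple[int, int]] = {}
    if sim.sustained_disconnect_prob <= 0:
        return gaps
    for pid in patient_ids:
        if rng.random() < sim.sustained_disconnect_prob:
            latest_start = max(2, cfg.follow_up_days - sim.sustained_gap_days + 1)
            start = int(rng.integers(2, latest_start + 1))
            gaps[pid] = (start, min(cfg.follow_up_days, start + sim.sustained_gap_days - 1))
    return gaps


def run_trial(config: TrialConfig) -> TrialLog:
    """Run the full in-silico trial; the log is a pure function of the config."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=6)
    sim = config.simulator

    cohort = generate_cohort(config.n_patients, sim.marginals, seed=int(seeds[0]))
    profiles = assign_profiles(
        cohort,
        cluster_mix=sim.cluster_mix,
        effect_scale=sim.effect_scale,
        carryover_scale=sim.carryover_scale,
        seed=int(seeds[1]),
        propensity_mean=sim.propensity_mean,
        propensity_sd=sim.propensity_sd,
        disconnect_rate=sim.disconnect_rate,
    )
    if sim.single_factor is not None:
        if sim.single_factor not in _IDX:
            raise ValueError(f"unknown factor {sim.single_factor!r}")
        for p in profiles.values():
            p.factor_effects[:] = 0.0
            p.factor_effects[_IDX[sim.single_factor]] = sim.effect_scale
            p.carryover_effects[:] = 0.0
    assignments = block_randomize(cohort, config.block_size, seed=int(seeds[2]))
    catalog = build_catalog(config.n_templates_per_set, seed=int(seeds[3]))

    rng = np.random.default_rng(int(seeds[4]))
    gap_rng = np.random.default_rng(int(seeds[5]))

    arm_of = dict(zip(assignments["patient_id"], assignments["arm"]))
    int_ids = [pid for pid in cohort["patient_id"] if arm_of[pid] == "intervention"]
    ctl_ids = [pid for pid in cohort["patient_id"] if arm_of[pid] == "control"]
    patients = {row["patient_id"]: row for _, row in cohort.iterrows()}
    gaps = _sustained_gaps(list(cohort["patient_id"]), config, gap_rng)

    if config.policy == "random":
        return _run_random_policy(
            config, cohort, profiles, assignments, catalog, int_ids, ctl_ids, gaps, rng
        )

    bp = config.bandit
    state = BanditState(
        epsilon=bp.epsilon,
        epsilon_decay=bp.epsilon_decay,
        epsilon_floor=bp.epsilon_floor,
        learning_rate=bp.learning_rate,
        ips_cap=bp.ips_cap,
    )

    last_sent = {pid: np.zeros(N_FACTORS) for pid in int_ids}  # 0 = never sent
    pending: dict[str, tuple] = {}   # pid -> (context, decision, fraction or None)
    prev_factors: dict[str, Optional[FactorVector]] = {pid: None for pid in int_ids}

    msg_rows: list[dict] = []
    adh_rows: list[dict] = []
    rew_rows: list[dict] = []

    for day in range(1, config.follow_up_days + 1):
        for pid in int_ids:
            # deliver yesterday's reward before today's decision
            if pid in pending:
                ctx_y, dec_y, frac_y = pending.pop(pid)
                rew_rows.append(
                    {"patient_id": pid, "decision_day": day - 1,
                     "reward": np.nan if frac_y is None else frac_y}
                )
                if frac_y is not None:
                    update(state, ctx_y, dec_y, frac_y)

            taken_already = rng.random() < sim.taken_already_rate
            ds = np.where(last_sent[pid] > 0, day - last_sent[pid], day)
            ctx = featurize(patients[pid], ds, taken_already)
            dec = decide(state, ctx, rng)
            tmpl = select_template(catalog, dec, rng)
            msg_rows.append(
                {"patient_id": pid, "study_day": day, **_factor_vector_row(dec),
                 "template_id": tmpl.template_id}
            )
            frac = simulate_day(profiles[pid], patients[pid], dec, prev_factors[pid], rng)
            if pid in gaps and gaps[pid][0] <= day <= gaps[pid][1]:
                frac = None
            adh_rows.append(
                {"patient_id": pid, "study_day": day,
                 "fraction_taken": np.nan if frac is None else frac}
            )
            ind = dec.indicators()
            last_sent[pid] = np.where(ind > 0, day, last_sent[pid])
            prev_factors[pid] = dec
            pending[pid] = (ctx, dec, frac)

        for pid in ctl_ids:
            frac = simulate_day(profiles[pid], patients[pid], None, None, rng)
            if pid in gaps and gaps[pid][0] <= day <= gaps[pid][1]:
                frac = None
            adh_rows.append(
                {"patient_id": pid, "study_day": day,
                 "fraction_taken": np.nan if frac is None else frac}
            )

    return TrialLog(
        cohort=cohort,
        profiles=profiles,
        assignments=assignments,
        messages=pd.DataFrame(msg_rows, columns=MESSAGE_COLUMNS),
        adherence=pd.DataFrame(adh_rows, columns=["patient_id", "study_day", "fraction_taken"]),
        rewards=pd.DataFrame(rew_rows, columns=["patient_id", "decision_day", "reward"]),
        config=config,
        final_state=state,
    )


def _run_random_policy(
    config: TrialConfig,
    cohort: pd.DataFrame,
    profiles: dict[str, LatentProfile],
    assignments: pd.DataFrame,
    catalog: Catalog,
    int_ids: list[str],
    ctl_ids: list[str],
    gaps: dict[str, tuple[int, int]],
    rng: np.random.Generator,
) -> TrialLog:
    """Vectorized non-adaptive arm: uniform random factor selection.

    Statistically matches the epsilon=1 bandit but runs orders of magnitude
    faster, which the replicate-heavy calibration studies rely on.
    """
    from .cohort import simulate_adherence_matrix

    T = config.follow_up_days
    n_int = len(int_ids)
    decisions = random_factor_matrix(n_int, T, rng)

    # pre-index catalog for vectorized template choice
    sets = {tuple(fs.indicators()): [t for t in catalog.templates if t.factor_set == fs]
            for fs in catalog.factor_sets()}

    msg_rows: list[dict] = []
    for i, pid in enumerate(int_ids):
        for day in range(1, T + 1):
            fv = FactorVector.from_indicators(decisions[i, day - 1])
            matches = sets[tuple(fv.indicators())]
            tmpl = matches[int(rng.integers(len(matches)))]
            msg_rows.append(
                {"patient_id": pid, "study_day": day, **_factor_vector_row(fv),
                 "template_id": tmpl.template_id}
            )

    int_profiles = [profiles[pid] for pid in int_ids]
    int_meds = cohort.set_index("patient_id").loc[int_ids, "n_medications"].to_numpy()
    frac_int = simulate_adherence_matrix(int_profiles, int_meds, decisions, T, rng)

    ctl_profiles = [profiles[pid] for pid in ctl_ids]
    ctl_meds = cohort.set_index("patient_id").loc[ctl_ids, "n_medications"].to_numpy()
    frac_ctl = simulate_adherence_matrix(ctl_profiles, ctl_meds, None, T, rng)

    adh_rows: list[dict] = []
    rew_rows: list[dict] = []
    for i, pid in enumerate(int_ids):
        for day in range(1, T + 1):
            f = frac_int[i, day - 1]
            if pid in gaps and gaps[pid][0] <= day <= gaps[pid][1]:
                f = np.nan
            adh_rows.append({"patient_id": pid, "study_day": day, "fraction_taken": f})
            if day < T:  # reward delivered next day; final day has no delivery
                rew_rows.append({"patient_id": pid, "decision_day": day, "reward": f})
    for i, pid in enumerate(ctl_ids):
        for day in range(1, T + 1):
            f = frac_ctl[i, day - 1]
            if pid in gaps and gaps[pid][0] <= day <= gaps[pid][1]:
                f = np.nan
            adh_rows.append({"patient_id": pid, "study_day": day, "fraction_taken": f})

    return TrialLog(
        cohort=cohort,
        profiles=profiles,
        assignments=assignments,
        messages=pd.DataFrame(msg_rows, columns=MESSAGE_COLUMNS),
        adherence=pd.DataFrame(adh_rows, columns=["patient_id", "study_day", "fraction_taken"]),
        rewards=pd.DataFrame(rew_rows, columns=["patient_id", "decision_day", "reward"]),
        config=config,
        final_state=None,
    )


def apply_sensitivity_filters(log: TrialLog, mode: str) -> TrialLog:
    """Sensitivity-analysis filters on a trial log.

    ``"omit_first_14_days"`` drops study days 1-14 for every patient (early
    observer effects of new pill bottles); ``"censor_30_day_gap"`` truncates
    each patient's streams at the start of their first run of >= 30
    consecutive missing adherence days (pill bottle not connected).
    """
    if mode == "omit_first_14_days":
        keep = log.adherence["study_day"] > 14
        return replace(
            log,
            adherence=log.adherence[keep].reset_index(drop=True),
            messages=log.messages[log.messages["study_day"] > 14].reset_index(drop=True),
            rewards=log.rewards[log.rewards["decision_day"] > 14].reset_index(drop=True),
        )
    if mode == "censor_30_day_gap":
        cutoffs: dict[str, int] = {}
        for pid, grp in log.adherence.groupby("patient_id"):
            grp = grp.sort_values("study_day")
            missing = grp["fraction_taken"].isna().to_numpy()
            days = grp["study_day"].to_numpy()
            run = 0
            for i, miss in enumerate(missing):
                run = run + 1 if miss else 0
                if run >= 30:
                    cutoffs[pid] = int(days[i - run + 1]) - 1
                    break
        if not cutoffs:
            return replace(log)

        def _trunc(df: pd.DataFrame, day_col: str) -> pd.DataFrame:
            cut = df["patient_id"].map(lambda p: cutoffs.get(p, np.inf))
            return df[df[day_col] <= cut].reset_index(drop=True)

        return replace(
            log,
            adherence=_trunc(log.adherence, "study_day"),
            messages=_trunc(log.messages, "study_day"),
            rewards=_trunc(log.rewards, "decision_day"),
        )
    raise ValueError(f"unknown sensitivity filter mode: {mode!r}")
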