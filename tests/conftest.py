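"""Shared fixtures.

The expensive DQN trainings (50,000 timesteps each) are session-scoped so
that property tests and acceptance-level checks share one trained model per
scenario instead of retraining.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tkirec import (
    CohortSpec,
    RewardConfig,
    TrainConfig,
    TreatmentEnvironment,
    apply_inclusion_filters,
    compute_reward,
    engineer_features,
    generate_cohort,
    train_dqn,
)
from tkirec.pipeline import modeling_table, run_pipeline


@pytest.fixture(scope="session")
def engineered_cohort() -> pd.DataFrame:
    """A filtered, engineered synthetic cohort large enough for subsampling."""
    raw = generate_cohort(CohortSpec(n_patients=600, seed=7))
    kept, _ = apply_inclusion_filters(raw)
    return engineer_features(kept)


@pytest.fixture(scope="session")
def imbalanced_dataset(engineered_cohort) -> pd.DataFrame:
    """Modelling table with the study's class sizes: 196 early-progression
    vs 122 progression-free rows, drawn from the synthetic cohort."""
    table = modeling_table(engineered_cohort)
    rng = np.random.default_rng(42)
    ones = table.index[table["progression_category"] == 1]
    zeros = table.index[table["progression_category"] == 0]
    assert len(ones) >= 196 and len(zeros) >= 122
    pick = np.concatenate(
        [rng.choice(ones, 196, replace=False), rng.choice(zeros, 122, replace=False)]
    )
    return table.loc[np.sort(pick)].reset_index(drop=True)


def make_four_stratum_fixture(seed: int = 5, n: int = 200):
    """Discrete one-step fixture: 4 one-hot strata, mixed recorded actions
    and outcomes, penalized (unmasked) scenario so all 16 (stratum, action)
    cells are reachable."""
    rng = np.random.default_rng(seed)
    strata = rng.integers(0, 4, n)
    states = np.eye(4)[strata]
    records = pd.DataFrame(
        {
            "action_code": rng.integers(0, 4, n),
            "progression_category": rng.integers(0, 2, n),
            "tki_line": np.where(rng.random(n) < 0.5, 1, 2),
        }
    )
    cfg = RewardConfig(scenario_mode="penalized")
    return states, records, strata, cfg


def brute_force_q(records: pd.DataFrame, strata: np.ndarray, cfg: RewardConfig) -> np.ndarray:
    """Monte-Carlo-free oracle: the exact per-(stratum, action) mean reward."""
    rows = records.to_dict("records")
    out = np.zeros((4, 4))
    for s in range(4):
        idx = np.flatnonzero(strata == s)
        for a in range(4):
            out[s, a] = np.mean([compute_reward(rows[i], a, cfg) for i in idx])
    return out


@pytest.fixture(scope="session")
def four_stratum_trained():
    """The discrete fixture, its brute-force Q oracle, and a 50k-step DQN."""
    states, records, strata, cfg = make_four_stratum_fixture()
    env = TreatmentEnvironment(states, records, cfg)
    qf, log = train_dqn(env, train_cfg=TrainConfig(seed=2))
    return {
        "qf": qf,
        "log": log,
        "brute": brute_force_q(records, strata, cfg),
        "states": states,
        "records": records,
        "strata": strata,
    }


def make_dominance_env(n_states: int = 60, seed: int = 9):
    """Environment where action 3 strictly dominates every state.

    All records carry action 3 with a progression-free outcome, so under the
    penalized scenario the shaped rewards are 16 / 12 / 11 / 10 for actions
    3 / 2 / 1 / 0 — a dominance margin of at least 4."""
    rng = np.random.default_rng(seed)
    states = rng.normal(size=(n_states, 6))
    records = pd.DataFrame(
        {
            "action_code": np.full(n_states, 3),
            "progression_category": np.zeros(n_states, dtype=int),
            "tki_line": np.full(n_states, 2),
        }
    )
    return TreatmentEnvironment(states, records, RewardConfig(scenario_mode="penalized"))


@pytest.fixture(scope="session")
def dominance_recovery_fractions() -> list[float]:
    """Fraction of states whose greedy action is the dominant action 3,
    for three independently seeded 50k-step trainings."""
    fractions = []
    for seed in (101, 102, 103):
        env = make_dominance_env()
        qf, _ = train_dqn(env, train_cfg=TrainConfig(seed=seed))
        greedy = qf.predict(env.states).argmax(axis=1)
        fractions.append(float(np.mean(greedy == 3)))
    return fractions


@pytest.fixture(scope="session")
def default_policy_run():
    """Full default pipeline on the default synthetic cohort, 50k steps."""
    return run_pipeline(
        cohort_spec=CohortSpec(n_patients=318, seed=0),
        train_cfg=TrainConfig(seed=0),
        seed=0,
    )
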