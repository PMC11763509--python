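"""End-to-end glue: cohort -> filters -> balance -> environment -> policy.

The canonical analysis order mirrors the study design: engineer the filtered
cohort, balance the one-year progression classes with SMOTE over the full
engineered table, take a stratified 90/10 modelling split, and train the
one-step DQN on the training portion.  (Balancing before splitting leaks
synthetic neighbours of holdout points into training; a ``split_first`` flag
reverses the order for a leakage-free variant.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balancing import SmoteConfig, smote_balance, train_eval_split
from .cohort import CohortSpec, generate_cohort
from .engineering import (
    FEATURE_COLUMNS,
    InclusionRules,
    apply_inclusion_filters,
    engineer_features,
    feature_matrix,
)
from .rl.dqn import QFunction, QNetworkSpec, TrainConfig, train_dqn
from .rl.env import TreatmentEnvironment
from .rl.rewards import RewardConfig
from .rl.scaling import standardize

MODELING_COLUMNS = FEATURE_COLUMNS + ["action_code"]


def modeling_table(engineered: pd.DataFrame) -> pd.DataFrame:
    """Feature matrix plus the recorded action and the outcome label."""
    table = feature_matrix(engineered)
    table["action_code"] = engineered["action_code"].astype(float).to_numpy()
    table["progression_category"] = engineered["progression_category"].astype(int).to_numpy()
    return table.reset_index(drop=True)


def _enforce_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Round SMOTE-interpolated categoricals and re-align action with line.

    The action code is categorical 0..3; after interpolation it is rounded,
    and the quantitative treatment-line feature is snapped to 1 for
    first-line actions and to >= 2 for later-line actions so masks stay
    well defined.
    """
    out = table.copy()
    out["action_code"] = np.rint(out["action_code"]).clip(0, 3)
    first = out["action_code"] < 2
    line = np.rint(out["line_treatment"]).clip(1, None)
    out["line_treatment"] = np.where(first, 1.0, np.maximum(line, 2.0))
    return out


def balance_modeling_table(
    engineered: pd.DataFrame, smote_cfg: SmoteConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """SMOTE-balance the engineered cohort on the progression endpoint."""
    table = modeling_table(engineered)
    features = table[MODELING_COLUMNS]
    labels = table["progression_category"]
    balanced, balanced_labels, n_synthetic = smote_balance(features, labels, smote_cfg)
    balanced = _enforce_consistency(balanced)
    balanced["progression_category"] = balanced_labels.astype(int)
    return balanced, n_synthetic


def build_environment(
    table: pd.DataFrame, reward_cfg: RewardConfig | None = None
) -> tuple[TreatmentEnvironment, "FeatureScaler"]:
    """Standardize a modelling table into a one-step treatment environment."""
    reward_cfg = reward_cfg or RewardConfig()
    states, scaler = standardize(table[FEATURE_COLUMNS])
    records = pd.DataFrame(
        {
            "action_code": table["action_code"].astype(int).to_numpy(),
            "progression_category": table["progression_category"].astype(int).to_numpy(),
            "tki_line": table["line_treatment"].astype(int).to_numpy(),
        }
    )
    return TreatmentEnvironment(states, records, reward_cfg), scaler


@dataclass
class PolicyRun:
    qfunction: QFunction
    training_log: pd.DataFrame
    train_table: pd.DataFrame
    holdout_table: pd.DataFrame
    n_synthetic: int
    exclusions: pd.DataFrame


def run_pipeline(
    raw: pd.DataFrame | None = None,
    cohort_spec: CohortSpec | None = None,
    rules: InclusionRules | None = None,
    smote_cfg: SmoteConfig | None = None,
    reward_cfg: RewardConfig | None = None,
    train_cfg: TrainConfig | None = None,
    train_fraction: float = 0.9,
    split_first: bool = False,
    seed: int = 0,
) -> PolicyRun:
    """Run the full analysis and return the trained policy with its tables."""
    if raw is None:
        raw = generate_cohort(cohort_spec or CohortSpec(seed=seed))
    kept, exclusions = apply_inclusion_filters(raw, rules)
    engineered = engineer_features(kept)
    smote_cfg = smote_cfg or SmoteConfig(seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)

    if split_first:
        base = modeling_table(engineered)
        train_raw, holdout = train_eval_split(base, train_fraction, seed=seed)
        balanced_features, balanced_labels, n_synthetic = smote_balance(
            train_raw[MODELING_COLUMNS], train_raw["progression_category"], smote_cfg
        )
        train = _enforce_consistency(balanced_features)
        train["progression_category"] = balanced_labels.astype(int)
    else:
        balanced, n_synthetic = balance_modeling_table(engineered, smote_cfg)
        train, holdout = train_eval_split(balanced, train_fraction, seed=seed)

    env, scaler = build_environment(train, reward_cfg)
    qf, log = train_dqn(
        env,
        QNetworkSpec(input_dim=env.states.shape[1]),
        train_cfg,
        scaler=scaler,
        feature_columns=list(scaler.columns),
    )
    return PolicyRun(
        qfunction=qf,
        training_log=log,
        train_table=train,
        holdout_table=holdout,
        n_synthetic=n_synthetic,
        exclusions=exclusions,
    )
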