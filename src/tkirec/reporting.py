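"""Reports and recommendations from a trained treatment policy.

Summaries of the learned Q-function over a patient set (per-action
mean/sd/min/max), greedy action frequencies split by treatment line, partial
dependence of Q-values on individual features, a ranking AUC for comparing
the policy against supervised classifiers, and the single-patient
recommender that backs the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .engineering import ACTION_LABELS
from .rl.dqn import QFunction
from .rl.rewards import action_mask

_ACTION_COLUMNS = ["action_0", "action_1", "action_2", "action_3"]

#: Raw fields the recommender needs to build a feature row.
RECOMMEND_FIELDS = [
    "age",
    "gender",
    "ecog",
    "mutation",
    "smoking",
    "n_mets_cat",
    "bone_or_liver_met",
    "brain_met",
    "comorbidity",
    "neutrophils",
    "lymphocytes",
    "tki_line",
]


@dataclass
class Recommendation:
    action: int
    label: str
    q_values: list[float]
    scenario: str  # "first-line" or "later-line"
    masked_actions: list[int]

    def to_dict(self) -> dict:
        return {
            "action": self.action,
            "label": self.label,
            "q_values": self.q_values,
            "scenario": self.scenario,
            "masked_actions": self.masked_actions,
        }


def summarize_q(qf: QFunction, states: np.ndarray) -> pd.DataFrame:
    """Per-action mean, sd, min and max of Q over a state set.

    Rows are mean/sd/min/max, columns action_0..action_3 — the layout used
    for Q-value summary tables.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if len(states) == 0:
        raise ValueError("need at least one state to summarize")
    q = qf.predict(states)
    sd = q.std(axis=0, ddof=1) if len(q) > 1 else np.zeros(4)
    return pd.DataFrame(
        [q.mean(axis=0), sd, q.min(axis=0), q.max(axis=0)],
        index=["mean", "sd", "min", "max"],
        columns=_ACTION_COLUMNS,
    )


def action_frequencies(
    qf: QFunction, states: np.ndarray, line_flags, masked: bool = True
) -> pd.DataFrame:
    """Greedy action counts split into first-line and later-line scenarios.

    ``line_flags`` holds the recorded line of each patient (1 = first-line).
    With ``masked=True`` actions inconsistent with the patient's line are
    unavailable, so their counts are structurally zero.
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    line_flags = np.asarray(line_flags)
    if len(line_flags) != len(states):
        raise ValueError("line_flags and states must have the same length")
    q = qf.predict(states)
    if masked:
        masks = np.stack([action_mask(line) for line in line_flags])
        q = np.where(masks, q, -np.inf)
    choices = q.argmax(axis=1)
    out = pd.DataFrame(0, index=["first-line", "later-line"], columns=_ACTION_COLUMNS)
    for scenario, mask in (("first-line", line_flags == 1), ("later-line", line_flags != 1)):
        counts = np.bincount(choices[mask], minlength=4)
        out.loc[scenario] = counts
    return out


def partial_dependence(
    qf: QFunction, states: np.ndarray, feature: str, grid
) -> pd.DataFrame:
    """Mean Q per action as one feature sweeps a grid of raw values.

    For each grid value the feature column is overwritten (on the
    standardized scale, via the stored scaler) in every state and the
    Q-values averaged; the result is a len(grid) x 4 curve per action.
    """
    if feature not in qf.scaler.columns:
        raise ValueError(f"unknown feature {feature!r}")
    j = qf.scaler.columns.index(feature)
    states = np.atleast_2d(np.asarray(states, dtype=float)).copy()
    rows = []
    for g in np.asarray(grid, dtype=float):
        states[:, j] = qf.scaler.transform_value(feature, g)
        rows.append(qf.predict(states).mean(axis=0))
    return pd.DataFrame(rows, index=np.asarray(grid, dtype=float), columns=_ACTION_COLUMNS)


def policy_score_auc(qf: QFunction, states: np.ndarray, recorded_actions, outcomes) -> float:
    """Ranking quality of the policy's value estimates for observed care.

    Each patient is scored by the Q-value of the action they actually
    received (standardized across patients; AUC is invariant to monotone
    transforms) and the score is ranked against the progression-free-year
    outcome (1 = progression-free >= 12 months).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    recorded_actions = np.asarray(recorded_actions, dtype=int)
    outcomes = np.asarray(outcomes, dtype=int)
    if len(np.unique(outcomes)) < 2:
        raise ValueError("outcomes contain a single class; AUC undefined")
    q = qf.predict(states)
    scores = q[np.arange(len(q)), recorded_actions]
    scores = (scores - scores.mean()) / (scores.std() or 1.0)
    return float(roc_auc_score(outcomes, scores))


def record_to_features(patient: dict) -> pd.DataFrame:
    """Engineer a single raw patient dict into a one-row feature table."""
    missing = [f for f in RECOMMEND_FIELDS if f not in patient or patient[f] is None]
    if missing:
        raise ValueError(f"patient record is missing fields: {', '.join(missing)}")
    if float(patient["lymphocytes"]) <= 0 or float(patient["neutrophils"]) <= 0:
        raise ValueError("neutrophil and lymphocyte counts must be positive")
    return pd.DataFrame(
        [
            {
                "logage": math.log(float(patient["age"])),
                "lognlr": math.log(float(patient["neutrophils"]) / float(patient["lymphocytes"])),
                "line_treatment": float(patient["tki_line"]),
                "gender_female": float(patient["gender"] == "female"),
                "ecog_high": float(patient["ecog"] == "2-4"),
                "mutation_other": float(patient["mutation"] != "exon19"),
                "smoking_current": float(patient["smoking"] == "current"),
                "mets_4plus": float(patient["n_mets_cat"] == "4plus"),
                "bone_or_liver_met": float(patient["bone_or_liver_met"]),
                "brain_met": float(patient["brain_met"]),
                "comorbidity": float(patient["comorbidity"]),
            }
        ]
    )


def recommend(qf: QFunction, patient: dict) -> Recommendation:
    """Recommend a TKI action for one raw patient record.

    Actions whose treatment-line half disagrees with the patient's recorded
    line are masked; the recommendation is the argmax of the remaining
    Q-values, ties broken toward the lowest action code.
    """
    features = record_to_features(patient)
    state = qf.scaler.transform(features, warn_out_of_range=True)
    q = qf.predict(state)[0]
    line = int(patient["tki_line"])
    mask = action_mask(line)
    masked_q = np.where(mask, q, -np.inf)
    action = int(masked_q.argmax())
    return Recommendation(
        action=action,
        label=ACTION_LABELS[action],
        q_values=[float(v) for v in q],
        scenario="first-line" if line == 1 else "later-line",
        masked_actions=[int(a) for a in np.flatnonzero(~mask)],
    )


def frequency_plot(frequencies: pd.DataFrame, path) -> None:
    """Grouped bar chart of greedy action counts per scenario."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for ax, scenario in zip(axes, frequencies.index):
        ax.bar(range(4), frequencies.loc[scenario], color="#4878a8")
        ax.set_xticks(range(4), [str(a) for a in range(4)])
        ax.set_title(scenario)
        ax.set_xlabel("action")
    axes[0].set_ylabel("patients")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def partial_dependence_plot(curves: pd.DataFrame, feature: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        ax.plot(curves.index, curves[col], label=col.replace("_", " "))
    ax.set_xlabel(feature)
    ax.set_ylabel("mean Q")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
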