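"""Reward shaping for the one-step treatment decision.

Each episode scores a single treatment choice against what actually happened
to the patient.  Matching the recorded action is rewarded according to the
observed outcome (a progression-free year pays more than early progression);
choosing a different action than the recorded one yields a neutral
"mismatch" reward between the two, because the counterfactual outcome is
unobserved.  A small additive bonus favours second-or-higher-generation TKIs
(actions 1 and 3), encoding the external evidence that newer-generation
agents prolong progression-free survival.

The line of the first TKI branches the decision into two scenarios.  In
``masked`` mode (default) actions whose line half disagrees with the
patient's recorded line are simply unavailable: first-line patients choose
between actions 0 and 1, later-line patients between 2 and 3.  In
``penalized`` mode all four actions are available but a line-inconsistent
choice pays a fixed penalty.

IMPORTANT CAVEAT — off-policy gap: the data record only the outcome of the
treatment actually given.  The neutral mismatch reward is a modelling choice,
not an estimate of the counterfactual outcome; ``counterfactual`` lets
callers plug in their own estimator for mismatched (record, action) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

#: Actions that use a second-or-higher-generation TKI.
HIGHER_GENERATION_ACTIONS = (1, 3)


@dataclass
class RewardConfig:
    """Reward table over (scenario, action, outcome).

    Defaults put expected rewards in the low teens, a convenient scale for
    reading Q-value summaries; only their ordering matters for the learned
    policy.
    """

    scenario_mode: str = "masked"  # or "penalized"
    match_good: float = 15.0  # chose the recorded action, progression-free year
    match_bad: float = 10.0  # chose the recorded action, progression < 12 months
    mismatch: float = 12.0  # chose an action the patient did not receive
    generation_bonus: float = 1.0  # additive, actions 1 and 3
    line_inconsistency_penalty: float = 2.0  # "penalized" mode only
    counterfactual: Optional[Callable] = None  # (record, action) -> base reward

    def validate(self) -> None:
        if self.scenario_mode not in ("masked", "penalized"):
            raise ValueError(f"unknown scenario_mode {self.scenario_mode!r}")
        if not self.match_good > self.match_bad:
            raise ValueError("match_good must exceed match_bad")
        if self.generation_bonus < 0:
            raise ValueError("generation_bonus must be non-negative")

    def to_dict(self) -> dict:
        return {
            "scenario_mode": self.scenario_mode,
            "match_good": self.match_good,
            "match_bad": self.match_bad,
            "mismatch": self.mismatch,
            "generation_bonus": self.generation_bonus,
            "line_inconsistency_penalty": self.line_inconsistency_penalty,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RewardConfig":
        return cls(**payload)


def compute_reward(record, action: int, cfg: RewardConfig) -> float:
    """Reward for recommending ``action`` to a patient with known outcome.

    ``record`` needs ``action_code``, ``progression_category`` and
    ``tki_line`` attributes or keys (a pandas row works).
    """
    if action not in (0, 1, 2, 3):
        raise ValueError(f"action must be in 0..3, got {action!r}")
    cfg.validate()

    def get(name):
        if hasattr(record, name):
            return getattr(record, name)
        return record[name]

    recorded = int(get("action_code"))
    category = int(get("progression_category"))

    if action == recorded:
        base = cfg.match_good if category == 0 else cfg.match_bad
    elif cfg.counterfactual is not None:
        base = float(cfg.counterfactual(record, action))
    else:
        base = cfg.mismatch

    reward = base
    if action in HIGHER_GENERATION_ACTIONS:
        reward += cfg.generation_bonus
    if cfg.scenario_mode == "penalized":
        first_line = int(get("tki_line")) == 1
        action_first = action < 2
        if first_line != action_first:
            reward -= cfg.line_inconsistency_penalty
    return float(reward)


def action_mask(tki_line: int) -> np.ndarray:
    """Boolean availability of actions 0..3 given the recorded treatment line."""
    if int(tki_line) < 1:
        raise ValueError(f"tki_line must be >= 1, got {tki_line!r}")
    if int(tki_line) == 1:
        return np.array([True, True, False, False])
    return np.array([False, False, True, True])
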