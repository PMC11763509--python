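"""One-step episodic treatment environment.

The decision problem is a contextual bandit: each episode draws one patient
uniformly at random, the agent recommends one of the four TKI actions for
that patient's state, receives the shaped reward, and the episode terminates.
There are no state transitions — the clinical data record a single treatment
decision per patient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rewards import RewardConfig, action_mask, compute_reward


class TreatmentEnvironment:
    """Holds standardized patient states, their records, and the reward rule."""

    def __init__(self, states: np.ndarray, records: pd.DataFrame, reward_cfg: RewardConfig):
        states = np.asarray(states, dtype=float)
        if states.ndim != 2 or len(states) == 0:
            raise ValueError("environment needs a non-empty 2-D state matrix")
        if len(states) != len(records):
            raise ValueError("states and records must align row for row")
        reward_cfg.validate()
        self.states = states
        self.records = records.reset_index(drop=True)
        self.reward_cfg = reward_cfg

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_actions(self) -> int:
        return 4

    def sample(self, rng: np.random.Generator) -> int:
        """Uniformly sample a patient index for the next episode."""
        return int(rng.integers(0, self.n_states))

    def mask(self, index: int) -> np.ndarray:
        """Action availability for patient ``index`` under the scenario mode."""
        if self.reward_cfg.scenario_mode == "masked":
            return action_mask(int(self.records.iloc[index]["tki_line"]))
        return np.ones(4, dtype=bool)

    def reward(self, index: int, action: int) -> float:
        return compute_reward(self.records.iloc[index], action, self.reward_cfg)


def run_episode(
    env: TreatmentEnvironment, action_selector, rng: np.random.Generator
) -> tuple[np.ndarray, int, float, bool]:
    """Play one episode: sample a patient, decide, collect the reward.

    ``action_selector`` is called as ``selector(state, mask, rng)`` and must
    return an unmasked action.  The terminal flag is always True — one
    decision per patient.
    """
    index = env.sample(rng)
    state = env.states[index]
    mask = env.mask(index)
    action = int(action_selector(state, mask, rng))
    if not mask[action]:
        raise ValueError(f"selector chose masked action {action}")
    reward = env.reward(index, action)
    return state, action, reward, True
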