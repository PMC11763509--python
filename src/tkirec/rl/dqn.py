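"""Deep Q-learning with Boltzmann exploration for one-step episodes.

Training follows the classic DQN recipe — experience replay, a periodically
synced target network, squared TD error minimized by Adam — specialized to
the one-step episodic treatment environment.  Every episode is terminal, so
the TD target reduces to the immediate reward and the learned Q-values
converge toward the expected shaped reward of each (state, action) pair; the
discount factor is carried through the implementation for completeness but
cannot influence the fixed point.

Exploration is Boltzmann (softmax) action sampling: the probability of
action ``a`` is proportional to ``exp(Q_a / tau)``.  High temperatures
explore uniformly, low temperatures exploit the current Q estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .env import TreatmentEnvironment
from .network import Adam, QNetwork
from .rewards import RewardConfig
from .scaling import FeatureScaler


@dataclass
class QNetworkSpec:
    input_dim: int
    hidden: tuple[int, int] = (64, 64)
    output_dim: int = 4

    def dims(self) -> tuple[int, ...]:
        if self.output_dim != 4:
            raise ValueError("the treatment action space has exactly 4 actions")
        return (self.input_dim, *self.hidden, self.output_dim)


@dataclass
class TrainConfig:
    total_timesteps: int = 50_000
    learning_rate: float = 1e-3
    #: Learning rate is annealed linearly to this fraction of its initial
    #: value by the final timestep; 1.0 keeps it constant.  Annealing damps
    #: the steady-state oscillation of Adam around the TD fixed point, which
    #: matters because rewards vary within each (state, action) cell.
    final_lr_fraction: float = 0.02
    gamma: float = 0.99
    batch_size: int = 32
    replay_capacity: int = 10_000
    target_update_interval: int = 500
    tau: float = 2.0  # Boltzmann temperature
    seed: int = 0
    log_window: int = 500

    def validate(self) -> None:
        if self.total_timesteps < 1:
            raise ValueError("total_timesteps must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.batch_size < 1 or self.replay_capacity < self.batch_size:
            raise ValueError("need replay_capacity >= batch_size >= 1")
        if not 0.0 < self.final_lr_fraction <= 1.0:
            raise ValueError("final_lr_fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "total_timesteps": self.total_timesteps,
            "learning_rate": self.learning_rate,
            "final_lr_fraction": self.final_lr_fraction,
            "gamma": self.gamma,
            "batch_size": self.batch_size,
            "replay_capacity": self.replay_capacity,
            "target_update_interval": self.target_update_interval,
            "tau": self.tau,
            "seed": self.seed,
            "log_window": self.log_window,
        }


def boltzmann_select(
    q: np.ndarray, tau: float, rng: np.random.Generator, mask: np.ndarray | None = None
) -> int:
    """Sample an action with probability proportional to exp(q_a / tau).

    The maximum is subtracted before exponentiation for overflow safety;
    masked actions receive probability zero.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("Q-values must be finite")
    logits = q / tau
    if mask is not None:
        logits = np.where(mask, logits, -np.inf)
        if not np.any(mask):
            raise ValueError("all actions masked")
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return int(rng.choice(len(q), p=p))


def boltzmann_probabilities(q: np.ndarray, tau: float, mask: np.ndarray | None = None) -> np.ndarray:
    """The Boltzmann action distribution itself (useful for tests and reports)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    logits = np.asarray(q, dtype=float) / tau
    if mask is not None:
        logits = np.where(mask, logits, -np.inf)
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


@dataclass
class QFunction:
    """A trained Q-network plus everything needed to score raw records."""

    network: QNetwork
    scaler: FeatureScaler
    reward_cfg: RewardConfig
    train_cfg: TrainConfig
    feature_columns: list[str] = field(default_factory=list)

    def predict(self, states: np.ndarray) -> np.ndarray:
        """Q-values for already-standardized states; (n, 4), always finite."""
        q = self.network.forward(states)
        if not np.all(np.isfinite(q)):
            raise ValueError("Q-network produced non-finite values")
        return q

    def save(self, path) -> None:
        payload = {
            "network": self.network.to_dict(),
            "scaler": self.scaler.to_dict(),
            "reward_cfg": self.reward_cfg.to_dict(),
            "train_cfg": self.train_cfg.to_dict(),
            "feature_columns": list(self.feature_columns),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "QFunction":
        payload = json.loads(Path(path).read_text())
        return cls(
            network=QNetwork.from_dict(payload["network"]),
            scaler=FeatureScaler.from_dict(payload["scaler"]),
            reward_cfg=RewardConfig.from_dict(payload["reward_cfg"]),
            train_cfg=TrainConfig(**payload["train_cfg"]),
            feature_columns=list(payload["feature_columns"]),
        )


def predict_q(qf: QFunction, record: pd.DataFrame | dict, scaler: FeatureScaler | None = None) -> np.ndarray:
    """Score one raw (unstandardized) record; returns a finite 4-vector.

    Values outside the training range are still scored, with a warning that
    the Q-values are extrapolations.
    """
    scaler = scaler or qf.scaler
    if isinstance(record, dict):
        record = pd.DataFrame([record])
    state = scaler.transform(record, warn_out_of_range=True)
    return qf.predict(state)[0]


def train_dqn(
    env: TreatmentEnvironment,
    qspec: QNetworkSpec | None = None,
    train_cfg: TrainConfig | None = None,
    scaler: FeatureScaler | None = None,
    feature_columns: list[str] | None = None,
) -> tuple[QFunction, pd.DataFrame]:
    """Train a Q-network on the treatment environment.

    Returns the trained QFunction and a training log with the mean reward
    per ``log_window`` timesteps.  All randomness (initialization,
    exploration, replay sampling) flows from one generator seeded with
    ``train_cfg.seed``, so identical inputs reproduce bit-identical models.
    """
    cfg = train_cfg or TrainConfig()
    cfg.validate()
    spec = qspec or QNetworkSpec(input_dim=env.states.shape[1])
    if spec.input_dim != env.states.shape[1]:
        raise ValueError("QNetworkSpec input_dim does not match the environment states")

    rng = np.random.default_rng(cfg.seed)
    online = QNetwork(spec.dims(), rng)
    target = QNetwork(spec.dims(), rng)
    target.copy_from(online)
    optimizer = Adam(online, lr=cfg.learning_rate)

    cap = cfg.replay_capacity
    buf_state = np.zeros((cap, env.states.shape[1]))
    buf_action = np.zeros(cap, dtype=int)
    buf_reward = np.zeros(cap)
    buf_size = 0
    buf_pos = 0

    log_rows = []
    window_rewards: list[float] = []

    for step in range(1, cfg.total_timesteps + 1):
        index = env.sample(rng)
        state = env.states[index]
        mask = env.mask(index)
        q = online.forward(state)[0]
        action = boltzmann_select(q, cfg.tau, rng, mask=mask)
        reward = env.reward(index, action)

        buf_state[buf_pos] = state
        buf_action[buf_pos] = action
        buf_reward[buf_pos] = reward
        buf_pos = (buf_pos + 1) % cap
        buf_size = min(buf_size + 1, cap)
        window_rewards.append(reward)

        if buf_size >= cfg.batch_size:
            batch = rng.integers(0, buf_size, size=cfg.batch_size)
            # Episodes are terminal, so the bootstrap term gamma * max Q'(s')
            # vanishes and the target is the immediate reward.
            targets = buf_reward[batch]
            loss, grad_w, grad_b = online.gradients(buf_state[batch], buf_action[batch], targets)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at timestep {step} "
                    f"(lr={cfg.learning_rate}, batch mean reward={targets.mean():.3f})"
                )
            frac = step / cfg.total_timesteps
            optimizer.lr = cfg.learning_rate * (1.0 - (1.0 - cfg.final_lr_fraction) * frac)
            optimizer.step(online, grad_w, grad_b)

        if step % cfg.target_update_interval == 0:
            target.copy_from(online)

        if step % cfg.log_window == 0:
            log_rows.append({"timestep": step, "mean_reward": float(np.mean(window_rewards))})
            window_rewards = []

    qf = QFunction(
        network=online,
        scaler=scaler
        or FeatureScaler(
            columns=[f"x{i}" for i in range(env.states.shape[1])],
            mean=np.zeros(env.states.shape[1]),
            sd=np.ones(env.states.shape[1]),
            feature_min=env.states.min(axis=0),
            feature_max=env.states.max(axis=0),
        ),
        reward_cfg=env.reward_cfg,
        train_cfg=cfg,
        feature_columns=feature_columns or [],
    )
    return qf, pd.DataFrame(log_rows)


def greedy_actions(qf: QFunction, states: np.ndarray, masks: np.ndarray | None = None) -> np.ndarray:
    """Argmax policy over (optionally masked) Q-values; ties -> lowest code."""
    q = qf.predict(states)
    if masks is not None:
        q = np.where(masks, q, -np.inf)
    return q.argmax(axis=1)
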