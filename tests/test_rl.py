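"""Standardization, rewards, Boltzmann exploration and DQN training."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkirec.rl import (
    QNetworkSpec,
    RewardConfig,
    TrainConfig,
    TreatmentEnvironment,
    action_mask,
    boltzmann_probabilities,
    boltzmann_select,
    compute_reward,
    predict_q,
    run_episode,
    standardize,
    train_dqn,
)

# ---------------------------------------------------------- standardization


def test_standardize_centers_and_scales():
    rng = np.random.default_rng(0)
    table = pd.DataFrame(rng.normal(5, 3, size=(200, 3)), columns=list("abc"))
    states, scaler = standardize(table)
    assert np.abs(states.mean(axis=0)).max() < 1e-9
    assert np.abs(states.std(axis=0) - 1).max() < 1e-9
    assert scaler.dropped == []


def test_zero_variance_column_is_dropped_and_recorded():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "const": [7.0, 7.0, 7.0]})
    states, scaler = standardize(table)
    assert states.shape == (3, 1)
    assert scaler.dropped == ["const"]
    assert scaler.columns == ["a"]


def test_scaler_reapplication_is_idempotent():
    rng = np.random.default_rng(1)
    table = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    states, scaler = standardize(table)
    assert np.array_equal(scaler.transform(table), states)


def test_scaler_names_missing_features():
    table = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
    _, scaler = standardize(table)
    with pytest.raises(ValueError, match="b"):
        scaler.transform(table[["a"]])


# ------------------------------------------------------------------ rewards


def _record(action_code=0, progression_category=0, tki_line=1):
    return {
        "action_code": action_code,
        "progression_category": progression_category,
        "tki_line": tki_line,
    }


def test_reward_match_table():
    cfg = RewardConfig(generation_bonus=0.0)
    assert compute_reward(_record(0, 0), 0, cfg) == cfg.match_good
    assert compute_reward(_record(0, 1), 0, cfg) == cfg.match_bad
    assert compute_reward(_record(0, 0), 2, cfg) == cfg.mismatch


def test_generation_bonus_is_additive():
    cfg = RewardConfig(generation_bonus=1.5)
    rec = _record(action_code=0, progression_category=0, tki_line=2)
    # Actions 2 and 3 both mismatch the recorded action; their difference is
    # exactly the generation bonus.
    assert compute_reward(rec, 3, cfg) - compute_reward(rec, 2, cfg) == pytest.approx(1.5)


def test_line_penalty_only_in_penalized_mode():
    rec = _record(action_code=3, progression_category=0, tki_line=2)
    masked = RewardConfig(scenario_mode="masked", generation_bonus=0.0)
    penal = RewardConfig(scenario_mode="penalized", generation_bonus=0.0,
                         line_inconsistency_penalty=2.5)
    assert compute_reward(rec, 0, masked) == masked.mismatch
    assert compute_reward(rec, 0, penal) == penal.mismatch - 2.5
    assert compute_reward(rec, 3, penal) == penal.match_good


def test_counterfactual_hook_overrides_mismatch():
    cfg = RewardConfig(generation_bonus=0.0, counterfactual=lambda rec, a: 99.0)
    assert compute_reward(_record(0, 0), 2, cfg) == 99.0
    assert compute_reward(_record(0, 0), 0, cfg) == cfg.match_good  # hook not used on match


def test_reward_validates_action_and_config():
    with pytest.raises(ValueError):
        compute_reward(_record(), 4, RewardConfig())
    with pytest.raises(ValueError, match="match_good"):
        compute_reward(_record(), 0, RewardConfig(match_good=5.0, match_bad=9.0))


def test_action_mask_by_line():
    assert action_mask(1).tolist() == [True, True, False, False]
    assert action_mask(3).tolist() == [False, False, True, True]


# ---------------------------------------------------------------- Boltzmann


def test_boltzmann_symmetry_and_closed_form():
    p = boltzmann_probabilities(np.array([1.0, 1.0, 1.0, 1.0]), tau=7.3)
    assert np.allclose(p, 0.25, atol=1e-12)
    p = boltzmann_probabilities(
        np.array([0.0, math.log(2.0), 0.0, 0.0]), tau=1.0,
        mask=np.array([True, True, False, False]),
    )
    assert p[0] == pytest.approx(1 / 3, abs=1e-12)
    assert p[1] == pytest.approx(2 / 3, abs=1e-12)
    assert p[2] == p[3] == 0.0


def test_boltzmann_low_temperature_limit_is_argmax():
    q = np.array([14.0, 14.1, 13.5, 14.7])
    p = boltzmann_probabilities(q, tau=1e-3)
    assert p[3] == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(0)
    assert all(boltzmann_select(q, 1e-3, rng) == 3 for _ in range(20))


def test_boltzmann_high_temperature_limit_is_uniform():
    q = np.array([14.0, 14.1, 13.5, 14.7])
    p = boltzmann_probabilities(q, tau=1e6)
    assert np.abs(p - 0.25).max() < 1e-3


def test_boltzmann_survives_huge_q_values():
    p = boltzmann_probabilities(np.array([1e8, 1e8 - 1.0, 0.0, -1e8]), tau=1.0)
    assert np.isfinite(p).all()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@given(
    q=st.lists(st.floats(min_value=-50, max_value=50), min_size=4, max_size=4),
    tau=st.floats(min_value=0.05, max_value=100.0),
)
@settings(deadline=None, max_examples=80)
def test_boltzmann_probabilities_sum_to_one_and_are_monotone(q, tau):
    p = boltzmann_probabilities(np.array(q), tau)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    order = np.argsort(q)
    assert (np.diff(p[order]) >= -1e-12).all()


def test_boltzmann_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        boltzmann_select(np.zeros(4), 0.0, np.random.default_rng(0))


# -------------------------------------------------------------- environment


def _tiny_env(n=4, seed=0, mode="penalized"):
    rng = np.random.default_rng(seed)
    states = np.eye(n)
    records = pd.DataFrame(
        {
            "action_code": rng.integers(0, 4, n),
            "progression_category": rng.integers(0, 2, n),
            "tki_line": np.where(rng.random(n) < 0.5, 1, 2),
        }
    )
    return TreatmentEnvironment(states, records, RewardConfig(scenario_mode=mode))


def test_singleton_environment_always_serves_its_patient():
    env = _tiny_env(n=1)
    rng = np.random.default_rng(1)
    for _ in range(5):
        state, action, reward, done = run_episode(
            env, lambda s, m, r: int(np.flatnonzero(m)[0]), rng
        )
        assert np.array_equal(state, env.states[0])
        assert done is True


def test_episode_sampling_is_uniform_multinomial():
    env = _tiny_env(n=4)
    rng = np.random.default_rng(2)
    counts = np.zeros(4)
    for _ in range(10_000):
        state, *_ = run_episode(env, lambda s, m, r: int(np.flatnonzero(m)[0]), rng)
        counts[int(state.argmax())] += 1
    bound = 3 * math.sqrt(10_000 * 0.25 * 0.75)
    assert (np.abs(counts - 2500) < bound).all()


def test_selector_must_respect_the_mask():
    env = _tiny_env(n=3, mode="masked")
    idx = int(np.flatnonzero(env.records["tki_line"] == 1)[0])
    with pytest.raises(ValueError, match="masked"):
        env_selector = lambda s, m, r: 3  # later-line action for everyone
        # force sampling of a first-line patient
        class FixedRng:
            def integers(self, lo, hi):
                return idx
        run_episode(env, env_selector, FixedRng())


def test_empty_environment_rejected():
    with pytest.raises(ValueError):
        TreatmentEnvironment(np.empty((0, 3)), pd.DataFrame(), RewardConfig())


# --------------------------------------------------------------------- DQN


def test_training_is_bit_reproducible():
    env = _tiny_env(n=6, seed=3)
    cfg = TrainConfig(total_timesteps=3000, seed=42)
    qf1, log1 = train_dqn(env, train_cfg=cfg)
    qf2, log2 = train_dqn(env, train_cfg=cfg)
    assert np.array_equal(qf1.predict(env.states), qf2.predict(env.states))
    pd.testing.assert_frame_equal(log1, log2)


def test_one_step_q_matches_brute_force_mean_reward(four_stratum_trained):
    """For terminal one-step episodes the optimal Q is the expected
    immediate reward; the trained network must match the per-(stratum,
    action) brute-force average within 0.5."""
    qf = four_stratum_trained["qf"]
    brute = four_stratum_trained["brute"]
    q = qf.predict(np.eye(4))
    assert np.abs(q - brute).max() < 0.5


def test_training_log_reports_reward_windows(four_stratum_trained):
    log = four_stratum_trained["log"]
    assert list(log.columns) == ["timestep", "mean_reward"]
    assert log["timestep"].iloc[-1] == 50_000
    assert log["mean_reward"].notna().all()
    # Exploitation should lift the collected reward over training.
    assert log["mean_reward"].iloc[-1] >= log["mean_reward"].iloc[0]


def test_masked_training_never_selects_cross_line_actions():
    env = _tiny_env(n=8, seed=4, mode="masked")
    qf, _ = train_dqn(env, train_cfg=TrainConfig(total_timesteps=2000, seed=0))
    q = qf.predict(env.states)
    lines = env.records["tki_line"].to_numpy()
    masks = np.stack([action_mask(line) for line in lines])
    greedy = np.where(masks, q, -np.inf).argmax(axis=1)
    assert ((greedy < 2) == (lines == 1)).all()


def test_network_spec_must_match_environment():
    env = _tiny_env(n=4)
    with pytest.raises(ValueError, match="input_dim"):
        train_dqn(env, qspec=QNetworkSpec(input_dim=7), train_cfg=TrainConfig(total_timesteps=10))


def test_zero_timestep_budget_rejected():
    env = _tiny_env(n=4)
    with pytest.raises(ValueError):
        train_dqn(env, train_cfg=TrainConfig(total_timesteps=0))


def test_predict_q_is_pure_and_warns_on_extrapolation(four_stratum_trained):
    qf = four_stratum_trained["qf"]
    record = {f"x{i}": 0.5 for i in range(4)}
    v1 = predict_q(qf, dict(record))
    v2 = predict_q(qf, dict(record))
    assert np.array_equal(v1, v2)
    assert v1.shape == (4,)
    assert np.isfinite(v1).all()
    record["x0"] = 200.0  # far outside the training range
    with pytest.warns(UserWarning, match="training range"):
        extrapolated = predict_q(qf, record)
    assert np.isfinite(extrapolated).all()


def test_predict_q_names_missing_features(four_stratum_trained):
    qf = four_stratum_trained["qf"]
    with pytest.raises(ValueError, match="x3"):
        predict_q(qf, {"x0": 0.0, "x1": 0.0, "x2": 0.0})


def test_qfunction_round_trips_through_json(tmp_path, four_stratum_trained):
    qf = four_stratum_trained["qf"]
    path = tmp_path / "model.json"
    qf.save(path)
    from tkirec.rl.dqn import QFunction

    loaded = QFunction.load(path)
    states = np.eye(4)
    assert np.allclose(loaded.predict(states), qf.predict(states), atol=1e-12)
    assert loaded.train_cfg == qf.train_cfg


def test_raising_generation_bonus_never_lowers_higher_generation_share():
    rng = np.random.default_rng(6)
    n = 80
    states = rng.normal(size=(n, 5))
    records = pd.DataFrame(
        {
            "action_code": rng.integers(0, 4, n),
            "progression_category": rng.integers(0, 2, n),
            "tki_line": np.where(rng.random(n) < 0.7, 1, 2),
        }
    )
    shares = []
    for bonus in (0.0, 3.0):
        env = TreatmentEnvironment(states, records, RewardConfig(generation_bonus=bonus))
        qf, _ = train_dqn(env, train_cfg=TrainConfig(total_timesteps=10_000, seed=5))
        masks = np.stack([action_mask(line) for line in records["tki_line"]])
        greedy = np.where(masks, qf.predict(states), -np.inf).argmax(axis=1)
        shares.append(float(np.isin(greedy, (1, 3)).mean()))
    assert shares[1] >= shares[0]
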