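import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqreplay.agents import simulate_agent
from seqreplay.behavior import (AgentParams, ChoiceModel, RarityTrace,
                                ValueState, choice_probabilities, fit_model,
                                nll_choices, rarity_series, update_rarity,
                                value_update)
from seqreplay.task import TaskConfig, generate_task_schedule


def test_value_update_delta_rule():
    st0 = ValueState.initial()
    st0.q[0, 0, 0] = 4.5
    new = value_update(st0, 0, 0, 0, 0, reward=9.0, alpha=0.5)
    assert new.q[0, 0, 0] == pytest.approx(6.75)
    assert new.v[0] == pytest.approx(6.75)
    # all other entries untouched
    assert np.all(new.q[1] == 4.5) and np.all(new.v[1:] == 4.5)


@pytest.mark.parametrize("alpha,expected", [(0.0, 4.5), (1.0, 9.0)])
def test_value_update_boundary_rates(alpha, expected):
    new = value_update(ValueState.initial(), 0, 0, 0, 0, 9.0, alpha)
    assert new.q[0, 0, 0] == pytest.approx(expected)


def test_value_update_rejects_bad_alpha():
    with pytest.raises(ValueError, match="alpha"):
        value_update(ValueState.initial(), 0, 0, 0, 0, 9.0, 1.5)


def test_softmax_closed_form():
    st0 = ValueState.initial()
    st0.v[0], st0.v[1] = 6.75, 4.5
    p = choice_probabilities(st0, 0, 0, AgentParams(0.5, 1.0), model="mb")
    assert p[0] == pytest.approx(1 / (1 + math.exp(-2.25)), abs=1e-6)
    assert p.sum() == pytest.approx(1.0)


def test_equal_values_symmetric_choice():
    p = choice_probabilities(ValueState.initial(), 1, 1,
                             AgentParams(0.5, 3.0, 0.7), model="hybrid")
    assert p == pytest.approx([0.5, 0.5])


def test_hybrid_boundaries_equal_pure_controllers(rng):
    st0 = ValueState.initial()
    st0.q += rng.random(st0.q.shape)
    st0.v += rng.random(st0.v.shape)
    for w, pure in [(1.0, "mb"), (0.0, "mf")]:
        ph = choice_probabilities(st0, 0, 1, AgentParams(0.3, 2.0, w), "hybrid")
        pp = choice_probabilities(st0, 0, 1, AgentParams(0.3, 2.0), pure)
        assert ph == pytest.approx(pp)


@pytest.fixture(scope="module")
def sim_data():
    sched = generate_task_schedule(TaskConfig(), 11)
    return simulate_agent(sched, AgentParams(0.5, 2.0, 0.6), "hybrid", rng=4)


def test_nll_uniform_policy_is_n_log2(sim_data):
    nll = nll_choices(sim_data, AgentParams(0.5, 0.0, 0.5), "hybrid")
    assert nll == pytest.approx(144 * math.log(2))


def test_likelihood_nesting(sim_data):
    for w, pure in [(1.0, "mb"), (0.0, "mf")]:
        full = nll_choices(sim_data, AgentParams(0.43, 3.1, w), "hybrid")
        nested = nll_choices(sim_data, AgentParams(0.43, 3.1), pure)
        assert full == pytest.approx(nested, abs=1e-12)


def test_nll_skips_missing_choice_but_updates(sim_data):
    df = sim_data.copy()
    base = nll_choices(df, AgentParams(0.5, 2.0, 0.6), "hybrid")
    df.loc[0, "choice"] = np.nan  # path and reward kept
    dropped = nll_choices(df, AgentParams(0.5, 2.0, 0.6), "hybrid")
    assert dropped < base  # one fewer likelihood term
    # value update still happened: differs from also-deleting the feedback
    df2 = sim_data.copy()
    df2.loc[0, ["choice", "path", "reward"]] = np.nan
    assert dropped != pytest.approx(nll_choices(df2, AgentParams(0.5, 2.0, 0.6),
                                                "hybrid"))


def test_values_stay_in_reward_range(sim_data):
    # boundedness follows from the delta rule; spot-check via trajectory nll
    from seqreplay.behavior import value_trajectory

    traj = value_trajectory(sim_data, AgentParams(1.0, 2.0, 0.5), "hybrid")
    assert traj["mean_value"].between(0, 9).all()


def test_fit_is_deterministic_given_seed(sim_data):
    a = fit_model(sim_data, "hybrid", n_starts=5, seed=9)
    b = fit_model(sim_data, "hybrid", n_starts=5, seed=9)
    assert a.nll == b.nll
    assert a.estimates == b.estimates
    assert a.aic == pytest.approx(2 * 3 + 2 * a.nll)
    assert a.bic == pytest.approx(3 * math.log(144) + 2 * a.nll)


def test_choice_model_rejects_multi_participant(sim_data):
    df = pd.concat([sim_data, sim_data.assign(participant=1)])
    with pytest.raises(ValueError, match="one participant"):
        ChoiceModel(df)


def test_unknown_model_rejected(sim_data):
    with pytest.raises(ValueError, match="unknown model"):
        nll_choices(sim_data, AgentParams(0.5, 1.0), "sarsa")


def test_rarity_hand_recurrence():
    trace = RarityTrace.initial(2, rate=0.10)
    new = update_rarity(trace, np.array([1.0, 0.0]))
    assert new.f[0] == pytest.approx(0.55)
    assert new.r[0] == pytest.approx(0.45)


def test_rarity_fixed_point_and_complement():
    worlds = np.zeros(200, dtype=int)
    f = rarity_series(worlds, 2, rate=0.10)
    assert np.all(np.diff(f[:, 0]) >= 0)
    assert f[-1, 0] == pytest.approx(1.0, abs=1e-3)
    # complementary indicators keep the two traces summing to 1
    worlds = np.random.default_rng(0).integers(2, size=300)
    f = rarity_series(worlds, 2, rate=0.10)
    assert np.allclose(f.sum(axis=1), 1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
       st.floats(0.01, 0.5))
def test_rarity_closed_form(indicators, rate):
    """F_t = (1-rate)^t F_0 + rate * sum (1-rate)^(t-k) I_k."""
    f = rarity_series(np.asarray(indicators), 2, rate=rate)
    t = len(indicators) - 1
    closed = (1 - rate) ** t * 0.5 + rate * sum(
        (1 - rate) ** (t - 1 - k) * (indicators[k] == 0)
        for k in range(t))
    assert f[t, 0] == pytest.approx(closed, abs=1e-10)


def test_replay_labels_off_world_change_rejected(sim_data):
    from seqreplay.behavior import fit_replay_modulated

    df = sim_data.copy()
    df["world_change"] = 0.0
    labels = pd.Series(np.nan, index=df.index, dtype=object)
    labels.iloc[5] = "high"
    with pytest.raises(ValueError, match="world-change"):
        fit_replay_modulated(df, labels, n_starts=5)
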