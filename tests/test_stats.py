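import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqreplay.agents import generate_memory_probes, simulate_cohort
from seqreplay.behavior import AgentParams
from seqreplay.stats import (derive_trial_covariates, memory_summary, rt_glm,
                             stay_glm, tost_bound_logodds, tost_equivalence)
from seqreplay.task import TaskConfig, generate_task_schedule


def _mini_table(worlds, starts, paths, rewards):
    n = len(worlds)
    return pd.DataFrame({
        "participant": 0, "trial": range(n), "world": worlds,
        "start_state": starts, "path": paths, "reward": rewards,
        "choice": [p % 2 for p in paths], "rt": 0.7, "stakes": 1,
    })


def test_covariates_reference_previous_same_world_trial():
    # world sequence 1,2,1: trial 3's covariates come from trial 1
    df = _mini_table([1, 2, 1], [0, 0, 1], [2, 4, 2], [8.0, 1.0, 5.0])
    out = derive_trial_covariates(df)
    assert out.loc[2, "stay"] == 1.0         # same path as trial 0
    assert out.loc[2, "same_start"] == 0.0   # start changed vs trial 0
    assert out.loc[2, "prev_reward"] == 8.0  # not trial 1's reward
    assert np.isnan(out.loc[0, "stay"]) and np.isnan(out.loc[1, "stay"])


def test_defined_stay_trials_count_on_full_schedule():
    sched = generate_task_schedule(TaskConfig(), 2)
    df = simulate_cohort([sched], AgentParams(0.5, 2.0, 1.0), rng=0)
    out = derive_trial_covariates(df)
    assert out["stay"].notna().sum() == 144 - 2  # first trial of each world


def test_stay_glm_distinguishes_controllers(rng):
    scheds = [generate_task_schedule(TaskConfig(n_blocks=3), s)
              for s in range(12)]
    mb = derive_trial_covariates(
        simulate_cohort(scheds, AgentParams(0.7, 3.0, 1.0), rng=1))
    mf = derive_trial_covariates(
        simulate_cohort(scheds, AgentParams(0.7, 3.0, 0.0), rng=2))
    res_mb = stay_glm(mb)
    res_mf = stay_glm(mf)
    term = "prev_reward_z:same_start"
    z_mb = float(res_mb.loc[res_mb["term"] == term, "z"].iloc[0])
    z_mf = float(res_mf.loc[res_mf["term"] == term, "z"].iloc[0])
    assert abs(z_mb) < 3.0
    assert z_mf > 3.0
    # reward main effect positive for both learners
    assert float(res_mb.loc[res_mb["term"] == "prev_reward_z", "z"].iloc[0]) > 3


def test_tost_interior_and_boundary_points():
    assert tost_equivalence(0.0, 1e-6, 0.5)["p_equiv"] < 1e-10
    at_bound = tost_equivalence(0.5, 0.1, 0.5)
    assert at_bound["p_equiv"] >= 0.5
    with pytest.raises(ValueError, match="bound"):
        tost_equivalence(0.1, 0.1, 0.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0.0, 2.0), st.floats(0.05, 1.0), st.floats(0.1, 2.0))
def test_tost_monotone_in_estimate_and_bound(est, se, b):
    p1 = tost_equivalence(est, se, b)["p_equiv"]
    p2 = tost_equivalence(est + 0.1, se, b)["p_equiv"]
    p3 = tost_equivalence(est, se, b + 0.1)["p_equiv"]
    assert p2 >= p1 - 1e-12   # larger |estimate| -> harder to claim equivalence
    assert p3 <= p1 + 1e-12   # wider bound -> easier


def test_tost_calibration_at_the_bound(rng):
    # true effect exactly at +bound: rejection rate ~ alpha
    rejections = 0
    n = 2000
    for _ in range(n):
        est = rng.normal(0.5, 0.1)
        rejections += tost_equivalence(est, 0.1, 0.5)["p_equiv"] < 0.05
    assert rejections / n == pytest.approx(0.05, abs=0.02)


def test_tost_bound_mapping():
    assert tost_bound_logodds(0.5, 1.0) == pytest.approx(0.9069, abs=1e-3)


def test_rt_shift_recovered(rng):
    scheds = [generate_task_schedule(TaskConfig(n_blocks=2), s)
              for s in range(8)]
    df = derive_trial_covariates(
        simulate_cohort(scheds, AgentParams(0.5, 2.0, 1.0), rng=3))
    res = rt_glm(df)
    est = float(res.loc[res["term"] == "different_start", "estimate"].iloc[0])
    assert est > 0  # injected 9-ms planning cost


def test_rt_single_participant_flagged():
    sched = generate_task_schedule(TaskConfig(n_blocks=1), 0)
    df = derive_trial_covariates(
        simulate_cohort([sched], AgentParams(0.5, 2.0, 1.0), rng=0))
    res = rt_glm(df)
    assert res.attrs["engine"] == "ols_single_participant"


def test_memory_summary_counting_rules():
    probes = generate_memory_probes(2, 1, 8, p_probe_correct=1.0, rng=0)
    assert memory_summary(probes)["percent_correct"] == 100.0
    # one stage wrong on one of eight probes -> 87.5% for that block
    probes.loc[(probes["participant"] == 0) & (probes["probe"] == 3)
               & (probes["stage"] == 1), "correct"] = 0
    out = memory_summary(probes)
    assert out["per_block_percent"][0] == pytest.approx((87.5 + 100) / 2)


def test_memory_chance_level_closed_form(rng):
    # chance responding with 4 options per stage: (1/4)^3 ~ 1.56%
    rows = []
    for probe in range(4000):
        for stage in range(3):
            rows.append((0, 0, probe, stage, int(rng.random() < 0.25), 1))
    probes = pd.DataFrame(rows, columns=["participant", "block", "probe",
                                         "stage", "correct", "confidence"])
    out = memory_summary(probes)
    assert out["percent_correct"] == pytest.approx(100 * 0.25 ** 3, abs=0.8)


def test_incomplete_probe_excluded():
    probes = generate_memory_probes(1, 1, 4, p_probe_correct=1.0, rng=0)
    probes = probes.drop(probes[(probes["probe"] == 0)
                                & (probes["stage"] == 2)].index)
    out = memory_summary(probes)
    assert out["n_excluded_probes"] == 1
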