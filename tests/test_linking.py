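import numpy as np
import pandas as pd
import pytest

from seqreplay.agents import simulate_cohort
from seqreplay.behavior import AgentParams, rarity_series
from seqreplay.linking import (across_participant_correlation,
                               build_regressor_table, dissociation_test,
                               lag_profile, link_glm, replay_split_labels)
from seqreplay.stats import derive_trial_covariates
from seqreplay.task import TaskConfig, generate_task_schedule


@pytest.fixture(scope="module")
def table():
    scheds = [generate_task_schedule(TaskConfig(n_blocks=2), s)
              for s in range(4)]
    df = simulate_cohort(scheds, AgentParams(0.5, 2.0, 1.0), rng=0)
    return build_regressor_table(derive_trial_covariates(df))


def test_rarity_column_matches_recurrence_oracle(table):
    grp = table[table["participant"] == 0]
    f = rarity_series(grp["world"].to_numpy(int), 2, 0.10)
    w = grp["world"].to_numpy(int)
    want = 1.0 - f[np.arange(len(grp)), 1 - w]
    assert np.allclose(grp["rarity_other"].to_numpy(), want)


def test_first_world_trials_have_undefined_start_contrast(table):
    grp = table[table["participant"] == 0]
    assert grp["different_start"].isna().sum() == 2


def test_alternating_worlds_never_leave_gap():
    df = pd.DataFrame({
        "participant": 0, "trial": range(6), "world": [0, 1, 0, 1, 0, 1],
        "start_state": 0, "path": [0, 2, 0, 2, 0, 2], "choice": 0,
        "reward": 5.0, "rt": 0.7, "stakes": 1,
    })
    t = build_regressor_table(derive_trial_covariates(df))
    assert (t["other_world_gap"].dropna() == 0).all()


def test_link_glm_recovers_injected_coupling(rng):
    # scores built directly from a known coupling to different_start
    rows = []
    for pid in range(8):
        for t in range(60):
            diff = int(rng.random() < 0.5)
            rows.append((pid, t, diff, rng.normal(0.5 * diff, 1.0)))
    df = pd.DataFrame(rows, columns=["participant", "trial",
                                     "different_start", "score"])
    table = df[["participant", "trial", "different_start"]]
    res = link_glm(df[["participant", "trial", "score"]], table,
                   ["different_start"])
    row = res[res["term"] == "different_start"].iloc[0]
    assert row["estimate"] == pytest.approx(0.5, abs=0.15)
    assert row["p"] < 1e-4


def test_link_glm_null_regressor_covered(rng):
    rows = [(pid, t, int(rng.random() < 0.5), rng.normal())
            for pid in range(8) for t in range(60)]
    df = pd.DataFrame(rows, columns=["participant", "trial",
                                     "different_start", "score"])
    res = link_glm(df[["participant", "trial", "score"]],
                   df[["participant", "trial", "different_start"]],
                   ["different_start"], tost_terms=["different_start"])
    row = res[res["term"] == "different_start"].iloc[0]
    assert row["ci_low"] < 0 < row["ci_high"]
    assert row["tost_p"] < 0.05


def test_lag_profile_grid_arithmetic(rng):
    scores_by_lag = {}
    table_rows = [(0, t, int(t % 2)) for t in range(40)]
    table = pd.DataFrame(table_rows, columns=["participant", "trial",
                                              "different_start"])
    for lag in range(10, 131, 10):
        rows = [(0, t, rng.normal()) for t in range(40)]
        scores_by_lag[lag] = pd.DataFrame(
            rows, columns=["participant", "trial", "score"])
    prof = lag_profile(scores_by_lag, table, "different_start")
    assert len(prof) == 13
    assert list(prof["lag_ms"]) == list(range(10, 131, 10))


def test_correlation_identities(rng):
    v = rng.normal(size=10)
    assert across_participant_correlation(v, v)["r"] == pytest.approx(1.0)
    assert across_participant_correlation(v, -v)["r"] == pytest.approx(-1.0)
    flagged = across_participant_correlation(np.ones(5), v[:5])
    assert np.isnan(flagged["r"]) and flagged["flag"] == "zero variance"


def test_correlation_sampling_distribution(rng):
    rs = []
    cov = np.array([[1.0, -0.5], [-0.5, 1.0]])
    chol = np.linalg.cholesky(cov)
    for _ in range(1000):
        xy = rng.normal(size=(24, 2)) @ chol.T
        rs.append(across_participant_correlation(xy[:, 0], xy[:, 1])["r"])
    assert np.mean(rs) == pytest.approx(-0.5, abs=0.05)


def test_dissociation_z_identities():
    assert dissociation_test(1.0, 0.5, 1.0, 0.5)["z"] == 0.0
    assert dissociation_test(1.0, 0.5, 1.0, 0.5)["p_one_tailed"] == 0.5
    se = np.hypot(0.3, 0.4)
    res = dissociation_test(1.96 * se, 0.3, 0.0, 0.4)
    assert res["p_one_tailed"] == pytest.approx(0.025, abs=1e-3)
    a = dissociation_test(0.7, 0.2, 0.2, 0.3)
    b = dissociation_test(0.2, 0.3, 0.7, 0.2)
    assert a["z"] == pytest.approx(-b["z"])
    with pytest.raises(ValueError, match="positive"):
        dissociation_test(1.0, 0.0, 0.5, 0.2)


def test_replay_split_label_properties(table, rng):
    scores = table[["participant", "trial"]].copy()
    scores["score"] = rng.normal(size=len(scores))
    labels = replay_split_labels(scores, table)
    # labels attach to the trial after an eligible feedback trial
    eligible = table.set_index(["participant", "trial"])["world_change_next"]
    for _, row in labels.iterrows():
        assert eligible.loc[(row["participant"], row["trial"] - 1)] == 1
    counts = labels.groupby("participant")["label"].value_counts().unstack()
    assert (abs(counts["high"] - counts["low"]) <= 1).all()


def test_replay_split_degenerate_scores_flagged(table, caplog):
    scores = table[["participant", "trial"]].copy()
    scores["score"] = 1.0
    import logging

    with caplog.at_level(logging.WARNING, logger="seqreplay.linking"):
        labels = replay_split_labels(scores, table)
    assert (labels["label"] == "low").all()
    assert "degenerate" in caplog.text
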