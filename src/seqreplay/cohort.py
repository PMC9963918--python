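"""End-to-end synthetic cohorts with ground-truth replay-behavior coupling.

Builds, per participant: a task schedule, a (by default strongly
model-based) agent's choices, trial covariates, and reactivation series for
the planning and feedback periods with injected replay whose rate is coupled
to task variables:

* planning period - forward replay of the *current* world's paths at 70 ms,
  with extra events on trials where the start state differs from the
  previous same-world trial (the benefit-of-planning coupling);
* feedback period - backward replay of the *other* world's paths at 40 ms,
  with an event rate increasing in the rarity of recent other-world
  experience (the memory-preservation coupling).

This is the generative model against which the full analysis pipeline's
double dissociation is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import simulate_agent
from .behavior import AgentParams
from .linking import build_regressor_table
from .neural import (FEEDBACK_WINDOW_MS, PLANNING_WINDOW_MS,
                     ReplayInjectionSpec, generate_reactivation_series)
from .stats import derive_trial_covariates
from .task import TaskConfig, generate_task_schedule
from .tdlm import trialwise_sequenceness
from .transitions import TransitionSpec

__all__ = ["CohortSpec", "ReplayCohort", "simulate_replay_cohort",
           "trialwise_scores"]


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a synthetic cohort."""

    n_participants: int = 24
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(
        default_factory=lambda: AgentParams(alpha=0.5, beta=2.0, w=1.0))
    agent_model: str = "hybrid"
    planning_lag_ms: float = 70.0
    feedback_lag_ms: float = 40.0
    fidelity: float = 0.6
    planning_base_rate: float = 1.0
    planning_diff_start_boost: float = 2.0
    feedback_base_rate: float = 0.5
    feedback_rarity_gain: float = 4.0
    planning_window_ms: float = PLANNING_WINDOW_MS
    feedback_window_ms: float = FEEDBACK_WINDOW_MS


@dataclass
class ReplayCohort:
    """Simulated cohort: choices + covariates and per-trial reactivations."""

    spec: CohortSpec
    choices: pd.DataFrame        # includes derived covariates
    table: pd.DataFrame          # regressor table (rarity, value-free)
    planning: dict               # participant -> list of ReactivationMatrix
    feedback: dict
    transition_spec: TransitionSpec = None
    seed: int | None = None


def simulate_replay_cohort(spec: CohortSpec = CohortSpec(),
                           seed: int | None = 0) -> ReplayCohort:
    rng = np.random.default_rng(seed)
    frames, planning, feedback = [], {}, {}
    tspec = None
    for pid in range(spec.n_participants):
        sched = generate_task_schedule(spec.task,
                                       int(rng.integers(2**31 - 1)))
        if tspec is None:
            tspec = sched.transition_spec()
        df = simulate_agent(sched, spec.agent, spec.agent_model,
                            rng=np.random.default_rng(
                                int(rng.integers(2**31 - 1))),
                            participant=pid)
        df = derive_trial_covariates(df)
        table = build_regressor_table(df)
        frames.append(table)
        p_trials, f_trials = [], []
        for _, tr in table.iterrows():
            w = int(tr["world"])
            cur_paths = tspec.paths_of_world(w)
            oth_paths = tspec.paths_of_world(1 - w)
            diff = tr["different_start"]
            rate_p = spec.planning_base_rate
            if diff == 1.0:
                rate_p += spec.planning_diff_start_boost
            inj_p = ReplayInjectionSpec(
                lag_ms=spec.planning_lag_ms, direction="forward",
                events_per_trial=rate_p, fidelity=spec.fidelity,
                affected_paths=cur_paths)
            p_trials.append(generate_reactivation_series(
                tspec, spec.planning_window_ms, (inj_p,),
                rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
                window="planning", trial_id=int(tr["trial"])))
            rate_f = (spec.feedback_base_rate
                      + spec.feedback_rarity_gain * float(tr["rarity_other"]))
            inj_f = ReplayInjectionSpec(
                lag_ms=spec.feedback_lag_ms, direction="backward",
                events_per_trial=rate_f, fidelity=spec.fidelity,
                affected_paths=oth_paths)
            f_trials.append(generate_reactivation_series(
                tspec, spec.feedback_window_ms, (inj_f,),
                rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
                window="feedback", trial_id=int(tr["trial"])))
        planning[pid] = p_trials
        feedback[pid] = f_trials
    table = pd.concat(frames, ignore_index=True)
    return ReplayCohort(spec, table, table, planning, feedback, tspec, seed)


def trialwise_scores(reacts_by_participant: dict, tspec: TransitionSpec,
                     table: pd.DataFrame, lag_ms: float,
                     world_subset: str = "current",
                     direction: str = "forward") -> pd.DataFrame:
    """Per-trial sequenceness restricted to current- or other-world paths.

    Returns columns participant, trial, score, where score is the forward or
    backward coefficient at ``lag_ms`` with the directional regressors
    restricted to the trial's current-world (or other-world) paths.
    """
    if world_subset not in ("current", "other"):
        raise ValueError("world_subset must be 'current' or 'other'")
    world_of_trial = table.set_index(["participant", "trial"])["world"]
    rows = []
    for pid, trials in reacts_by_participant.items():
        for react in trials:
            w = int(world_of_trial.loc[(pid, react.trial_id)])
            if world_subset == "other":
                w = 1 - w
            subset = tspec.paths_of_world(w)
            fwd, bwd = trialwise_sequenceness(react.values, tspec, lag_ms,
                                              subset)
            rows.append((pid, react.trial_id,
                         fwd if direction == "forward" else bwd))
    return pd.DataFrame(rows, columns=["participant", "trial", "score"])
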