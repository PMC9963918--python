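"""Simulated agents producing choice datasets from a task schedule.

Agents choose with the same controllers the fitting code evaluates
(model-free, model-based, hybrid, replay-modulated), so generative choice
probabilities can be checked against :func:`seqreplay.behavior.nll_choices`.
Synthetic reaction times are lognormal with an additive shift on start-state
change trials (the study's planning-cost signature; default 9 ms).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import AgentParams, ValueState, choice_probabilities, value_update
from .task import TaskSchedule

__all__ = ["simulate_agent", "simulate_cohort", "generate_memory_probes"]

RT_START_CHANGE_SHIFT_S = 0.009


def simulate_agent(schedule: TaskSchedule, params: AgentParams,
                   model: str = "hybrid",
                   rng: np.random.Generator | int | None = None,
                   participant=0,
                   rt_base_s: float = 0.7, rt_sd_s: float = 0.15,
                   rt_start_change_s: float = RT_START_CHANGE_SHIFT_S,
                   replay_labels=None) -> pd.DataFrame:
    """Play the schedule with one agent; returns the trial table.

    Columns: participant, trial, block, world, start_state, choice, path,
    reward (points actually shown, pre-stakes), stakes, rt, plus the
    generative probability of the chosen option (``gen_p``) for oracle checks.

    For the replay-modulated controller, ``replay_labels`` is a per-trial
    sequence with "high"/"low" on world-change trials (None elsewhere); the
    matching inverse temperature from ``params`` applies on those trials.
    """
    cfg = schedule.config
    rng = np.random.default_rng(rng)
    state = ValueState.initial(cfg.n_worlds, cfg.n_start_states_per_world,
                               cfg.n_paths_per_world)
    last_opt = [None] * cfg.n_worlds
    last_start = [None] * cfg.n_worlds
    rows = []
    for t in range(schedule.n_trials):
        w = int(schedule.world[t])
        s = int(schedule.start_state[t])
        beta = None
        if replay_labels is not None and replay_labels[t] is not None:
            beta = (params.beta_high if replay_labels[t] == "high"
                    else params.beta_low)
        probs = choice_probabilities(state, w, s, params, model,
                                     last_option=last_opt[w], beta=beta)
        c = int(rng.random() < probs[1])
        path = schedule.path_of_option(w, c)
        reward = float(schedule.rewards[t, path])
        start_changed = last_start[w] is not None and last_start[w] != s
        rt = rt_base_s * np.exp(rng.normal(0.0, rt_sd_s / rt_base_s))
        rt += rt_start_change_s * start_changed
        rows.append((participant, t, t // cfg.trials_per_block, w, s, c, path,
                     reward, int(schedule.stakes[t]), rt, float(probs[c])))
        state = value_update(state, w, s, c, path, reward, params.alpha)
        last_opt[w] = c
        last_start[w] = s
    return pd.DataFrame(rows, columns=[
        "participant", "trial", "block", "world", "start_state", "choice",
        "path", "reward", "stakes", "rt", "gen_p"])


def simulate_cohort(schedules, params: AgentParams, model: str = "hybrid",
                    rng: np.random.Generator | int | None = None
                    ) -> pd.DataFrame:
    """Simulate one agent per schedule; participants indexed 0..n-1."""
    rng = np.random.default_rng(rng)
    frames = [
        simulate_agent(sch, params, model,
                       rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
                       participant=i)
        for i, sch in enumerate(schedules)
    ]
    return pd.concat(frames, ignore_index=True)


def generate_memory_probes(n_participants: int = 24, n_blocks: int = 6,
                           probes_per_block: int = 8, n_stages: int = 3,
                           p_probe_correct: float = 0.95,
                           rng: np.random.Generator | int | None = None
                           ) -> pd.DataFrame:
    """Synthetic sequence-memory probe table (stage-level correctness).

    A probe counts as correct only if all ``n_stages`` stage selections are
    correct; probe-level accuracy is drawn Bernoulli(``p_probe_correct``), and
    an incorrect probe has one randomly chosen stage wrong.  Confidence is
    higher (3-4) on correct probes, lower (1-3) otherwise.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for pid in range(n_participants):
        for b in range(n_blocks):
            for probe in range(probes_per_block):
                ok = rng.random() < p_probe_correct
                wrong_stage = rng.integers(n_stages) if not ok else -1
                conf = int(rng.integers(3, 5) if ok else rng.integers(1, 4))
                for stage in range(n_stages):
                    rows.append((pid, b, probe, stage,
                                 int(stage != wrong_stage), conf))
    return pd.DataFrame(rows, columns=[
        "participant", "block", "probe", "stage", "correct", "confidence"])
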