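"""Synthetic dual-environment two-step task schedules.

The task interleaves two independent environments ("worlds").  Each world has
two equivalent start states whose two options lead deterministically onto the
same two three-state paths, ending in 0-9 reward points that drift across
trials; a stakes cue multiplies the points earned (but not learned) on a
trial.  The default configuration reproduces the study design: 6 blocks of 24
trials (144 trials), 12 path states, stakes of 1x or 5x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transitions import TransitionSpec, default_transitions

__all__ = ["TaskConfig", "TaskSchedule", "generate_task_schedule"]


@dataclass(frozen=True)
class TaskConfig:
    """Task-generator configuration.

    ``walk_sd`` is the per-trial SD (points) of the reflected Gaussian random
    walk that drives each path's latent reward; ``max_world_run`` caps
    consecutive repeats of a world in the pseudorandom schedule.
    """

    n_worlds: int = 2
    n_paths_per_world: int = 2
    path_length: int = 3
    n_start_states_per_world: int = 2
    n_blocks: int = 6
    trials_per_block: int = 24
    reward_min: float = 0.0
    reward_max: float = 9.0
    stakes_levels: tuple = (1, 5)
    walk_sd: float = 2.0
    sample_rate_hz: float = 100.0
    max_world_run: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reward_min >= self.reward_max:
            raise ValueError("reward_min must be below reward_max")
        for name in ("n_worlds", "n_paths_per_world", "path_length",
                     "n_start_states_per_world", "n_blocks", "trials_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def n_states(self) -> int:
        return self.n_worlds * self.n_paths_per_world * self.path_length

    @property
    def n_paths(self) -> int:
        return self.n_worlds * self.n_paths_per_world

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class TaskSchedule:
    """A realized trial schedule.

    ``world``/``start_state``/``stakes`` are per-trial; ``rewards`` holds the
    latent reward of every (global) path on every trial.  The option->path map
    is deterministic and shared by both start states of a world: option ``o``
    in world ``w`` leads to global path ``w * n_paths_per_world + o``, so the
    two start states are equivalent by construction.
    """

    config: TaskConfig
    world: np.ndarray
    start_state: np.ndarray
    stakes: np.ndarray
    rewards: np.ndarray
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.world)

    def path_of_option(self, world: int, option: int) -> int:
        return int(world) * self.config.n_paths_per_world + int(option)

    def transition_spec(self) -> TransitionSpec:
        cfg = self.config
        paths = tuple(
            tuple(range(cfg.path_length * p, cfg.path_length * (p + 1)))
            for p in range(cfg.n_paths)
        )
        worlds = tuple(p // cfg.n_paths_per_world for p in range(cfg.n_paths))
        return TransitionSpec(paths, worlds, cfg.n_states)

    def to_frame(self) -> pd.DataFrame:
        cfg = self.config
        df = pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "block": np.arange(self.n_trials) // cfg.trials_per_block,
            "world": self.world,
            "start_state": self.start_state,
            "stakes": self.stakes,
        })
        for p in range(cfg.n_paths):
            df[f"reward_path{p}"] = self.rewards[:, p]
        return df


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (repeatedly, for large excursions)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _pseudorandom_sequence(n: int, k: int, max_run: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Equal-marginal sequence over k symbols with runs capped at max_run."""
    if k == 1:
        return np.zeros(n, dtype=int)
    out = np.empty(n, dtype=int)
    run = 0
    prev = -1
    for t in range(n):
        if run >= max_run:
            choices = [c for c in range(k) if c != prev]
            out[t] = rng.choice(choices)
        else:
            out[t] = rng.integers(k)
        run = run + 1 if out[t] == prev else 1
        prev = out[t]
    return out


def generate_task_schedule(config: TaskConfig,
                           rng: np.random.Generator | int | None = None
                           ) -> TaskSchedule:
    """Draw a pseudorandom schedule with drifting bounded path rewards.

    Worlds and start states are drawn with equal marginal probability, world
    runs capped at ``config.max_world_run``.  Each path's latent reward starts
    uniform on [reward_min, reward_max] and follows a Gaussian random walk
    reflected at the bounds.
    """
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = config.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    cfg = config
    n = cfg.n_trials
    world = _pseudorandom_sequence(n, cfg.n_worlds, cfg.max_world_run, rng)
    start = rng.integers(cfg.n_start_states_per_world, size=n)
    stakes = rng.choice(np.asarray(cfg.stakes_levels), size=n)
    steps = rng.normal(0.0, cfg.walk_sd, size=(n, cfg.n_paths))
    steps[0] = rng.uniform(cfg.reward_min, cfg.reward_max, size=cfg.n_paths)
    walk = np.cumsum(steps, axis=0)
    rewards = _reflect(walk, cfg.reward_min, cfg.reward_max)
    return TaskSchedule(cfg, world, start, stakes, rewards, seed=seed)
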