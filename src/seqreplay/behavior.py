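"""Reinforcement-learning choice models for the dual-world two-step task.

A model-free controller caches action values ``Q[start-state, option]`` per
world; a model-based controller looks ahead through the deterministic
option->path map to a cached path value ``V[path]``.  Because both start
states of a world lead onto the same paths, only the model-based controller
generalizes reward feedback across equivalent start states.  The hybrid model
mixes the two with a weight ``w`` (share of the model-based value); a
replay-modulated variant fits separate softmax inverse temperatures for
world-change choices preceded by high versus low feedback replay.

Both value stores learn with a shared delta rule at rate ``alpha``; stakes
multiply earnings, not the learned 0-9 point signal.  An exponentially
weighted tracker of each world's appearance frequency (rate 0.10) provides
the "rarity" (1 - frequency) regressor used in the replay analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AgentParams", "ValueState", "RarityTrace", "FitResult",
    "value_update", "choice_probabilities", "nll_choices", "value_trajectory",
    "ChoiceModel", "fit_model", "fit_cohort", "fit_replay_modulated",
    "update_rarity", "rarity_series",
]

MODELS = ("mf", "mb", "hybrid", "replay_modulated")

_BOUNDS = {
    "alpha": (1e-4, 1.0),
    "beta": (0.0, 40.0),
    "w": (0.0, 1.0),
    "persev": (-5.0, 5.0),
    "beta_high": (0.0, 40.0),
    "beta_low": (0.0, 40.0),
}


def _param_names(model: str, persev: bool = False) -> tuple[str, ...]:
    base = {
        "mf": ("alpha", "beta"),
        "mb": ("alpha", "beta"),
        "hybrid": ("alpha", "beta", "w"),
        "replay_modulated": ("alpha", "beta", "w", "beta_high", "beta_low"),
    }
    try:
        names = base[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return names + (("persev",) if persev else ())


@dataclass
class AgentParams:
    """Controller parameters (see module docstring for semantics)."""

    alpha: float
    beta: float
    w: float | None = None
    persev: float = 0.0
    beta_high: float | None = None
    beta_low: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.w is not None and not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


@dataclass
class ValueState:
    """Model-free Q values and model-based path values, in reward points."""

    q: np.ndarray  # [world, start_state, option]
    v: np.ndarray  # [global path]

    @classmethod
    def initial(cls, n_worlds: int = 2, n_starts: int = 2, n_options: int = 2,
                init: float = 4.5) -> "ValueState":
        return cls(np.full((n_worlds, n_starts, n_options), float(init)),
                   np.full(n_worlds * n_options, float(init)))


def value_update(state: ValueState, world: int, start: int, option: int,
                 path: int, reward: float, alpha: float) -> ValueState:
    """Delta-rule update of the chosen Q entry and chosen path's V."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    q = state.q.copy()
    v = state.v.copy()
    q[world, start, option] += alpha * (reward - q[world, start, option])
    v[path] += alpha * (reward - v[path])
    return ValueState(q, v)


def _option_values(state: ValueState, world: int, start: int, model: str,
                   w: float | None) -> np.ndarray:
    n_opt = state.q.shape[2]
    mb = np.array([state.v[world * n_opt + o] for o in range(n_opt)])
    mf = state.q[world, start, :]
    if model == "mf":
        return mf
    if model == "mb":
        return mb
    if w is None:
        raise ValueError("hybrid/replay_modulated models require w")
    return w * mb + (1.0 - w) * mf


def choice_probabilities(state: ValueState, world: int, start: int,
                         params: AgentParams, model: str = "hybrid",
                         last_option: int | None = None,
                         beta: float | None = None) -> np.ndarray:
    """Softmax choice probabilities over the two options of a start state.

    ``last_option`` is the option leading to the most recently chosen path in
    this world (perseveration bonus applies to it); ``beta`` overrides the
    base inverse temperature (used for the replay-modulated model).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    vals = _option_values(state, world, start, model, params.w)
    b = params.beta if beta is None else beta
    logits = b * vals
    if last_option is not None and params.persev:
        logits = logits + params.persev * (np.arange(len(vals)) == last_option)
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


def nll_choices(data: pd.DataFrame, params: AgentParams, model: str = "hybrid",
                n_worlds: int = 2, n_starts: int = 2, n_options: int = 2,
                q_init: float = 4.5) -> float:
    """Negative log-likelihood of a chronologically ordered choice series.

    Missing choices contribute no likelihood term but still drive the value
    update when a path and reward were recorded.  For the replay-modulated
    model, rows may carry ``replay_label`` in {"high", "low"} on world-change
    trials, selecting ``beta_high``/``beta_low`` for that choice.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    worlds = data["world"].to_numpy(int)
    starts = data["start_state"].to_numpy(int)
    choices = data["choice"].to_numpy(float)
    paths = data["path"].to_numpy(float)
    rewards = data["reward"].to_numpy(float)
    labels = (data["replay_label"].to_numpy(object)
              if "replay_label" in data.columns else np.full(len(data), None))

    alpha, beta, w, persev = params.alpha, params.beta, params.w, params.persev
    use_mb = model in ("mb", "hybrid", "replay_modulated")
    w_eff = 1.0 if model == "mb" else (0.0 if model == "mf" else w)
    if w_eff is None:
        raise ValueError("hybrid/replay_modulated models require w")
    q = [[[q_init] * n_options for _ in range(n_starts)] for _ in range(n_worlds)]
    v = [q_init] * (n_worlds * n_options)
    last_opt = [None] * n_worlds
    nll = 0.0
    for t in range(len(worlds)):
        wd, st = worlds[t], starts[t]
        c = choices[t]
        if not math.isnan(c):
            b = beta
            lab = labels[t]
            if model == "replay_modulated" and lab is not None and lab == lab:
                if lab == "high":
                    b = params.beta_high
                elif lab == "low":
                    b = params.beta_low
            vals = [w_eff * v[wd * n_options + o] + (1 - w_eff) * q[wd][st][o]
                    for o in range(n_options)]
            logits = [b * x for x in vals]
            if persev and last_opt[wd] is not None:
                logits[last_opt[wd]] += persev
            m = max(logits)
            z = sum(math.exp(x - m) for x in logits)
            nll -= logits[int(c)] - m - math.log(z)
        if not math.isnan(rewards[t]) and not math.isnan(paths[t]):
            p = int(paths[t])
            o = p - wd * n_options
            q[wd][st][o] += alpha * (rewards[t] - q[wd][st][o])
            v[p] += alpha * (rewards[t] - v[p])
            last_opt[wd] = o
        if not math.isnan(c):
            last_opt[wd] = int(c)
    return nll


def value_trajectory(data: pd.DataFrame, params: AgentParams,
                     model: str = "hybrid", n_worlds: int = 2,
                     n_starts: int = 2, n_options: int = 2,
                     q_init: float = 4.5) -> pd.DataFrame:
    """Pre-choice option values under a controller replayed over the data.

    Returns per-trial ``mean_value`` (average of the two options' values at
    the trial's start state), ``chosen_value``, and the reward prediction
    error ``rpe`` = reward - chosen value.  Values are model-predicted, so
    this is the source of the "mean state value" regressor.
    """
    state = ValueState.initial(n_worlds, n_starts, n_options, q_init)
    w_eff = {"mb": 1.0, "mf": 0.0}.get(model, params.w)
    if w_eff is None:
        raise ValueError("hybrid/replay_modulated models require w")
    rows = []
    for _, tr in data.sort_values("trial").iterrows():
        wd, st = int(tr["world"]), int(tr["start_state"])
        vals = [w_eff * state.v[wd * n_options + o]
                + (1 - w_eff) * state.q[wd, st, o] for o in range(n_options)]
        c = tr["choice"]
        chosen = float(vals[int(c)]) if not math.isnan(c) else float("nan")
        r = float(tr["reward"])
        rows.append((float(np.mean(vals)), chosen,
                     r - chosen if not math.isnan(chosen) else float("nan")))
        if not math.isnan(r) and not math.isnan(tr["path"]):
            state = value_update(state, wd, st,
                                 int(tr["path"]) - wd * n_options,
                                 int(tr["path"]), r, params.alpha)
    return pd.DataFrame(rows, columns=["mean_value", "chosen_value", "rpe"])


@dataclass
class FitResult:
    """Maximum-likelihood fit of one participant's choice series."""

    model: str
    estimates: AgentParams
    nll: float
    aic: float
    bic: float
    n_trials: int
    n_params: int
    n_starts: int
    converged: bool
    start_nlls: np.ndarray = field(default_factory=lambda: np.array([]))
    participant: object = None

    def summary(self) -> pd.DataFrame:
        rows = {name: getattr(self.estimates, name)
                for name in _param_names(self.model, self.estimates.persev != 0)}
        rows.update(nll=self.nll, aic=self.aic, bic=self.bic,
                    converged=self.converged)
        return pd.DataFrame([rows], index=[self.participant])


class ChoiceModel:
    """Likelihood model of one participant's choices, statsmodels-style.

    >>> res = ChoiceModel(df, kind="hybrid").fit(n_starts=10, seed=0)
    >>> res.estimates.w
    """

    def __init__(self, data: pd.DataFrame, kind: str = "hybrid",
                 persev: bool = False, q_init: float = 4.5):
        if kind not in MODELS:
            raise ValueError(f"unknown model {kind!r}; expected one of {MODELS}")
        if "participant" in data.columns and data["participant"].nunique() > 1:
            raise ValueError("ChoiceModel fits one participant; use fit_cohort")
        self.data = data.sort_values("trial").reset_index(drop=True)
        self.kind = kind
        self.persev = persev
        self.q_init = q_init
        self.param_names = _param_names(kind, persev)

    def _nll_vec(self, x: np.ndarray) -> float:
        kw = dict(zip(self.param_names, x))
        params = AgentParams(**kw)
        return nll_choices(self.data, params, self.kind, q_init=self.q_init)

    def fit(self, n_starts: int = 10, seed=None) -> FitResult:
        """Best-of-starts bounded quasi-Newton maximum likelihood."""
        if n_starts < 5:
            raise ValueError("n_starts must be at least 5")
        rng = np.random.default_rng(seed)
        bounds = [_BOUNDS[name] for name in self.param_names]
        best = None
        start_nlls = []
        any_converged = False
        for _ in range(n_starts):
            x0 = np.array([rng.uniform(lo if np.isfinite(lo) else -5,
                                       hi if np.isfinite(hi) else 5)
                           for lo, hi in bounds])
            res = optimize.minimize(self._nll_vec, x0, method="L-BFGS-B",
                                    bounds=bounds)
            start_nlls.append(res.fun)
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if not any_converged:
            warnings.warn("no optimizer start converged; returning best point",
                          stacklevel=2)
        k = len(self.param_names)
        n = int(self.data["choice"].notna().sum())
        est = AgentParams(**dict(zip(self.param_names, best.x)))
        participant = (self.data["participant"].iloc[0]
                       if "participant" in self.data.columns else None)
        return FitResult(self.kind, est, float(best.fun),
                         aic=2 * k + 2 * best.fun,
                         bic=k * math.log(n) + 2 * best.fun,
                         n_trials=n, n_params=k, n_starts=n_starts,
                         converged=any_converged,
                         start_nlls=np.asarray(start_nlls),
                         participant=participant)


def fit_model(data: pd.DataFrame, model: str = "hybrid", n_starts: int = 10,
              seed=None, **kwargs) -> FitResult:
    """Fit one participant's series; thin wrapper over :class:`ChoiceModel`."""
    return ChoiceModel(data, kind=model, **kwargs).fit(n_starts, seed)


def fit_cohort(data: pd.DataFrame, model: str = "hybrid", n_starts: int = 10,
               seed=None, **kwargs) -> list[FitResult]:
    """Fit each participant independently (seeded per participant)."""
    rng = np.random.default_rng(seed)
    out = []
    for _, grp in data.groupby("participant", sort=True):
        out.append(fit_model(grp, model, n_starts,
                             seed=int(rng.integers(2**31 - 1)), **kwargs))
    return out


def fit_replay_modulated(data: pd.DataFrame, labels: pd.Series,
                         n_starts: int = 10, seed=None,
                         min_per_cell: int = 5):
    """Fit the replay-modulated model per participant and test beta_high > beta_low.

    ``labels`` is indexed like ``data`` with "high"/"low" on world-change
    trials only (anything else raises).  Participants with fewer than
    ``min_per_cell`` labeled trials in either cell are flagged and excluded
    from the paired one-tailed Wilcoxon signed-rank test.
    """
    data = data.copy()
    data["replay_label"] = labels
    labeled = data["replay_label"].notna()
    if "world_change" in data.columns:
        bad = labeled & (data["world_change"] != 1)
        if bad.any():
            raise ValueError("replay labels are only defined on world-change trials")
    fits, flagged = [], []
    rng = np.random.default_rng(seed)
    for pid, grp in data.groupby("participant", sort=True):
        counts = grp["replay_label"].value_counts()
        if counts.get("high", 0) < min_per_cell or counts.get("low", 0) < min_per_cell:
            flagged.append(pid)
            continue
        fits.append(fit_model(grp, "replay_modulated", n_starts,
                              seed=int(rng.integers(2**31 - 1))))
    bh = np.array([f.estimates.beta_high for f in fits])
    bl = np.array([f.estimates.beta_low for f in fits])
    if len(fits) >= 3 and np.any(bh != bl):
        stat = stats.wilcoxon(bh, bl, alternative="greater")
        p = float(stat.pvalue)
    else:
        p = float("nan")
    return {"fits": fits, "beta_high": bh, "beta_low": bl,
            "wilcoxon_p_one_tailed": p, "flagged_participants": flagged}


@dataclass
class RarityTrace:
    """Exponentially weighted world-appearance frequency and its inverse."""

    f: np.ndarray
    rate: float = 0.10

    @property
    def r(self) -> np.ndarray:
        return 1.0 - self.f

    @classmethod
    def initial(cls, n_worlds: int = 2, rate: float = 0.10,
                init: float = 0.5) -> "RarityTrace":
        return cls(np.full(n_worlds, float(init)), rate)


def update_rarity(trace: RarityTrace, appeared: np.ndarray) -> RarityTrace:
    """One delta-rule step of the appearance-frequency tracker per world."""
    if not 0.0 < trace.rate < 1.0:
        raise ValueError("rate must lie in (0, 1)")
    appeared = np.asarray(appeared, float)
    return RarityTrace(trace.f + trace.rate * (appeared - trace.f), trace.rate)


def rarity_series(worlds: np.ndarray, n_worlds: int = 2, rate: float = 0.10,
                  init: float = 0.5) -> np.ndarray:
    """Pre-trial frequency trace F for every world on every trial.

    Row ``t`` reflects appearances up to and including trial ``t - 1``, i.e.
    the value available when trial ``t`` begins.  Rarity is ``1 - F``.
    """
    worlds = np.asarray(worlds, int)
    out = np.empty((len(worlds), n_worlds))
    trace = RarityTrace.initial(n_worlds, rate, init)
    for t, w in enumerate(worlds):
        out[t] = trace.f
        trace = update_rarity(trace, np.arange(n_worlds) == w)
    return out
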