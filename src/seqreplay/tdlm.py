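"""Two-stage lagged-regression sequenceness ("TDLM") engine.

Stage 1 regresses each state's reactivation time course on the lag-shifted
time courses of all states (all lagged predictors entered jointly, plus an
intercept), yielding an empirical state-to-state prediction matrix at a given
lag.  Stage 2 regresses the vectorized empirical matrix onto the structural
regressors of a :class:`~seqreplay.transitions.TransitionSpec`; the forward
and backward coefficients are the "sequenceness" at that lag.  Repeating over
a lag grid gives the sequenceness curve; permuting the assignment of states to
path positions gives a familywise null threshold across lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transitions import TransitionSpec

__all__ = [
    "stage1_empirical",
    "stage2_sequenceness",
    "SequencenessAnalysis",
    "SequencenessResult",
    "trialwise_sequenceness",
    "sample_state_permutations",
]

DT_MS = 10
DEFAULT_LAGS_MS = tuple(range(10, 601, 10))


def _lag_steps(lag_ms: float, dt_ms: float = DT_MS) -> int:
    steps = lag_ms / dt_ms
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(f"lag {lag_ms} ms is not a positive multiple of the "
                         f"{dt_ms} ms sampling grid")
    return int(round(steps))


def stage1_empirical(values: np.ndarray, lag_ms: float,
                     dt_ms: float = DT_MS) -> np.ndarray:
    """Empirical state->state matrix at one lag for one [time x state] series.

    Entry ``(i, j)`` is the multiple-regression coefficient predicting state
    ``j``'s series from state ``i``'s series shifted by ``lag_ms``, with all
    lagged state series plus an intercept entered jointly.

    Rank-deficient designs (e.g. constant series) fall back to the
    minimum-norm least-squares solution with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be [time x state]")
    steps = _lag_steps(lag_ms, dt_ms)
    if values.shape[0] < steps + 2:
        raise ValueError("window too short for requested lag")
    x = values[:-steps]
    y = values[steps:]
    design = np.column_stack([np.ones(len(x)), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient stage-1 design; minimum-norm solution",
                      stacklevel=2)
    return beta[1:, :]


def _stage1_batch(stack: np.ndarray, steps: int) -> np.ndarray:
    """Stage-1 matrices for a [trial x time x state] stack, one lag.

    Solves the per-trial normal equations in a single batched call; falls
    back to per-trial least squares on singular designs.
    """
    x = stack[:, :-steps, :]
    y = stack[:, steps:, :]
    ones = np.ones(x.shape[:2] + (1,))
    design = np.concatenate([ones, x], axis=2)
    ata = np.einsum("nti,ntj->nij", design, design)
    atb = np.einsum("nti,ntj->nij", design, y)
    try:
        beta = np.linalg.solve(ata, atb)
    except np.linalg.LinAlgError:
        beta = np.empty_like(atb)
        for n in range(len(stack)):
            beta[n] = np.linalg.lstsq(design[n], y[n], rcond=None)[0]
    if not np.all(np.isfinite(beta)):
        for n in range(len(stack)):
            if not np.all(np.isfinite(beta[n])):
                beta[n] = np.linalg.lstsq(design[n], y[n], rcond=None)[0]
    return beta[:, 1:, :]


def stage2_sequenceness(empirical: np.ndarray, spec: TransitionSpec,
                        path_subset=None) -> tuple[float, float]:
    """Regress a vectorized empirical matrix on [T_F, T_B, T_cons, T_auto].

    Returns the forward and backward coefficients.  No intercept is used:
    ``T_cons`` and ``T_auto`` jointly absorb the matrix mean, keeping the
    four regressors linearly independent.
    """
    design = spec.design(path_subset)
    coef, *_ = np.linalg.lstsq(design, np.asarray(empirical, float).ravel(),
                               rcond=None)
    return float(coef[0]), float(coef[1])


def _stage2_pinv(spec: TransitionSpec, path_subset=None) -> np.ndarray:
    return np.linalg.pinv(spec.design(path_subset))


@dataclass
class SequencenessResult:
    """Per-lag forward/backward sequenceness, per participant and group mean.

    Attributes
    ----------
    lags_ms : lag grid evaluated
    forward, backward : arrays [participant x lag]
    mean_empirical : [participant x lag x state x state] stage-1 matrices
        averaged over trials (retained so permutation nulls can re-run the
        cheap stage 2 only)
    """

    lags_ms: np.ndarray
    forward: np.ndarray
    backward: np.ndarray
    mean_empirical: np.ndarray
    spec: TransitionSpec
    omitted_lags_ms: tuple = ()

    @property
    def group_forward(self) -> np.ndarray:
        return self.forward.mean(axis=0)

    @property
    def group_backward(self) -> np.ndarray:
        return self.backward.mean(axis=0)

    def peak_lag(self, direction: str = "forward") -> float:
        curve = self.group_forward if direction == "forward" else self.group_backward
        return float(self.lags_ms[int(np.argmax(curve))])

    def permutation_threshold(self, n_perms: int = 500, seed=None,
                              percentile: float = 95.0):
        """Familywise null threshold per direction.

        For each permutation of the assignment of states to path positions
        (identity excluded), stage 2 is re-run on the stored mean empirical
        matrices, and the absolute maximum of the group-mean curve across
        lags is recorded.  The threshold is the ``percentile`` of these
        maxima, per direction.  Also returns the per-permutation maxima.
        """
        perms = sample_state_permutations(self.spec.n_states, n_perms, seed)
        n_part, n_lag = self.forward.shape
        vecs = self.mean_empirical.reshape(n_part * n_lag, -1)
        maxima = np.empty((len(perms), 2))
        for k, perm in enumerate(perms):
            pinv = _stage2_pinv(self.spec.relabel(perm))
            coefs = vecs @ pinv.T          # [(part*lag) x 4]
            fwd = coefs[:, 0].reshape(n_part, n_lag).mean(axis=0)
            bwd = coefs[:, 1].reshape(n_part, n_lag).mean(axis=0)
            maxima[k] = np.abs(fwd).max(), np.abs(bwd).max()
        thresh = np.percentile(maxima, percentile, axis=0)
        return {"forward": float(thresh[0]), "backward": float(thresh[1]),
                "maxima": maxima}

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in range(self.forward.shape[0]):
            for i, lag in enumerate(self.lags_ms):
                rows.append((p, int(lag), self.forward[p, i], self.backward[p, i]))
        return pd.DataFrame(rows, columns=["participant", "lag_ms", "fwd", "bwd"])

    def plot(self, ax=None, threshold=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.lags_ms, self.group_forward, label="forward")
        ax.plot(self.lags_ms, self.group_backward, label="backward")
        if threshold is not None:
            ax.axhline(threshold["forward"], ls="--", c="C0", lw=0.8)
            ax.axhline(-threshold["backward"], ls="--", c="C1", lw=0.8)
        ax.set_xlabel("state-to-state lag (ms)")
        ax.set_ylabel("sequenceness")
        ax.legend()
        return ax


class SequencenessAnalysis:
    """Sequenceness curve estimation over a cohort of reactivation series.

    Parameters
    ----------
    reacts_by_participant
        One list of [time x state] arrays (trials) per participant.  Trials
        may differ in length; windows shorter than ``lag + 2`` samples are
        skipped for that lag (the lag is omitted entirely if no trial
        supports it).
    spec
        Transition structure.
    lags_ms
        Lag grid; defaults to 10..600 ms in 10-ms steps.
    """

    def __init__(self, reacts_by_participant, spec: TransitionSpec,
                 lags_ms=DEFAULT_LAGS_MS, dt_ms: float = DT_MS):
        if len(reacts_by_participant) == 0:
            raise ValueError("at least one participant required")
        self.reacts = [[np.asarray(t, float) for t in trials]
                       for trials in reacts_by_participant]
        for trials in self.reacts:
            if len(trials) == 0:
                raise ValueError("each participant needs at least one trial")
        self.spec = spec
        self.lags_ms = np.asarray(sorted(lags_ms), float)
        self.dt_ms = dt_ms

    def fit(self) -> SequencenessResult:
        """Compute per-participant mean empirical matrices and stage-2 curves."""
        n_states = self.spec.n_states
        kept, omitted = [], []
        min_len = min(len(t) for trials in self.reacts for t in trials)
        for lag in self.lags_ms:
            steps = _lag_steps(lag, self.dt_ms)
            (kept if min_len >= steps + 2 else omitted).append(lag)
        if omitted:
            warnings.warn(f"lags {omitted} ms omitted: window too short",
                          stacklevel=2)
        lags = np.asarray(kept, float)
        n_part, n_lag = len(self.reacts), len(lags)
        mean_emp = np.zeros((n_part, n_lag, n_states, n_states))
        pinv = _stage2_pinv(self.spec)
        fwd = np.zeros((n_part, n_lag))
        bwd = np.zeros((n_part, n_lag))
        for p, trials in enumerate(self.reacts):
            by_len: dict[int, list[np.ndarray]] = {}
            for t in trials:
                by_len.setdefault(len(t), []).append(t)
            stacks = [np.stack(group) for group in by_len.values()]
            for i, lag in enumerate(lags):
                steps = _lag_steps(lag, self.dt_ms)
                mats = np.concatenate(
                    [_stage1_batch(s, steps) for s in stacks], axis=0)
                mean_emp[p, i] = mats.mean(axis=0)
                coef = pinv @ mean_emp[p, i].ravel()
                fwd[p, i], bwd[p, i] = coef[0], coef[1]
        return SequencenessResult(lags, fwd, bwd, mean_emp, self.spec,
                                  tuple(omitted))


def trialwise_sequenceness(react: np.ndarray, spec: TransitionSpec,
                           lag_ms: float, path_subset=None,
                           dt_ms: float = DT_MS) -> tuple[float, float]:
    """Single-trial forward/backward sequenceness at one analysis lag.

    ``path_subset`` restricts the directional regressors to the given paths
    (e.g. the two current-world paths); the controls stay global.  A flat
    (constant) series scores 0 in both directions.
    """
    react = np.asarray(react, float)
    if np.allclose(react.std(axis=0), 0):
        warnings.warn("degenerate (flat) trial; sequenceness set to 0",
                      stacklevel=2)
        return 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emp = stage1_empirical(react, lag_ms, dt_ms)
    return stage2_sequenceness(emp, spec, path_subset)


def sample_state_permutations(n_states: int, n_perms: int, seed=None,
                              max_tries: int = 200) -> np.ndarray:
    """Unique non-identity permutations of state-to-position assignment."""
    rng = np.random.default_rng(seed)
    seen = {tuple(range(n_states))}
    perms = []
    tries = 0
    while len(perms) < n_perms and tries < max_tries * n_perms:
        perm = tuple(rng.permutation(n_states))
        tries += 1
        if perm in seen:
            continue
        seen.add(perm)
        perms.append(perm)
    if len(perms) < n_perms:
        warnings.warn(f"only {len(perms)} unique permutations available; "
                      f"requested {n_perms}", stacklevel=2)
    return np.asarray(perms, dtype=int)
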