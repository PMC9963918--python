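"""Synthetic neural data: reactivation probability series and sensor epochs.

These generators emulate the substrate of the replay analyses with explicit
ground truth.  A reactivation series is a [time x state] matrix of classifier
probabilities on a 10-ms grid; injected replay events place a probability
bump on a path's three states at a controlled state-to-state lag, in forward
or reversed (backward) order, on top of low positive baseline noise
(Beta(1, 10), mimicking one-vs-rest classifier outputs).  Sensor epochs
express one spatial pattern per state at a nominal latency, for training and
validating the decoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transitions import TransitionSpec, default_transitions

__all__ = [
    "ReplayInjectionSpec", "ReactivationMatrix", "EpochSet",
    "generate_reactivation_series", "generate_sensor_epochs",
    "PLANNING_WINDOW_MS", "FEEDBACK_WINDOW_MS",
]

DT_MS = 10
# 2.5-s planning period minus the first 160 ms; latter 3.5 s of 5-s feedback.
PLANNING_WINDOW_MS = 2340
FEEDBACK_WINDOW_MS = 3500


@dataclass(frozen=True)
class ReplayInjectionSpec:
    """Ground-truth replay events to inject into a reactivation series."""

    lag_ms: float = 70.0
    direction: str = "forward"
    events_per_trial: float = 2.0
    fidelity: float = 0.8
    affected_paths: tuple = (0, 1)
    baseline_a: float = 1.0
    baseline_b: float = 10.0
    poisson: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if not 0.0 < self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in (0, 1]")
        steps = self.lag_ms / DT_MS
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ValueError("lag must be a positive multiple of the 10-ms grid")

    @property
    def lag_steps(self) -> int:
        return int(round(self.lag_ms / DT_MS))


@dataclass
class ReactivationMatrix:
    """[time x state] classifier probability series for one trial period."""

    values: np.ndarray
    times_ms: np.ndarray
    window: str = "planning"
    trial_id: int | None = None
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("reactivation probabilities must lie in [0, 1]")
        self.values = v


def generate_reactivation_series(
        spec: TransitionSpec | None = None,
        window_ms: float = PLANNING_WINDOW_MS,
        injections: tuple[ReplayInjectionSpec, ...] = (),
        rng: np.random.Generator | int | None = None,
        amplitude: float = 1.0,
        window: str = "planning",
        trial_id: int | None = None) -> ReactivationMatrix:
    """One trial's reactivation series with optional injected replay.

    Each injected event places a bump of height ``fidelity * amplitude`` on
    the three states of a randomly chosen affected path at offsets
    (0, lag, 2*lag), in path order for forward events and reversed for
    backward events.  Event counts are Poisson(``events_per_trial``) (or the
    rounded rate with ``poisson=False``); onsets are uniform over positions
    where the whole triple fits inside the window.  Values are clipped to
    [0, 1] after the baseline and bumps are summed.
    """
    if spec is None:
        spec = default_transitions()
    rng = np.random.default_rng(rng)
    n_samp = int(round(window_ms / DT_MS))
    for inj in injections:
        if n_samp < 3 * inj.lag_steps:
            raise ValueError("window must cover at least three lag steps")
    if injections:
        a, b = injections[0].baseline_a, injections[0].baseline_b
    else:
        a, b = 1.0, 10.0
    # baseline_a or baseline_b of 0 requests a noiseless (all-zero) baseline
    values = (rng.beta(a, b, size=(n_samp, spec.n_states))
              if a > 0 and b > 0 else np.zeros((n_samp, spec.n_states)))
    events = []
    for inj in injections:
        lag = inj.lag_steps
        n_events = (rng.poisson(inj.events_per_trial) if inj.poisson
                    else int(round(inj.events_per_trial)))
        last_onset = n_samp - 2 * lag - 1
        for _ in range(n_events):
            path = int(rng.choice(inj.affected_paths))
            onset = int(rng.integers(0, last_onset + 1))
            states = spec.paths[path]
            if inj.direction == "backward":
                states = states[::-1]
            for k, s in enumerate(states):
                values[onset + k * lag, s] += inj.fidelity * amplitude
            events.append({"onset": onset, "path": path,
                           "direction": inj.direction, "lag_ms": inj.lag_ms})
    np.clip(values, 0.0, 1.0, out=values)
    times = np.arange(n_samp) * DT_MS
    return ReactivationMatrix(values, times, window, trial_id, events)


@dataclass
class EpochSet:
    """Labeled [epoch x sensor x time] arrays for decoder training."""

    data: np.ndarray
    labels: np.ndarray
    times_ms: np.ndarray

    @property
    def n_states(self) -> int:
        return len(np.unique(self.labels))

    def at_latency(self, latency_ms: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times_ms - latency_ms)))
        if abs(self.times_ms[idx] - latency_ms) > 1e-6:
            raise ValueError(f"latency {latency_ms} ms not on the time grid")
        return self.data[:, :, idx]


def generate_sensor_epochs(n_states: int = 12, n_sensors: int = 24,
                           n_epochs_per_state: int = 10,
                           noise_sd: float = 1.0,
                           latency_ms: float = 200.0,
                           times_ms=None,
                           pattern_amplitude: float = 2.0,
                           orthogonal: bool = True,
                           rng: np.random.Generator | int | None = None
                           ) -> EpochSet:
    """Epochs expressing one spatial pattern per state at ``latency_ms``.

    With ``orthogonal=True`` the state patterns are orthonormal rows (scaled
    by ``pattern_amplitude``), which requires ``n_sensors >= n_states``.
    The pattern is present only at the nominal latency sample; everything
    else is white noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(rng)
    if times_ms is None:
        times_ms = np.arange(-100, 501, DT_MS, dtype=float)
    times_ms = np.asarray(times_ms, float)
    if orthogonal:
        if n_sensors < n_states:
            raise ValueError("orthogonal patterns require n_sensors >= n_states")
        q, _ = np.linalg.qr(rng.normal(size=(n_sensors, n_states)))
        patterns = pattern_amplitude * q.T
    else:
        patterns = pattern_amplitude * rng.normal(size=(n_states, n_sensors))
    lat_idx = int(np.argmin(np.abs(times_ms - latency_ms)))
    labels = np.repeat(np.arange(n_states), n_epochs_per_state)
    rng.shuffle(labels)
    data = rng.normal(0.0, noise_sd,
                      size=(len(labels), n_sensors, len(times_ms)))
    data[:, :, lat_idx] += patterns[labels]
    return EpochSet(data, labels, times_ms)
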