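"""Task transition structure for sequence (replay) analysis.

The task graph is four non-branching three-state paths spread over two
independent environments ("worlds"): world 0 owns paths 0-1, world 1 owns
paths 2-3, and every state belongs to exactly one path, giving 12 decodable
states.  Sequence analysis regresses an empirical state-to-state matrix onto
structural regressors built from this graph: a forward transition indicator
``T_F`` (within-path successor pairs), its transpose ``T_B`` (backward), a
constant off-diagonal matrix ``T_cons`` absorbing background co-activation,
and the identity ``T_auto`` absorbing autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain

import numpy as np

__all__ = ["TransitionSpec", "default_transitions"]


@dataclass(frozen=True)
class TransitionSpec:
    """Path definitions and derived structural regressor matrices.

    Parameters
    ----------
    paths
        Ordered state triples, one per path, over states ``0..n_states-1``.
    world_of_path
        World index of each path (two paths per world).
    """

    paths: tuple[tuple[int, ...], ...]
    world_of_path: tuple[int, ...]
    n_states: int = 12

    def __post_init__(self) -> None:
        states = list(chain.from_iterable(self.paths))
        if sorted(states) != list(range(self.n_states)):
            raise ValueError(
                "paths must partition the states 0..%d" % (self.n_states - 1)
            )
        if len(self.world_of_path) != len(self.paths):
            raise ValueError("world_of_path must label every path")
        tf = self.t_f
        if tf.sum() != sum(len(p) - 1 for p in self.paths):
            raise ValueError("duplicate transitions in path definitions")
        if np.any((tf * tf.T) != 0):
            raise ValueError("forward and backward transitions must not overlap")

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def worlds(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.world_of_path)))

    def paths_of_world(self, world: int) -> tuple[int, ...]:
        return tuple(i for i, w in enumerate(self.world_of_path) if w == world)

    def _forward(self, path_subset=None) -> np.ndarray:
        mat = np.zeros((self.n_states, self.n_states))
        subset = range(self.n_paths) if path_subset is None else path_subset
        for p in subset:
            triple = self.paths[p]
            for a, b in zip(triple[:-1], triple[1:]):
                mat[a, b] = 1.0
        return mat

    @property
    def t_f(self) -> np.ndarray:
        """Forward transition indicator (state i followed by state j)."""
        return self._forward()

    @property
    def t_b(self) -> np.ndarray:
        """Backward transition indicator, the transpose of ``t_f``."""
        return self._forward().T

    @property
    def t_cons(self) -> np.ndarray:
        """All-ones off-diagonal control for mean off-diagonal level."""
        return 1.0 - np.eye(self.n_states)

    @property
    def t_auto(self) -> np.ndarray:
        """Identity control for self-transitions (autocorrelation)."""
        return np.eye(self.n_states)

    def design(self, path_subset=None) -> np.ndarray:
        """Stage-2 design: columns [T_F, T_B, T_cons, T_auto], vectorized.

        With ``path_subset``, the directional regressors are restricted to
        transitions of those paths; the controls are unchanged.
        """
        tf = self._forward(path_subset)
        return np.column_stack(
            [tf.ravel(), tf.T.ravel(), self.t_cons.ravel(), self.t_auto.ravel()]
        )

    def relabel(self, assignment: np.ndarray) -> "TransitionSpec":
        """Reassign states to path positions (used by permutation nulls)."""
        assignment = np.asarray(assignment)
        new_paths = tuple(
            tuple(int(assignment[s]) for s in triple) for triple in self.paths
        )
        return TransitionSpec(new_paths, self.world_of_path, self.n_states)


def default_transitions() -> TransitionSpec:
    """The 2-world x 2-path x 3-state graph with consecutive state numbering."""
    paths = tuple(tuple(range(3 * p, 3 * p + 3)) for p in range(4))
    return TransitionSpec(paths, (0, 0, 1, 1), 12)
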