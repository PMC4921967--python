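"""State space and generator matrix of the imitation chain.

The population of ``N`` individuals is described by the strategy counts
``(n_R, n_S, n_P)`` with ``n_R + n_S + n_P = N``. Because ``n_P`` is
determined by the other two counts, the process is a two-dimensional Markov
chain on the discrete simplex; ordering the states by ``(n_R, n_S)`` --
level ``l = n_R``, phase ``n_S`` within the level -- yields a
level-dependent quasi-birth-death (QBD) structure: a single imitation event
moves exactly one individual between two strategies, so ``n_R`` changes by
at most one and the generator is block-tridiagonal in the level index.

Transition rates implement imitation with mutation noise. At a state with
average payoffs ``pi`` (see :func:`rspqbd.games.average_payoffs`), the
transition that moves one individual from strategy ``i`` to strategy ``k``
occurs at rate

    ``[pi_k - pi_i]_+ + epsilon``     (kernel ``payoff_difference``)

whenever ``n_i > 0`` (and rate 0 otherwise): switches toward strategies
with a strictly higher average payoff, plus a uniform spontaneous-switch
rate ``epsilon >= 0`` implementing the mutation hypothesis of bounded
rationality. An alternative kernel ``prevalence_weighted`` scales imitation
by the number of potential switchers and the prevalence of the target
strategy, ``n_i ((n_k / N) [pi_k - pi_i]_+ + epsilon)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .games import Game, average_payoffs

__all__ = [
    "PopulationState",
    "StateSpace",
    "RateSpec",
    "Generator",
    "KERNELS",
    "enumerate_states",
    "switch_rate",
    "build_generator",
    "cyclic_permute_state",
]

PopulationState = Tuple[int, int, int]

#: Ordered strategy pairs (from, to) of the six possible switches.
SWITCH_PAIRS = [(i, k) for i in range(3) for k in range(3) if i != k]

KERNELS = ("payoff_difference", "prevalence_weighted")


@dataclass(frozen=True)
class RateSpec:
    """Imitation-rate rule: noise level and kernel identifier."""

    epsilon: float = 0.01
    kernel: str = "payoff_difference"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.kernel not in KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel!r}; choose from {KERNELS}")


class StateSpace:
    """Ordered enumeration of the ``(N+1)(N+2)/2`` population states.

    States are ordered lexicographically by ``(n_R, n_S)``; this is the row
    and column order of the generator matrix. ``level_of`` a state is
    ``n_R``, its ``phase_of`` is ``n_S``.
    """

    def __init__(self, N: int):
        if N < 1:
            raise ValueError(f"population size must be >= 1, got {N}")
        self.N = N
        self.states: List[PopulationState] = [
            (r, s, N - r - s) for r in range(N + 1) for s in range(N - r + 1)
        ]
        self._index = {st: i for i, st in enumerate(self.states)}
        # level l occupies rows level_start[l] .. level_start[l+1]-1
        sizes = [N - l + 1 for l in range(N + 1)]
        self.level_start = np.concatenate([[0], np.cumsum(sizes)])

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[PopulationState]:
        return iter(self.states)

    def index(self, state: PopulationState) -> int:
        return self._index[tuple(state)]

    def level_of(self, state: PopulationState) -> int:
        return state[0]

    def phase_of(self, state: PopulationState) -> int:
        return state[1]

    def level_slice(self, level: int) -> slice:
        return slice(int(self.level_start[level]),
                     int(self.level_start[level + 1]))

    def frequencies(self) -> np.ndarray:
        """All states as strategy-frequency vectors, shape (len, 3)."""
        return np.asarray(self.states, dtype=float) / self.N


def enumerate_states(N: int) -> StateSpace:
    """All population compositions of size ``N``, in QBD (level, phase) order."""
    return StateSpace(N)


def cyclic_permute_state(state: PopulationState) -> PopulationState:
    """Relabel counts under the cyclic map R -> S -> P -> R.

    The count of the *new* strategy S is the old count of R, etc.:
    ``(n_R, n_S, n_P) -> (n_P, n_R, n_S)``.
    """
    r, s, p = state
    return (p, r, s)


def switch_rate(state: PopulationState, frm: int, to: int, game: Game,
                N: int, spec: RateSpec) -> float:
    """Rate of the transition moving one individual from ``frm`` to ``to``."""
    if frm == to:
        raise ValueError("switch requires two distinct strategies")
    n = state
    if n[frm] == 0:
        return 0.0
    pi = average_payoffs(game, n, N)
    adv = max(pi[to] - pi[frm], 0.0)
    if spec.kernel == "payoff_difference":
        return adv + spec.epsilon
    # prevalence_weighted
    return n[frm] * ((n[to] / N) * adv + spec.epsilon)


class Generator:
    """Generator matrix Q of the imitation chain, with its QBD block view.

    ``Q`` is sparse (CSR): each state couples only to its at-most-six
    one-switch neighbours, plus the conservative diagonal. ``block(l, m)``
    returns the dense block coupling level ``l`` to level ``m``
    (``|l - m| <= 1``; all other blocks are zero).
    """

    def __init__(self, Q: sp.csr_matrix, space: StateSpace, game: Game,
                 spec: RateSpec):
        self.Q = Q
        self.space = space
        self.game = game
        self.spec = spec

    @property
    def N(self) -> int:
        return self.space.N

    def block(self, l: int, m: int) -> np.ndarray:
        if abs(l - m) > 1:
            raise ValueError("QBD generator has no blocks beyond the "
                             "tridiagonal band")
        return self.Q[self.space.level_slice(l),
                      self.space.level_slice(m)].toarray()

    def is_irreducible(self) -> bool:
        ncomp, _ = self._components()
        return ncomp == 1

    def _components(self) -> Tuple[int, np.ndarray]:
        off = self.Q.copy()
        off.setdiag(0)
        off.eliminate_zeros()
        return connected_components(off, directed=True, connection="strong")

    def components(self) -> List[List[PopulationState]]:
        """Strongly connected classes of the transition graph."""
        ncomp, labels = self._components()
        groups: List[List[PopulationState]] = [[] for _ in range(ncomp)]
        for st, lab in zip(self.space.states, labels):
            groups[lab].append(st)
        return groups

    def to_triplets(self):
        """(row, col, value) arrays plus the state-index table, for export."""
        coo = self.Q.tocoo()
        import pandas as pd
        trip = pd.DataFrame({"row": coo.row, "col": coo.col,
                             "value": coo.data})
        idx = pd.DataFrame(self.space.states, columns=["n_R", "n_S", "n_P"])
        idx.insert(0, "index", np.arange(len(self.space)))
        return trip, idx


def build_generator(space: StateSpace, game: Game,
                    spec: RateSpec) -> Generator:
    """Assemble the sparse block-tridiagonal generator Q over ``space``.

    Off-diagonal entries come from :func:`switch_rate`; each diagonal entry
    is minus its row's off-diagonal sum, so rows sum to zero exactly (the
    diagonal is accumulated from the same floating-point rate values).
    """
    N = space.N
    if N < 2:
        raise ValueError("build_generator requires N >= 2 (payoffs need an "
                         "opponent)")
    rows, cols, vals = [], [], []
    for a, st in enumerate(space.states):
        out = 0.0
        for frm, to in SWITCH_PAIRS:
            r = switch_rate(st, frm, to, game, N, spec)
            if r <= 0.0:
                continue
            nxt = list(st)
            nxt[frm] -= 1
            nxt[to] += 1
            rows.append(a)
            cols.append(space.index(tuple(nxt)))
            vals.append(r)
            out += r
        rows.append(a)
        cols.append(a)
        vals.append(-out)
    Q = sp.csr_matrix((vals, (rows, cols)),
                      shape=(len(space), len(space)))
    return Generator(Q, space, game, spec)
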