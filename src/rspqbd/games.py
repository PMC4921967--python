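"""Payoff-matrix families for the Rock-Scissors-Paper game and their
equilibrium structure.

Strategies are indexed ``(R, S, P) = (0, 1, 2)`` everywhere. A :class:`Game`
holds the 3x3 payoff matrix ``A`` of a symmetric two-player normal-form game:
``A[i, j]`` is the payoff of an individual playing strategy ``i`` against an
opponent playing strategy ``j`` (dimensionless).

Two one-parameter families are provided:

* :func:`make_symmetric_general` -- the cyclically symmetric RSP game with
  zero diagonal, winning payoff ``1 + delta`` and losing payoff ``-1``. At
  ``delta = 0`` it is the standard zero-sum game; the sign of ``delta``
  controls the replicator stability of the barycentre ``(1/3, 1/3, 1/3)``.
* :func:`make_asymmetric` -- a cyclic game without the three-fold symmetry,
  whose interior replicator fixed point is ``(1/2, 1/3, 1/6)`` for every
  value of the parameter ``gamma``, while the stability of that point flips
  at ``gamma = 1``.

The cyclic dominance orientation used throughout is the one consistent with
the finite-population limiting distributions this package reproduces: within
the ordering (R, S, P), each strategy is displaced by the one that follows
it cyclically (S invades R, P invades S, R invades P), i.e. the winning
entries sit at positions (R, P), (S, R) and (P, S).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "STRATEGIES",
    "Game",
    "NoInteriorEquilibrium",
    "make_standard",
    "make_symmetric_general",
    "make_asymmetric",
    "make_custom",
    "average_payoffs",
    "interior_equilibrium",
]

#: Strategy labels in index order.
STRATEGIES = ("R", "S", "P")

#: Cyclic relabeling R -> S -> P -> R as an index permutation:
#: ``CYCLE[i]`` is the image of strategy ``i``.
CYCLE = (1, 2, 0)


class NoInteriorEquilibrium(ValueError):
    """The game has no completely mixed Nash equilibrium."""


@dataclass(frozen=True)
class Game:
    """A 3x3 symmetric normal-form game plus family metadata.

    Parameters
    ----------
    payoff
        Payoff matrix, row = own strategy, column = opponent strategy.
    family
        One of ``standard``, ``symmetric_general``, ``asymmetric``,
        ``custom``.
    parameter
        The family parameter (``delta`` or ``gamma``), if any.
    self_play
        Average-payoff convention for finite populations. ``True`` (default):
        an individual's payoff is the population mean ``(A n)_i / N``
        including itself. ``False``: self-matching is excluded and the mean
        runs over the other ``N - 1`` individuals.
    """

    payoff: np.ndarray
    family: str = "custom"
    parameter: Optional[float] = None
    self_play: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.payoff, dtype=float)
        if a.shape != (3, 3):
            raise ValueError(f"payoff matrix must be 3x3, got shape {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("payoff matrix must be finite in every entry")
        object.__setattr__(self, "payoff", a)
        a.setflags(write=False)

    def cyclic_relabel(self) -> "Game":
        """The game with strategies relabeled R -> S -> P -> R."""
        perm = np.argsort(CYCLE)  # preimage: row i of result = row perm[i]
        a = self.payoff[np.ix_(perm, perm)]
        return Game(a, family=self.family, parameter=self.parameter,
                    self_play=self.self_play)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "matrix": self.payoff.tolist(),
            "self_play": self.self_play,
        }
        if self.parameter is not None:
            d["parameter"] = self.parameter
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Game":
        family = d.get("family", "custom")
        parameter = d.get("parameter")
        self_play = bool(d.get("self_play", True))
        if "matrix" in d:
            g = cls(np.asarray(d["matrix"], float), family=family,
                    parameter=parameter, self_play=self_play)
            return g
        if family == "standard":
            g = make_standard()
        elif family == "symmetric_general":
            g = make_symmetric_general(float(parameter))
        elif family == "asymmetric":
            g = make_asymmetric(float(parameter))
        else:
            raise ValueError(
                "config must give an explicit 'matrix' for family "
                f"{family!r}")
        if not self_play:
            g = Game(g.payoff, family=g.family, parameter=g.parameter,
                     self_play=False)
        return g


def _cyclic_matrix(win: float, loss: float) -> np.ndarray:
    """Zero-diagonal cyclic matrix with wins at (R,P), (S,R), (P,S)."""
    return np.array([
        [0.0, loss, win],
        [win, 0.0, loss],
        [loss, win, 0.0],
    ])


def make_symmetric_general(delta: float) -> Game:
    """The cyclically symmetric RSP game with win payoff ``1 + delta``.

    ``delta`` tilts the win/loss balance: the product of winning payoffs is
    ``(1 + delta)^3`` against a loss product of 1, so the interior
    equilibrium ``(1/3, 1/3, 1/3)`` is asymptotically stable under the
    replicator dynamic for ``delta > 0``, neutrally stable at ``delta = 0``
    (the zero-sum standard game) and unstable for ``delta < 0``.

    Raises
    ------
    ValueError
        If ``delta <= -1`` (the winning payoff must stay positive).
    """
    if not delta > -1:
        raise ValueError(
            f"delta must exceed -1 (winning payoff 1+delta > 0); got {delta}")
    return Game(_cyclic_matrix(1.0 + delta, -1.0),
                family="symmetric_general", parameter=float(delta))


def make_standard() -> Game:
    """The standard zero-sum RSP game (win +1, loss -1, tie 0)."""
    return Game(_cyclic_matrix(1.0, -1.0), family="standard", parameter=0.0)


def make_asymmetric(gamma: float) -> Game:
    """A cyclic RSP game without the three-fold symmetry.

    The matrix is::

        [[ 0,      -3,   6*gamma],
         [ 2*gamma, 0,  -6      ],
         [-2,       3*gamma,  0 ]]

    Against the mixed strategy ``p = (1/2, 1/3, 1/6)`` every strategy earns
    ``gamma - 1``, so ``p`` is the interior replicator fixed point for every
    admissible ``gamma``. The determinant is ``36 (gamma^3 - 1)``: the fixed
    point is a stable focus for ``gamma > 1``, surrounded by closed orbits
    at ``gamma = 1``, and an unstable focus for ``gamma < 1``; all three
    simplex vertices are saddles.

    Raises
    ------
    ValueError
        If ``gamma <= 0``.
    """
    if not gamma > 0:
        raise ValueError(f"gamma must be positive; got {gamma}")
    g = float(gamma)
    a = np.array([
        [0.0, -3.0, 6.0 * g],
        [2.0 * g, 0.0, -6.0],
        [-2.0, 3.0 * g, 0.0],
    ])
    return Game(a, family="asymmetric", parameter=g)


def make_custom(matrix: Sequence[Sequence[float]],
                self_play: bool = True) -> Game:
    """Wrap an explicit 3x3 payoff matrix."""
    return Game(np.asarray(matrix, float), family="custom",
                self_play=self_play)


def average_payoffs(game: Game, state: Sequence[int], N: int) -> np.ndarray:
    """Average payoff of an R-, S- and P-player in a finite population.

    With counts ``n = (n_R, n_S, n_P)`` summing to ``N``, the default
    convention (``game.self_play = True``) is the population mean

    .. math:: \\pi_i = (A n)_i / N,

    i.e. an individual samples its opponent uniformly from the whole
    population, itself included. With ``self_play = False`` the focal
    individual is excluded:

    .. math:: \\pi_i = ((A n)_i - A_{ii}) / (N - 1).

    For the zero-diagonal game families the two conventions differ only by
    the constant factor ``N / (N - 1)``.

    Returns
    -------
    numpy.ndarray
        ``pi`` of shape (3,): payoffs for a hypothetical player of each
        strategy at this state (defined even when the strategy is unplayed).
    """
    n = np.asarray(state, dtype=float)
    if n.shape != (3,) or np.any(n < 0):
        raise ValueError(f"state must be 3 non-negative counts, got {state}")
    if N < 2:
        raise ValueError(f"population size must be at least 2, got {N}")
    if n.sum() != N:
        raise ValueError(f"state {tuple(state)} does not sum to N={N}")
    a = game.payoff
    if game.self_play:
        return a @ n / N
    return (a @ n - np.diag(a)) / (N - 1)


def interior_equilibrium(game: Game) -> np.ndarray:
    """The completely mixed Nash equilibrium / interior replicator fixed point.

    Solves for the strategy vector ``x`` in the open simplex at which all
    three strategies earn the same expected payoff against ``x``:
    ``(A x)_0 = (A x)_1 = (A x)_2`` with ``sum(x) = 1``. (The normalising
    constant of the closed-form solution is absorbed into the returned
    vector.)

    Raises
    ------
    NoInteriorEquilibrium
        If the equal-payoff system is singular or its solution leaves the
        open simplex.
    """
    a = game.payoff
    m = np.vstack([a[0] - a[1], a[1] - a[2], np.ones(3)])
    b = np.array([0.0, 0.0, 1.0])
    try:
        x = np.linalg.solve(m, b)
    except np.linalg.LinAlgError as exc:
        raise NoInteriorEquilibrium(
            "equal-payoff system is singular; no unique interior "
            "equilibrium") from exc
    if np.any(x <= 0):
        raise NoInteriorEquilibrium(
            f"equal-payoff solution {x} lies outside the open simplex")
    return x
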