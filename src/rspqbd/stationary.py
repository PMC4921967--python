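"""Stationary (limiting) distribution of the imitation chain.

Solves ``pi Q = 0`` with ``sum(pi) = 1`` for an irreducible generator. Two
routes are provided and used as mutual cross-checks:

* ``block_gauss_seidel`` -- Stewart-style iterative solution exploiting the
  QBD level structure: the balance equations couple each level only to its
  two neighbours, so a sweep solves, level by level,

      ``x_l Q[l,l] = -(x_{l-1} Q[l-1,l] + x_{l+1} Q[l+1,l])``

  with the diagonal blocks LU-factorised once. Sweeps alternate ascending
  and descending level order (symmetric Gauss-Seidel) and the iterate is
  renormalised after every sweep.
* ``direct`` -- sparse LU on the transposed balance equations with one
  equation replaced by the normalisation constraint.

The stationary distribution is invariant under rescaling of the generator
(time units are arbitrary); :func:`scale_invariance_check` asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .chain import Generator, StateSpace, cyclic_permute_state

__all__ = [
    "Distribution",
    "SolverReport",
    "ReducibleChainError",
    "solve_stationary",
    "scale_invariance_check",
]


class ReducibleChainError(ValueError):
    """The chain has more than one recurrent class; no unique limiting
    distribution exists."""


@dataclass
class SolverReport:
    method: str
    iterations: int
    residual: float
    converged: bool


@dataclass
class Distribution:
    """A probability vector over a :class:`~rspqbd.chain.StateSpace`."""

    probs: np.ndarray
    space: StateSpace

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.space),):
            raise ValueError("probability vector does not match state space")

    def __getitem__(self, state) -> float:
        return float(self.probs[self.space.index(tuple(state))])

    def cyclic_permuted(self) -> "Distribution":
        """The distribution of the cyclically relabeled process."""
        out = np.empty_like(self.probs)
        for st, p in zip(self.space.states, self.probs):
            out[self.space.index(cyclic_permute_state(st))] = p
        return Distribution(out, self.space)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.space.states, columns=["n_R", "n_S", "n_P"])
        df["probability"] = self.probs
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path) -> "Distribution":
        df = pd.read_csv(path)
        N = int(df.iloc[0][["n_R", "n_S", "n_P"]].sum())
        space = StateSpace(N)
        probs = np.zeros(len(space))
        for _, row in df.iterrows():
            st = (int(row["n_R"]), int(row["n_S"]), int(row["n_P"]))
            probs[space.index(st)] = row["probability"]
        return cls(probs, space)


def _require_irreducible(gen: Generator) -> None:
    comps = gen.components()
    if len(comps) > 1:
        summary = "; ".join(
            f"class {i}: {len(c)} states e.g. {c[0]}"
            for i, c in enumerate(comps[:4]))
        raise ReducibleChainError(
            f"chain is reducible ({len(comps)} strongly connected "
            f"classes): {summary}")


def _residual(pi: np.ndarray, Q: sp.csr_matrix) -> float:
    return float(np.abs(pi @ Q).max())


def _solve_direct(gen: Generator) -> np.ndarray:
    Q = gen.Q
    n = Q.shape[0]
    A = Q.T.tolil()
    A[n - 1, :] = 1.0  # replace one balance equation by normalisation
    b = np.zeros(n)
    b[n - 1] = 1.0
    pi = spla.spsolve(A.tocsc(), b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _solve_block_gauss_seidel(gen: Generator, tol: float,
                              max_iter: int) -> tuple[np.ndarray, int, bool]:
    space = gen.space
    N = space.N
    Q = gen.Q.tocsc()
    sl = [space.level_slice(l) for l in range(N + 1)]
    # pre-factorise the (small, dense) diagonal blocks of Q^T per level
    lu = [la.lu_factor(Q[sl[l], sl[l]].toarray().T) for l in range(N + 1)]
    sub = [Q[sl[l - 1], sl[l]].toarray().T for l in range(1, N + 1)]
    sup = [Q[sl[l + 1], sl[l]].toarray().T for l in range(N)]

    pi = np.full(Q.shape[0], 1.0 / Q.shape[0])
    order_up = list(range(N + 1))
    for it in range(1, max_iter + 1):
        order = order_up if it % 2 == 1 else order_up[::-1]
        for l in order:
            rhs = np.zeros(sl[l].stop - sl[l].start)
            if l > 0:
                rhs -= sub[l - 1] @ pi[sl[l - 1]]
            if l < N:
                rhs -= sup[l] @ pi[sl[l + 1]]
            pi[sl[l]] = la.lu_solve(lu[l], rhs)
        s = pi.sum()
        if s <= 0 or not np.isfinite(s):
            raise RuntimeError("block Gauss-Seidel iterate degenerated "
                               f"(sum {s}) at sweep {it}")
        pi /= s
        if _residual(pi, gen.Q) <= tol:
            return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum(), it, True
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum(), max_iter, False


def solve_stationary(gen: Generator, method: str = "block_gauss_seidel",
                     tol: float = 1e-11,
                     max_iter: int = 100000) -> tuple[Distribution, SolverReport]:
    """Limiting distribution ``pi`` with ``pi Q = 0`` and ``sum(pi) = 1``.

    Parameters
    ----------
    method
        ``block_gauss_seidel`` (default) or ``direct``.
    tol
        Convergence threshold on the residual ``max |pi Q|``.
    max_iter
        Sweep budget for the iterative method; on exhaustion the report has
        ``converged=False`` (no exception, no silent success).

    Raises
    ------
    ReducibleChainError
        If the transition graph is not strongly connected (e.g.
        ``epsilon = 0``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    _require_irreducible(gen)
    if method == "direct":
        pi = _solve_direct(gen)
        res = _residual(pi, gen.Q)
        report = SolverReport("direct", 1, res, res <= max(tol, 1e-12))
    elif method == "block_gauss_seidel":
        pi, its, ok = _solve_block_gauss_seidel(gen, tol, max_iter)
        report = SolverReport("block_gauss_seidel", its,
                              _residual(pi, gen.Q), ok)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Distribution(pi, gen.space), report


def scale_invariance_check(gen: Generator, c: float,
                           atol: float = 1e-9) -> bool:
    """True iff solving with the generator rescaled by ``c > 0`` returns the
    same distribution entrywise within ``atol``."""
    if c <= 0:
        raise ValueError("scale factor must be positive")
    base, _ = solve_stationary(gen)
    scaled_gen = Generator(gen.Q * c, gen.space, gen.game, gen.spec)
    scaled, _ = solve_stationary(scaled_gen)
    return bool(np.allclose(base.probs, scaled.probs, rtol=0, atol=atol))
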