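"""Deterministic replicator dynamics: the infinite-population reference.

The replicator equation on the strategy simplex,

.. math:: \\dot x_i = x_i \\big( (A x)_i - x^T A x \\big),

is the deterministic counterpart of the stochastic imitation chain. Its
interior fixed point coincides with the mixed Nash equilibrium, and the
sign of the real parts of the Jacobian eigenvalues (restricted to the
simplex tangent plane) classifies it as asymptotically stable, neutrally
stable, or unstable. The stochastic model's limiting distribution
concentrates near the fixed point exactly in the stable regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .games import Game, interior_equilibrium

__all__ = ["StabilityVerdict", "replicator_field", "classify_interior",
           "integrate_trajectory"]

#: eigenvalue tolerance for calling a fixed point neutrally stable
NEUTRAL_TOL = 1e-9


@dataclass
class StabilityVerdict:
    kind: str  # asymptotically_stable | neutrally_stable | unstable
    eigen_real_parts: np.ndarray
    fixed_point: np.ndarray


def replicator_field(game: Game, x) -> np.ndarray:
    """Replicator vector field at simplex point ``x``; components sum to 0."""
    x = np.asarray(x, dtype=float)
    ax = game.payoff @ x
    phi = x @ ax
    return x * (ax - phi)


def _reduced_jacobian(game: Game, x: np.ndarray) -> np.ndarray:
    """Jacobian of the flow in the chart (x_R, x_S), x_P = 1 - x_R - x_S."""
    a = game.payoff
    ax = a @ x
    phi = x @ ax
    # d(phi)/dx_j = (A x)_j + (A^T x)_j
    dphi = ax + a.T @ x
    J = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            J[i, j] = x[i] * (a[i, j] - dphi[j])
            if i == j:
                J[i, j] += ax[i] - phi
    # chart reduction: dg_i/dy_j = J_ij - J_i2 for i,j in {0,1}
    return np.array([[J[i, j] - J[i, 2] for j in range(2)]
                     for i in range(2)])


def classify_interior(game: Game) -> StabilityVerdict:
    """Stability of the interior fixed point by linearisation.

    Eigenvalues of the Jacobian restricted to the simplex tangent plane are
    computed in the two-dimensional chart ``(x_R, x_S)``. The verdict is by
    the maximum real part: negative beyond ``NEUTRAL_TOL`` is
    asymptotically stable, within it neutrally stable, above it unstable.
    """
    p = interior_equilibrium(game)
    eig = np.linalg.eigvals(_reduced_jacobian(game, p))
    max_re = float(eig.real.max())
    if max_re < -NEUTRAL_TOL:
        kind = "asymptotically_stable"
    elif max_re <= NEUTRAL_TOL:
        kind = "neutrally_stable"
    else:
        kind = "unstable"
    return StabilityVerdict(kind, eig.real, p)


def integrate_trajectory(game: Game, x0, horizon: float,
                         n_points: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the replicator flow from ``x0`` for time ``horizon``.

    Uses adaptive Runge-Kutta (RK45, rtol=atol=1e-9). The component sum is
    conserved by the dynamics; if floating-point drift off the simplex
    exceeds 1e-9 at any output point the trajectory is renormalised there.

    Returns
    -------
    (times, path)
        ``times`` shape (n_points,), ``path`` shape (n_points, 3).
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.min() < -1e-12 or abs(x0.sum() - 1) > 1e-9:
        raise ValueError(f"x0 {x0} is not on the simplex")
    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(lambda t, x: replicator_field(game, x),
                    (0.0, horizon), x0, t_eval=t_eval,
                    rtol=1e-9, atol=1e-9, method="RK45")
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    path = sol.y.T
    drift = np.abs(path.sum(axis=1) - 1.0)
    bad = drift > 1e-9
    if bad.any():
        path[bad] /= path[bad].sum(axis=1, keepdims=True)
    return sol.t, path
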