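"""Exact stochastic simulation of the imitation chain (Gillespie algorithm).

An independent Monte-Carlo route to the limiting distribution: simulate the
continuous-time chain event by event (exponential holding times at the
state's total out-rate, events chosen proportionally to their rates) and
estimate stationary probabilities as time-weighted occupancy fractions with
batch-means standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .chain import (SWITCH_PAIRS, Generator, PopulationState, RateSpec,
                    StateSpace, build_generator, enumerate_states)
from .games import Game

__all__ = ["Trajectory", "OccupancyEstimate", "simulate", "occupancy",
           "central_state"]


def central_state(N: int) -> PopulationState:
    """The lattice state closest to the simplex barycentre."""
    r = round(N / 3)
    s = round(N / 3)
    return (r, s, N - r - s)


@dataclass
class Trajectory:
    """A simulated path: event times, visited states, and bookkeeping.

    ``times[j]`` is the entry time into ``states[j]``; the path occupies
    ``states[j]`` until ``times[j+1]`` (or until ``horizon`` for the last
    state). ``absorbed`` flags an early stop in a state with zero out-rate.
    """

    times: np.ndarray
    states: np.ndarray  # (n_events+1, 3) int counts
    horizon: float
    seed: int
    absorbed: bool

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=["n_R", "n_S", "n_P"])
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


@dataclass
class OccupancyEstimate:
    """Time-weighted state occupancy with batch-means standard errors."""

    probs: np.ndarray
    space: StateSpace
    total_time: float
    burn_in: float
    stderr: np.ndarray

    def __getitem__(self, state) -> float:
        return float(self.probs[self.space.index(tuple(state))])

    def stderr_of(self, state) -> float:
        return float(self.stderr[self.space.index(tuple(state))])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.space.states, columns=["n_R", "n_S", "n_P"])
        df["probability"] = self.probs
        df["stderr"] = self.stderr
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


def _rate_table(gen: Generator):
    """Per-state out-rates and neighbour indices, precomputed for speed."""
    space = gen.space
    n_states = len(space)
    nbr = np.full((n_states, 6), -1, dtype=np.int64)
    rates = np.zeros((n_states, 6))
    Q = gen.Q.tocoo()
    # slot switches by (frm,to) pair order for reproducible event picking
    pair_index = {pair: j for j, pair in enumerate(SWITCH_PAIRS)}
    states = space.states
    for r, c, v in zip(Q.row, Q.col, Q.data):
        if r == c:
            continue
        src, dst = states[r], states[c]
        diff = tuple(d - s for s, d in zip(src, dst))
        frm = diff.index(-1)
        to = diff.index(1)
        j = pair_index[(frm, to)]
        nbr[r, j] = c
        rates[r, j] = v
    return rates, nbr


def simulate(game: Game, N: int, spec: RateSpec,
             init: Optional[PopulationState] = None,
             horizon: float = 1000.0, seed: int = 0,
             space: Optional[StateSpace] = None) -> Trajectory:
    """Simulate the chain exactly up to time ``horizon``.

    The full rate table is precomputed from the generator, so each event is
    a categorical draw plus an exponential holding time. If a state with
    zero total out-rate is reached (possible only at ``epsilon = 0``), the
    trajectory stops there with ``absorbed=True``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if space is None:
        space = enumerate_states(N)
    if init is None:
        init = central_state(N)
    if sum(init) != N or any(c < 0 for c in init):
        raise ValueError(f"initial state {init} invalid for N={N}")
    gen = build_generator(space, game, spec)
    rates, nbr = _rate_table(gen)
    total = rates.sum(axis=1)
    cum = np.cumsum(rates, axis=1)

    rng = np.random.default_rng(seed)
    cur = space.index(init)
    t = 0.0
    times = [0.0]
    visited = [cur]
    absorbed = False
    while True:
        r_tot = total[cur]
        if r_tot <= 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / r_tot)
        if t >= horizon:
            break
        u = rng.random() * r_tot
        j = int(np.searchsorted(cum[cur], u, side="right"))
        j = min(j, 5)
        cur = int(nbr[cur, j])
        times.append(t)
        visited.append(cur)
    states = np.asarray([space.states[i] for i in visited], dtype=np.int64)
    return Trajectory(np.asarray(times), states, horizon, seed, absorbed)


def occupancy(traj: Trajectory, burn_in: Optional[float] = None,
              n_batches: int = 20) -> OccupancyEstimate:
    """Time-weighted occupancy after ``burn_in`` (default 10% of horizon).

    The post-burn-in window is split into ``n_batches`` equal-time batches;
    the per-state standard error is the batch-means estimate
    ``std(batch occupancies, ddof=1) / sqrt(n_batches)``.
    """
    if burn_in is None:
        burn_in = 0.1 * traj.horizon
    end = traj.times[-1] if traj.absorbed else traj.horizon
    if burn_in >= end:
        raise ValueError(
            f"burn_in {burn_in} is not before the trajectory end {end} "
            f"(absorbed={traj.absorbed})")
    N = int(traj.states[0].sum())
    space = enumerate_states(N)
    idx = np.asarray([space.index(tuple(s)) for s in traj.states])

    edges = np.linspace(burn_in, end, n_batches + 1)
    batch = np.zeros((n_batches, len(space)))
    starts = traj.times
    ends = np.append(traj.times[1:], end)
    for b in range(n_batches):
        lo, hi = edges[b], edges[b + 1]
        dur = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
        np.add.at(batch[b], idx, dur)
        batch[b] /= hi - lo
    probs = batch.mean(axis=0)
    probs = probs / probs.sum()
    stderr = batch.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return OccupancyEstimate(probs, space, float(end - burn_in),
                             float(burn_in), stderr)
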