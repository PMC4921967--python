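"""Experiment configuration, summary reports and ternary heat-map export.

The reporting layer turns a solved limiting distribution into the artefacts
used to read off the long-run behaviour of the game:

* a high-probability state listing (the tabular view of where the
  distribution concentrates, with cumulative mass);
* a ternary heat-map grid mapping each state to barycentric coordinates
  with a hue value monotone in probability (R at the top vertex, S bottom
  left, P bottom right);
* probability mass near a target mixed strategy (L1 ball on frequencies),
  quantifying concentration around an equilibrium.

:func:`run_experiment` ties these together for a single :class:`RunConfig`
and writes all outputs to disk deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .chain import RateSpec, build_generator, enumerate_states
from .games import Game
from .gillespie import occupancy, simulate
from .stationary import Distribution, SolverReport, solve_stationary

__all__ = ["RunConfig", "ConfigError", "list_high_probability_states",
           "heatmap_grid", "mass_near", "plot_heatmap", "run_experiment"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending fields."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    N: int
    epsilon: float = 0.01
    game: dict = field(default_factory=dict)
    kernel: str = "payoff_difference"
    method: str = "block_gauss_seidel"
    tol: float = 1e-11
    max_iter: int = 100000
    simulate: bool = False
    horizon: float = 1000.0
    seed: int = 0
    outdir: str = "."

    def validate(self) -> None:
        problems = []
        if not (isinstance(self.N, int) and self.N >= 2):
            problems.append(f"N must be an integer >= 2 (got {self.N!r})")
        if self.epsilon < 0:
            problems.append(f"epsilon must be >= 0 (got {self.epsilon!r})")
        if self.tol <= 0:
            problems.append(f"tol must be positive (got {self.tol!r})")
        if self.method not in ("block_gauss_seidel", "direct"):
            problems.append(f"unknown solver method {self.method!r}")
        if self.horizon <= 0:
            problems.append(f"horizon must be positive (got {self.horizon!r})")
        try:
            self.make_game()
        except Exception as exc:
            problems.append(f"game block invalid: {exc}")
        if problems:
            raise ConfigError("; ".join(problems))

    def make_game(self) -> Game:
        return Game.from_dict(self.game)

    def rate_spec(self) -> RateSpec:
        return RateSpec(epsilon=self.epsilon, kernel=self.kernel)

    def to_dict(self) -> dict:
        return {
            "N": self.N, "epsilon": self.epsilon, "game": dict(self.game),
            "kernel": self.kernel, "method": self.method, "tol": self.tol,
            "max_iter": self.max_iter, "simulate": self.simulate,
            "horizon": self.horizon, "seed": self.seed,
            "outdir": self.outdir,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def list_high_probability_states(dist: Distribution,
                                 threshold: float = 0.01) -> pd.DataFrame:
    """States with probability above ``threshold``, most probable first.

    Ties are broken by ``(n_R, n_S)`` lexicographic order; a ``cumulative``
    column accumulates the listed probabilities.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    df = dist.to_frame()
    df = df[df["probability"] > threshold]
    df = df.sort_values(["probability", "n_R", "n_S"],
                        ascending=[False, True, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["cumulative"] = df["probability"].cumsum()
    return df


def heatmap_grid(dist: Distribution, hue_scale: str = "linear") -> pd.DataFrame:
    """Barycentric heat-map data: one row per state.

    Columns ``x_R, x_S, x_P`` are the strategy frequencies ``n/N``;
    ``hue`` is monotone in probability, normalised to the run's maximum
    (``linear``) or a log-scaled variant (``log``).
    """
    freq = dist.space.frequencies()
    p = dist.probs
    pmax = p.max()
    if hue_scale == "linear":
        hue = p / pmax if pmax > 0 else np.zeros_like(p)
    elif hue_scale == "log":
        floor = max(p[p > 0].min(), pmax * 1e-12) if pmax > 0 else 1.0
        lp = np.log10(np.clip(p, floor, None))
        lo, hi = lp.min(), np.log10(pmax)
        hue = (lp - lo) / (hi - lo) if hi > lo else np.ones_like(p)
    else:
        raise ValueError(f"hue_scale must be 'linear' or 'log', got "
                         f"{hue_scale!r}")
    return pd.DataFrame({
        "x_R": freq[:, 0], "x_S": freq[:, 1], "x_P": freq[:, 2],
        "probability": p, "hue": hue,
    })


def mass_near(dist: Distribution, target, radius: float) -> float:
    """Stationary mass within L1 ``radius`` of ``target`` in frequency space."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    target = np.asarray(target, dtype=float)
    d = np.abs(dist.space.frequencies() - target).sum(axis=1)
    return float(dist.probs[d <= radius + 1e-12].sum())


def plot_heatmap(grid: pd.DataFrame, path, title: str = "") -> None:
    """Basic ternary rendering of a heat-map grid (R top, S bottom left,
    P bottom right); colours are not calibrated to any reference figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # barycentric -> cartesian with R at apex, S lower-left, P lower-right
    x = grid["x_P"].to_numpy() + 0.5 * grid["x_R"].to_numpy()
    y = np.sqrt(3) / 2 * grid["x_R"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4.6))
    sc = ax.scatter(x, y, c=grid["hue"], cmap="jet", s=18)
    ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], "k-", lw=0.8)
    for tx, ty, lab in [(0.5, np.sqrt(3) / 2 + 0.03, "R"),
                        (-0.03, -0.04, "S"), (1.03, -0.04, "P")]:
        ax.text(tx, ty, lab, ha="center", va="center")
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8, label="hue")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def run_experiment(config: RunConfig) -> dict:
    """Solve (and optionally simulate) one configuration; write artefacts.

    Writes into ``config.outdir``: ``distribution.csv``, ``heatmap.csv``,
    ``report.txt``, ``report.json``, ``config.yaml`` and, when
    ``config.simulate`` is set, ``occupancy.csv``. Returns a dict with the
    in-memory results. Deterministic: identical config (and seed) gives
    byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    game = config.make_game()
    spec = config.rate_spec()
    space = enumerate_states(config.N)
    gen = build_generator(space, game, spec)
    dist, report = solve_stationary(gen, method=config.method,
                                    tol=config.tol,
                                    max_iter=config.max_iter)
    listing = list_high_probability_states(dist, 0.01)
    grid = heatmap_grid(dist)

    dist.to_csv(outdir / "distribution.csv")
    grid.to_csv(outdir / "heatmap.csv", index=False, float_format="%.15g")
    config.to_yaml(outdir / "config.yaml")

    top = listing.head(30)
    lines = [
        f"N={config.N} epsilon={config.epsilon} "
        f"game={config.game.get('family', 'custom')} "
        f"parameter={config.game.get('parameter')}",
        f"solver={report.method} iterations={report.iterations} "
        f"residual={report.residual:.3e} converged={report.converged}",
        "",
        "states with limiting probability > 0.01 "
        f"(total {len(listing)}, cumulative "
        f"{listing['probability'].sum():.4f}):",
        "  n_R n_S n_P  probability",
    ]
    for _, row in top.iterrows():
        lines.append(f"  {int(row.n_R):3d} {int(row.n_S):3d} "
                     f"{int(row.n_P):3d}  {row.probability:.4f}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")

    report_json = {
        "config": config.to_dict(),
        "solver": {"method": report.method,
                   "iterations": report.iterations,
                   "residual": report.residual,
                   "converged": report.converged},
        "n_states": len(space),
        "cumulative_above_0.01": float(listing["probability"].sum()),
        "top_states": [
            {"n_R": int(r.n_R), "n_S": int(r.n_S), "n_P": int(r.n_P),
             "probability": round(float(r.probability), 4)}
            for _, r in top.iterrows()],
    }
    (outdir / "report.json").write_text(json.dumps(report_json, indent=2))

    result = {"distribution": dist, "solver_report": report,
              "listing": listing, "heatmap": grid}

    if config.simulate:
        traj = simulate(game, config.N, spec, horizon=config.horizon,
                        seed=config.seed, space=space)
        occ = occupancy(traj)
        occ.to_csv(outdir / "occupancy.csv")
        result["occupancy"] = occ
    return result
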