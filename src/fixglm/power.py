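"""Monte Carlo validity engine: probability of observing an effect as a
function of the number of participants and trials per condition.

The generative model is a two-level Gaussian hierarchy: participant i's
mean amplitude in condition c is

    y_ic = b_i + delta * [c == effect condition] + e_ic,
    b_i ~ N(0, between_sd^2),   e_ic ~ N(0, within_sd^2 / trials),

i.e. the trial-averaged single-trial noise shrinks with the number of
trials averaged per condition. The default detection test is the paired
contrast between the two conditions (the subject effect cancels); the test
is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ExperimentConfig:
    n_participants: int = 19
    trials: int = 13
    effect_uv: float = 1.5
    between_sd_uv: float = 2.0
    within_sd_uv: float = 10.0
    alpha: float = 0.05
    test: str = "paired_t"   # or a callable (y1, y2, alpha) -> bool

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need >= 2 participants")
        if self.trials < 1:
            raise ValueError("need >= 1 trial")
        if min(self.between_sd_uv, self.within_sd_uv) < 0:
            raise ValueError("SDs must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _simulate_condition_means(cfg: ExperimentConfig, reps: int,
                              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_participants
    b = rng.normal(0.0, cfg.between_sd_uv, size=(reps, n))
    sem = cfg.within_sd_uv / np.sqrt(cfg.trials)
    y1 = b + rng.normal(0.0, sem, size=(reps, n))
    y2 = b + cfg.effect_uv + rng.normal(0.0, sem, size=(reps, n))
    return y1, y2


def _paired_t_pvalues(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    d = y2 - y1
    n = d.shape[1]
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    return 2 * sps.t.sf(np.abs(t), n - 1)


def simulate_experiment(config: ExperimentConfig, seed: int = 0) -> bool:
    """Simulate one experiment and report whether the effect is detected
    (p < alpha on the configured test)."""
    return bool(detection_rate(config, reps=1, seed=seed) > 0.5)


def detection_rate(config: ExperimentConfig, reps: int = 1000,
                   seed: int = 0) -> float:
    """Fraction of simulated experiments in which the test rejects."""
    rng = np.random.default_rng([seed, 606])
    y1, y2 = _simulate_condition_means(config, reps, rng)
    if config.test == "paired_t":
        p = _paired_t_pvalues(y1, y2)
        return float(np.mean(p < config.alpha))
    if callable(config.test):
        hits = [config.test(y1[r], y2[r], config.alpha) for r in range(reps)]
        return float(np.mean(hits))
    raise ValueError(f"unknown test spec {config.test!r}")


@dataclass(frozen=True)
class PowerGrid:
    """Detection probability over a participants x trials grid."""

    n_participants: tuple[int, ...]
    trials: tuple[int, ...]
    power: np.ndarray  # len(n_participants) x len(trials)
    reps: int
    seed: int
    config: ExperimentConfig

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        if p.shape != (len(self.n_participants), len(self.trials)):
            raise ValueError("power grid shape mismatch")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        object.__setattr__(self, "power", p)

    def to_frame(self) -> pd.DataFrame:
        rows = [(n, t, self.power[i, j])
                for i, n in enumerate(self.n_participants)
                for j, t in enumerate(self.trials)]
        return pd.DataFrame(rows, columns=["n_participants", "trials", "power"])


def power_surface(
    n_participants: Sequence[int],
    trials: Sequence[int],
    config: ExperimentConfig | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> PowerGrid:
    """Map detection probability over a (participants x trials) grid."""
    if not len(n_participants) or not len(trials):
        raise ValueError("grid must be nonempty")
    cfg = config if config is not None else ExperimentConfig()
    power = np.zeros((len(n_participants), len(trials)))
    for i, n in enumerate(n_participants):
        for j, t in enumerate(trials):
            cell = replace(cfg, n_participants=int(n), trials=int(t))
            power[i, j] = detection_rate(cell, reps=reps,
                                         seed=(seed * 1009 + i * 131 + j) % (2 ** 31))
    return PowerGrid(tuple(int(n) for n in n_participants),
                     tuple(int(t) for t in trials), power, reps, seed,
                     cfg)


def plot_power_surface(grid: PowerGrid, path=None):
    """Optional heat-map figure of the power surface."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.power, origin="lower", vmin=0, vmax=1, aspect="auto",
                   cmap="viridis")
    ax.set_xticks(range(len(grid.trials)), grid.trials)
    ax.set_yticks(range(len(grid.n_participants)), grid.n_participants)
    ax.set_xlabel("trials per condition")
    ax.set_ylabel("participants")
    fig.colorbar(im, ax=ax, label="detection probability")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
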