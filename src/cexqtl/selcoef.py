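"""Selection-coefficient estimation for a toxin-antidote drive locus.

The observable is a per-generation deviation trajectory: at each sampled
generation, the maximum deviation of allele frequency toward the
element-bearing parent among markers in a window around the locus (default:
the element's whole chromosome). Candidate penetrance values s on a grid
spanning [0, 1] are each simulated with replicate populations; the best fit
minimises the summed absolute difference between the mean simulated
trajectory and the observed one across shared generations. No interpolation
between grid values is attempted: the estimate is a grid member.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bulkpop import ExtinctionError, SimConfig, simulate_cross
from .genome import ALLELE_B, GeneticMap, MarkerGrid
from .selection import DriveElement

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.linspace(0.0, 1.0, 20)


@dataclass(frozen=True)
class ObservedTrajectory:
    """Per-generation maximum deviation toward the element allele."""

    generations: np.ndarray  # strictly increasing ints
    deviations: np.ndarray  # in [-0.5, 0.5]

    def __post_init__(self) -> None:
        gens = np.asarray(self.generations, dtype=int)
        dev = np.asarray(self.deviations, dtype=float)
        object.__setattr__(self, "generations", gens)
        object.__setattr__(self, "deviations", dev)
        if gens.size != dev.size:
            raise ValueError("generations and deviations differ in length")
        if np.any(np.diff(gens) <= 0):
            raise ValueError("generations must be strictly increasing")
        if np.any((dev < -0.5) | (dev > 0.5)):
            raise ValueError("deviations must lie in [-0.5, 0.5]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedTrajectory":
        df = df.sort_values("generation")
        return cls(df["generation"].to_numpy(), df["deviation"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"generation": self.generations, "deviation": self.deviations})


def deviation_trajectory(traj: pd.DataFrame, element: DriveElement,
                         markers: MarkerGrid, window_cm: float | None = None) -> ObservedTrajectory:
    """Reduce a per-marker trajectory table to the drive-locus deviation
    statistic: per generation, the maximum deviation of allele frequency
    toward the element allele over markers in the window (default: all
    markers on the element's chromosome)."""
    cm_locus = markers.map.bp_to_cm(element.chrom, element.pos)
    sub = traj[traj["chrom"] == element.chrom]
    if window_cm is not None:
        cm = np.array([markers.map.bp_to_cm(element.chrom, p) for p in sub["pos"]])
        sub = sub[np.abs(cm - cm_locus) <= window_cm]
    if sub.empty:
        raise ValueError("no markers in the deviation window")
    toward = sub["freq_b"] - 0.5
    if element.element_allele != ALLELE_B:
        toward = -toward
    out = sub.assign(toward=toward).groupby("generation")["toward"].max()
    return ObservedTrajectory(out.index.to_numpy(), out.to_numpy())


@dataclass
class SGridFit:
    """Replicate summary for one grid value of s."""

    s: float
    generations: np.ndarray
    mean: np.ndarray
    lo: np.ndarray  # 2.5th percentile across replicates
    hi: np.ndarray  # 97.5th percentile
    n_replicates: int
    n_dropped: int


def simulate_s_grid(element: DriveElement, gmap: GeneticMap, markers: MarkerGrid,
                    rng: np.random.Generator, grid: np.ndarray = DEFAULT_GRID,
                    replicates: int = 50, popsize: int = 10_000,
                    generations: int = 20, window_cm: float | None = None,
                    config: SimConfig | None = None) -> list[SGridFit]:
    """Simulate the deviation trajectory for every grid value of s.

    Each replicate propagates an independent population carrying the drive
    at penetrance s and records the locus-region deviation statistic per
    generation. Extinct replicates are dropped and logged; more than 20%
    dropped for an s value is an error.
    """
    base = config or SimConfig()
    base = base.with_(pop_cap=popsize, f1_founders=min(popsize, base.f1_founders),
                      generations=generations)
    fits: list[SGridFit] = []
    for s in np.asarray(grid, dtype=float):
        cfg = base.with_(drive=element.with_s(float(s)))
        trajs, dropped = [], 0
        for _ in range(replicates):
            try:
                traj, _ = simulate_cross(cfg, gmap, markers, rng=rng)
            except ExtinctionError as err:
                dropped += 1
                logger.info("s=%.3f replicate extinct (%s); dropped", s, err)
                continue
            obs = deviation_trajectory(traj, cfg.drive, markers, window_cm)
            trajs.append(obs.deviations)
        if dropped > 0.2 * replicates:
            raise RuntimeError(f"s={s:.3f}: {dropped}/{replicates} replicates extinct")
        arr = np.vstack(trajs)
        gens = np.arange(1, generations + 1)
        fits.append(SGridFit(float(s), gens, arr.mean(axis=0),
                             np.percentile(arr, 2.5, axis=0),
                             np.percentile(arr, 97.5, axis=0),
                             len(trajs), dropped))
    return fits


def average_across_experiments(trajs: list[ObservedTrajectory]) -> ObservedTrajectory:
    """Mean deviation per generation over experiments, on the intersection
    of their generation grids."""
    if not trajs:
        raise ValueError("no trajectories given")
    shared = set(trajs[0].generations.tolist())
    for t in trajs[1:]:
        shared &= set(t.generations.tolist())
    if not shared:
        raise ValueError("trajectories share no generations")
    gens = np.array(sorted(shared))
    stack = []
    for t in trajs:
        lut = dict(zip(t.generations.tolist(), t.deviations))
        stack.append([lut[g] for g in gens])
    return ObservedTrajectory(gens, np.mean(stack, axis=0))


@dataclass
class SelectionCoefficientResults:
    """Best-fit penetrance with per-grid residuals and simulation envelopes."""

    best_s: float
    residual: float
    grid: np.ndarray
    residuals: np.ndarray
    fits: list[SGridFit]
    observed: ObservedTrajectory

    def summary(self) -> str:
        lines = [
            "Drive selection-coefficient fit",
            "=" * 60,
            f"grid                  {len(self.grid)} values on [{self.grid[0]:g}, {self.grid[-1]:g}]",
            f"observed generations  {self.observed.generations.tolist()}",
            f"best-fit s            {self.best_s:.4f}",
            f"residual (sum |diff|) {self.residual:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        best = next(f for f in self.fits if f.s == self.best_s)
        ax.fill_between(best.generations, best.lo, best.hi, alpha=0.3,
                        label=f"simulated 95% band (s={self.best_s:.2f})")
        ax.plot(best.generations, best.mean, label="simulated mean")
        ax.plot(self.observed.generations, self.observed.deviations, "o-",
                label="observed")
        ax.set_xlabel("generation")
        ax.set_ylabel("max deviation toward element allele")
        ax.legend()
        return ax


def fit_selection_coefficient(observed: ObservedTrajectory,
                              fits: list[SGridFit]) -> SelectionCoefficientResults:
    """Pick the grid s minimising the summed absolute difference between the
    mean simulated and the observed deviation across shared generations.

    Absolute differences are used: a signed sum lets over- and under-shoot
    cancel and makes the objective non-identifiable.
    """
    residuals = np.empty(len(fits))
    for i, fit in enumerate(fits):
        mask = np.isin(fit.generations, observed.generations)
        obs_mask = np.isin(observed.generations, fit.generations)
        if not mask.any():
            raise ValueError("observed and simulated trajectories share no generations")
        residuals[i] = np.abs(fit.mean[mask] - observed.deviations[obs_mask]).sum()
    best = int(np.argmin(residuals))
    grid = np.array([f.s for f in fits])
    return SelectionCoefficientResults(float(grid[best]), float(residuals[best]),
                                       grid, residuals, fits, observed)


class SelectionCoefficientModel:
    """Model object tying an observed trajectory to the simulation grid.

    ``fit()`` simulates the grid (or reuses supplied grid fits) and returns
    a :class:`SelectionCoefficientResults`.
    """

    def __init__(self, observed: ObservedTrajectory, element: DriveElement,
                 gmap: GeneticMap, markers: MarkerGrid,
                 grid: np.ndarray = DEFAULT_GRID, replicates: int = 50,
                 popsize: int = 10_000, generations: int = 20,
                 window_cm: float | None = None, config: SimConfig | None = None):
        self.observed = observed
        self.element = element
        self.gmap = gmap
        self.markers = markers
        self.grid = np.asarray(grid, dtype=float)
        self.replicates = replicates
        self.popsize = popsize
        self.generations = generations
        self.window_cm = window_cm
        self.config = config

    def fit(self, seed: int | np.random.Generator | None = None,
            grid_fits: list[SGridFit] | None = None) -> SelectionCoefficientResults:
        if grid_fits is None:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            grid_fits = simulate_s_grid(self.element, self.gmap, self.markers, rng,
                                        self.grid, self.replicates, self.popsize,
                                        self.generations, self.window_cm, self.config)
        return fit_selection_coefficient(self.observed, grid_fits)
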