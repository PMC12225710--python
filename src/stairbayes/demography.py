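"""Transform theta samples into population-size trajectories and summaries.

The model is parameterised by ``theta_k = 4 N_k mu`` only; interval times
follow from the expected coalescent times:

    T_i = sum_{k=i}^{n} theta_k / (k (k - 1))

in units of expected substitutions per site.  Dividing by the per-site
per-generation mutation rate ``mu`` gives generations; multiplying by a
generation time gives years.  ``N_k = theta_k / (4 mu)``.

Each posterior sample defines a step function (``N_k`` on the half-open
interval ``[T_{k+1}, T_k)``, the most recent interval reaching time 0, and
the oldest size extended flat beyond ``T_2``).  Trajectories are summarised
on a plotting grid (default 500 log-spaced points up to the posterior 97.5%
quantile of ``T_2``) by the per-point posterior median and 95% credible
band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorTrace

__all__ = [
    "interval_times",
    "population_sizes",
    "step_function_values",
    "DemographicTrajectory",
    "summarize_trajectories",
    "plot_trajectory",
]


def interval_times(theta, mu: float | None = None) -> np.ndarray:
    """Start times ``T_2 >= T_3 >= ... >= T_n`` of the coalescent intervals.

    ``T_i`` is the expected time at which the sample first has ``i``
    ancestral lineages, in substitution units, or generations when ``mu``
    is given.
    """
    th = np.asarray(theta, dtype=float)
    n = th.shape[-1] + 1
    k = np.arange(2, n + 1)
    # T_i sums terms for k = i..n: reversed cumulative sum; extreme posterior
    # draws may overflow to inf, which propagates harmlessly through the
    # quantile summaries
    with np.errstate(over="ignore"):
        terms = th / (k * (k - 1.0))
        times = np.cumsum(terms[..., ::-1], axis=-1)[..., ::-1]
    if mu is not None:
        if mu <= 0:
            raise ValueError("mu must be positive")
        times = times / mu
    return times


def population_sizes(theta, mu: float) -> np.ndarray:
    """Per-interval effective sizes ``N_k = theta_k / (4 mu)``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    return np.asarray(theta, dtype=float) / (4.0 * mu)


def step_function_values(theta, grid: np.ndarray, mu: float | None = None,
                         sizes: np.ndarray | None = None) -> np.ndarray:
    """Evaluate one sample's size trajectory at the grid times.

    Right-continuous in time-before-present: a grid point ``t`` in
    ``[T_{k+1}, T_k)`` takes ``N_k``; points older than ``T_2`` take the
    oldest size.  ``sizes`` defaults to ``theta / (4 mu)`` (or raw theta
    when no ``mu`` is given, for substitution-scaled plots).
    """
    th = np.asarray(theta, dtype=float)
    times = interval_times(th, mu)
    if sizes is None:
        sizes = th / (4.0 * mu) if mu is not None else th
    # boundaries ascending: T_n < ... < T_2; interval k = n - j for bin j
    boundaries = times[::-1]  # T_n, T_{n-1}, ..., T_2
    idx = np.searchsorted(boundaries, grid, side="right")
    idx = np.minimum(idx, boundaries.size - 1)
    # bin j (between T_{n-j+1} and T_{n-j}) is interval k = n - j -> sizes index k-2
    sizes_chain = sizes[::-1]  # most recent first: N_n, ..., N_2
    return sizes_chain[idx]


@dataclass(frozen=True)
class DemographicTrajectory:
    """Posterior trajectory summary on a plotting grid.

    ``grid`` is time before present (generations when ``mu`` was supplied,
    years when a generation time was also given); ``median``, ``lower``,
    ``upper`` are the per-point posterior median and 2.5%/97.5% quantiles of
    the effective population size.
    """

    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    time_unit: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.grid,
                "median": self.median,
                "lower_2.5": self.lower,
                "upper_97.5": self.upper,
            }
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# stairbayes trajectory summary; time unit: {self.time_unit}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def summarize_trajectories(
    trace: PosteriorTrace | np.ndarray,
    mu: float | None = None,
    grid_points: int = 500,
    generation_time: float | None = None,
    grid: np.ndarray | None = None,
    log_spaced: bool = True,
) -> DemographicTrajectory:
    """Break every sampled trajectory into a fine grid and summarise.

    The grid spans from just above 0 to the posterior 97.5% quantile of the
    oldest time ``T_2`` (log-spaced by default), unless an explicit ``grid``
    is passed.
    """
    if isinstance(trace, PosteriorTrace):
        thetas = trace.theta_samples()
    else:
        thetas = np.atleast_2d(np.asarray(trace, dtype=float))
    if thetas.size == 0:
        raise ValueError("empty trace")
    if grid_points < 2:
        raise ValueError("need at least two grid points")

    scale = 1.0
    unit = "substitutions/site"
    if mu is not None:
        unit = "generations"
        if generation_time is not None:
            scale = generation_time
            unit = "years"

    t2 = interval_times(thetas, mu)[:, 0] * scale
    if grid is None:
        t_max = np.quantile(t2, 0.975)
        t_min = t_max / 1e4 if log_spaced else 0.0
        if log_spaced:
            grid = np.geomspace(t_min, t_max, grid_points)
        else:
            grid = np.linspace(t_min, t_max, grid_points)
    grid = np.asarray(grid, dtype=float)

    values = np.empty((thetas.shape[0], grid.size))
    for j, th in enumerate(thetas):
        values[j] = step_function_values(th, grid / scale, mu)
    lower, median, upper = np.quantile(values, [0.025, 0.5, 0.975], axis=0)
    return DemographicTrajectory(
        grid=grid, median=median, lower=lower, upper=upper, time_unit=unit
    )


def plot_trajectory(
    trajectory: DemographicTrajectory,
    path=None,
    ax=None,
    truth: tuple[np.ndarray, np.ndarray] | None = None,
    log_axes: bool = True,
):
    """Median line with shaded 95% band; x = time before present, y = N_e.

    ``truth`` is an optional (times, sizes) step function overlay.  Returns
    the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        trajectory.grid, trajectory.lower, trajectory.upper,
        alpha=0.3, color="seagreen", label="95% CI",
    )
    ax.plot(trajectory.grid, trajectory.median, color="darkgreen", label="median")
    if truth is not None:
        t, sizes = truth
        ax.step(t, sizes, where="post", color="black", label="truth")
    if log_axes:
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel(f"time before present ({trajectory.time_unit})")
    ax.set_ylabel("effective population size")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
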