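"""Synthetic SFS data with known truth: standard demographic scenarios.

Six single-population histories (constant size, two-epoch, exponential
growth with and without an ancient constant period, a complex expansion and
a bottleneck) are defined as continuous size functions ``N(t)`` of time
before present in generations.  Each maps to the model's own
discretization — one ``theta_k = 4 N_k mu`` per expected coalescent
interval — by a fixed-point iteration: interval times are computed from the
current theta, ``N`` is read off at each interval midpoint, and the loop
repeats until theta is self-consistent.

Sites are unlinked, so ``l`` sites are drawn in one multinomial sample over
the frequency classes (monomorphic probability by the complement rule).
The default mutation rate is 1.2e-8 per bp per generation; scenario
parameters are package defaults chosen to exercise the canonical qualitative
shapes, and the emitted truth (theta, times, sizes) is always whatever the
scenario object says.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .demography import interval_times
from .likelihood import polymorphic_probs
from .sfs_io import SiteFrequencySpectrum

__all__ = [
    "DemographicScenario",
    "SCENARIO_NAMES",
    "scenario",
    "scenario_to_theta",
    "simulate_sfs",
    "simulate_scenario",
    "run_polarization_experiment",
]

DEFAULT_MU = 1.2e-8  # per bp per generation


@dataclass(frozen=True)
class DemographicScenario:
    """A continuous demographic history plus sampling design.

    ``size_function`` maps time before present (generations, >= 0) to the
    effective population size at that time.  ``change_points`` lists the
    times at which the history is non-smooth (used only for plotting the
    truth as a step function).
    """

    name: str
    size_function: Callable[[np.ndarray], np.ndarray]
    mu: float = DEFAULT_MU
    n: int = 20
    l: int = 1_000_000
    change_points: tuple[float, ...] = ()
    params: dict = field(default_factory=dict)

    def size_at(self, t) -> np.ndarray:
        return np.asarray(self.size_function(np.asarray(t, dtype=float)))


def _constant(N0: float = 1e4):
    return lambda t: np.full_like(t, N0, dtype=float)


def _two_epoch(N_recent: float = 1e4, N_ancient: float = 1e5, t_change: float = 5e3):
    return lambda t: np.where(t < t_change, N_recent, N_ancient)


def _exp_growth(N0: float = 1e5, rate: float = 1e-4):
    # growth forward in time = decline backwards: N(t) = N0 * exp(-rate * t)
    return lambda t: N0 * np.exp(-rate * t)


def _exp_growth_constant(N0: float = 1e5, rate: float = 1e-4, t_const: float = 3e4):
    N_anc = N0 * math.exp(-rate * t_const)
    return lambda t: np.where(t < t_const, N0 * np.exp(-rate * t), N_anc)


def _complex_expansion(
    N_recent: float = 1e5, N_mid: float = 1e4, N_ancient: float = 3e4,
    t1: float = 5e3, t2: float = 3e4,
):
    return lambda t: np.where(t < t1, N_recent, np.where(t < t2, N_mid, N_ancient))


def _bottleneck(
    N0: float = 1e4, N_bottleneck: float = 1e3, N_ancient: float = 1e4,
    t_start: float = 2e3, t_end: float = 4e3,
):
    return lambda t: np.where(
        t < t_start, N0, np.where(t < t_end, N_bottleneck, N_ancient)
    )


_BUILDERS = {
    "constant": (_constant, ()),
    "two_epoch": (_two_epoch, (5e3,)),
    "exp_growth": (_exp_growth, ()),
    "exp_growth_constant": (_exp_growth_constant, (3e4,)),
    "complex_expansion": (_complex_expansion, (5e3, 3e4)),
    "bottleneck": (_bottleneck, (2e3, 4e3)),
}

SCENARIO_NAMES = tuple(_BUILDERS)


def scenario(
    name: str, mu: float = DEFAULT_MU, n: int = 20, l: int = 1_000_000, **params
) -> DemographicScenario:
    """Build a named scenario, overriding any of its size/time parameters."""
    try:
        builder, _ = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_BUILDERS)}"
        ) from None
    fn = builder(**params)
    changes: tuple[float, ...] = ()
    if name == "two_epoch":
        changes = (params.get("t_change", 5e3),)
    elif name == "exp_growth_constant":
        changes = (params.get("t_const", 3e4),)
    elif name == "complex_expansion":
        changes = (params.get("t1", 5e3), params.get("t2", 3e4))
    elif name == "bottleneck":
        changes = (params.get("t_start", 2e3), params.get("t_end", 4e3))
    return DemographicScenario(
        name=name, size_function=fn, mu=mu, n=n, l=l,
        change_points=changes, params=dict(params),
    )


def scenario_to_theta(
    scn: DemographicScenario,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-interval theta consistent with the continuous history.

    Fixed point of: theta -> interval times (generations) -> N at interval
    midpoints -> 4 N mu.  Converges in one step for a constant history.
    """
    n, mu = scn.n, scn.mu
    theta = np.full(n - 1, 4.0 * float(scn.size_at(0.0)) * mu)
    for _ in range(max_iter):
        times = interval_times(theta, mu)  # T_2..T_n in generations
        upper = times  # interval k ends at T_k
        lower = np.concatenate([times[1:], [0.0]])  # starts at T_{k+1}
        midpoints = 0.5 * (lower + upper)
        new_theta = 4.0 * scn.size_at(midpoints) * mu
        residual = np.max(np.abs(new_theta - theta) / theta)
        theta = new_theta
        if residual < tol:
            return theta
    raise RuntimeError(
        f"scenario-to-theta fixed point did not converge "
        f"(last max relative change {residual:.3g})"
    )


def truth_step_function(scn: DemographicScenario, t_max: float) -> tuple[np.ndarray, np.ndarray]:
    """(times, sizes) arrays of the true history for step plotting."""
    knots = np.concatenate([[0.0], np.asarray(scn.change_points), [t_max]])
    knots = np.unique(knots[knots <= t_max])
    mids = 0.5 * (knots[:-1] + knots[1:])
    return knots[:-1], scn.size_at(mids)


def simulate_sfs(
    theta, l: int, seed: int | np.random.Generator
) -> SiteFrequencySpectrum:
    """One multinomial draw of ``l`` unlinked sites over classes 0..n-1."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = polymorphic_probs(theta)
    if not probs.valid:
        raise ValueError("invalid theta: polymorphic probabilities sum to >= 1")
    n = len(probs.p) + 1
    p_full = np.concatenate([[1.0 - probs.p.sum()], probs.p])
    counts = rng.multinomial(int(l), p_full)
    return SiteFrequencySpectrum(
        n=n,
        counts=tuple(int(c) for c in counts[1:]),
        monomorphic_count=int(counts[0]),
        folded=False,
    )


def simulate_scenario(
    scn: DemographicScenario, seed: int | np.random.Generator
) -> tuple[SiteFrequencySpectrum, np.ndarray]:
    """Simulate a spectrum from a scenario; returns (sfs, true theta)."""
    theta = scenario_to_theta(scn)
    return simulate_sfs(theta, scn.l, seed), theta


def trajectory_deviation(
    median: np.ndarray, true_sizes: np.ndarray
) -> float:
    """Integrated absolute log10 deviation of a median trajectory from the
    truth, averaged over the grid points."""
    return float(np.mean(np.abs(np.log10(median) - np.log10(true_sizes))))


def run_polarization_experiment(
    scn: DemographicScenario,
    rho_grid=(0.0, 0.001, 0.005, 0.01, 0.05, 0.1),
    prior=None,
    mcmc=None,
    seed: int = 0,
    grid_points: int = 101,
):
    """Perturb, infer and score: per mis-polarization probability ``rho``,
    the integrated |log10| deviation of the posterior-median trajectory from
    the true history on a fixed grid.  The simulated spectrum and the MCMC
    stream are shared across ``rho`` values (paired design), so ``rho = 0``
    is the no-error baseline exactly.
    """
    import pandas as pd

    from .demography import summarize_trajectories
    from .mcmc import MCMCConfig, run_mcmc
    from .priors import PriorFamily, PriorSpec
    from .sfs_io import apply_polarization_error

    if prior is None:
        prior = PriorSpec(PriorFamily.GMRF1)
    if mcmc is None:
        mcmc = MCMCConfig(iterations=8000, replicates=1, seed=seed)

    theta_true = scenario_to_theta(scn)
    times_true = interval_times(theta_true, scn.mu)
    grid = np.geomspace(times_true[-1] / 2.0, times_true[0], grid_points)
    true_sizes = scn.size_at(grid)

    base = simulate_sfs(theta_true, scn.l, seed)
    rows = []
    for rho in rho_grid:
        perturbed = apply_polarization_error(base, rho, seed=seed + 1)
        trace = run_mcmc(perturbed, prior, mcmc=mcmc)
        traj = summarize_trajectories(trace, mu=scn.mu, grid=grid)
        rows.append(
            {
                "rho": rho,
                "deviation": trajectory_deviation(traj.median, true_sizes),
                "segregating_sites": perturbed.segregating_sites,
            }
        )
    return pd.DataFrame(rows)
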