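"""Reusable validation experiments: prior recovery, parameter recovery,
polarization-error sensitivity and model-selection sanity.

These drive the package end to end (simulate -> infer -> transform ->
score) at desk-scale problem sizes and are shared by the test suite and the
reproduction script.  Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .demography import interval_times, summarize_trajectories
from .mcmc import MCMCConfig, run_mcmc
from .model_selection import lpcv
from .priors import PriorFamily, PriorSpec, sample_prior
from .scenarios import (
    scenario,
    scenario_to_theta,
    simulate_sfs,
    trajectory_deviation,
)
from .sfs_io import SiteFrequencySpectrum, apply_polarization_error, fold_spectrum

__all__ = [
    "prior_recovery_ks",
    "constant_coverage",
    "two_epoch_direction",
    "polarization_ordering",
    "model_selection_margin",
]


def _zero_data_sfs(n: int) -> SiteFrequencySpectrum:
    return SiteFrequencySpectrum(
        n=n, counts=(0,) * (n - 1), monomorphic_count=0, folded=False
    )


def prior_recovery_ks(
    family: PriorFamily | str,
    n: int = 6,
    iterations: int = 40_000,
    seed: int = 0,
    n_prior_draws: int = 100_000,
) -> float:
    """Kolmogorov-Smirnov distance between the zero-data posterior and the
    prior, on the marginal of theta_2.

    With no sites the likelihood is identically zero, so the sampler must
    reproduce the prior — the standard MCMC correctness oracle.
    """
    spec = PriorSpec(PriorFamily(family))
    sfs = _zero_data_sfs(n)
    mcmc = MCMCConfig(
        iterations=iterations, replicates=1, seed=seed, target_samples=10_000,
        store_probs=False,
    )
    trace = run_mcmc(sfs, spec, mcmc=mcmc)
    posterior = trace.pooled()["theta_2"].to_numpy()
    rng = np.random.default_rng([seed, 202])
    prior_draws = np.array(
        [sample_prior(spec, n, rng).theta[0] for _ in range(n_prior_draws)]
    )
    # compare on the log scale: theta marginals span many decades under the
    # heavy-tailed hyperpriors (both samples share the same positivity floor)
    return float(ks_2samp(np.log10(posterior), np.log10(prior_draws)).statistic)


@dataclass
class CoverageResult:
    coverage: float  # fraction of (seed, grid point) pairs covering truth
    per_seed: np.ndarray
    deviation: float  # mean integrated |log10| error of the median


def constant_coverage(
    n_seeds: int = 20,
    iterations: int = 20_000,
    seed: int = 0,
    n: int = 20,
    l: int = 1_000_000,
    N0: float = 1e4,
    grid_points: int = 101,
    family: PriorFamily = PriorFamily.GMRF1,
) -> CoverageResult:
    """Simulate-and-recover on the constant-size history.

    For each replicate seed: draw an SFS (theta = 4 N0 mu = 4.8e-4 at the
    defaults), run the sampler, and check at each grid point whether the
    posterior 95% band covers the flat truth.
    """
    scn = scenario("constant", n=n, l=l, N0=N0)
    theta_true = scenario_to_theta(scn)
    times = interval_times(theta_true, scn.mu)
    grid = np.geomspace(times[-1] / 2.0, times[0], grid_points)
    covered = np.empty(n_seeds)
    deviations = np.empty(n_seeds)
    for j in range(n_seeds):
        rng = np.random.default_rng([seed, j])
        sfs = simulate_sfs(theta_true, l, rng)
        mcmc = MCMCConfig(
            iterations=iterations, replicates=1, seed=seed * 1000 + j,
            target_samples=1000, store_probs=False,
        )
        trace = run_mcmc(sfs, PriorSpec(family), mcmc=mcmc)
        traj = summarize_trajectories(trace, mu=scn.mu, grid=grid)
        covered[j] = np.mean((traj.lower <= N0) & (N0 <= traj.upper))
        deviations[j] = trajectory_deviation(traj.median, np.full(grid.size, N0))
    return CoverageResult(
        coverage=float(covered.mean()),
        per_seed=covered,
        deviation=float(deviations.mean()),
    )


def two_epoch_direction(
    seed: int = 0,
    iterations: int = 20_000,
    n: int = 20,
    l: int = 1_000_000,
) -> dict[str, float]:
    """Two-epoch recovery under the horseshoe prior: the posterior-median
    trajectory should step from the recent size up to the ancient size.

    Returns the median sizes at the young and old ends of the grid; correct
    qualitative recovery means ``recent < ancient`` (here 1e4 vs 1e5).
    """
    scn = scenario("two_epoch", n=n, l=l)
    theta_true = scenario_to_theta(scn)
    sfs = simulate_sfs(theta_true, l, np.random.default_rng([seed, 7]))
    mcmc = MCMCConfig(
        iterations=iterations, replicates=1, seed=seed, target_samples=1000,
        store_probs=False,
    )
    trace = run_mcmc(sfs, PriorSpec(PriorFamily.HSMRF1), mcmc=mcmc)
    times = interval_times(theta_true, scn.mu)
    grid = np.geomspace(times[-1] / 2.0, times[0], 101)
    traj = summarize_trajectories(trace, mu=scn.mu, grid=grid)
    young = float(np.median(traj.median[grid < 2e3]))
    old = float(np.median(traj.median[grid > 1.5e4]))
    return {"recent_median": young, "ancient_median": old, "ratio": old / young}


def polarization_ordering(
    rhos=(0.0, 0.005, 0.05),
    n_seeds: int = 5,
    iterations: int = 8_000,
    seed: int = 0,
    n: int = 20,
    l: int = 1_000_000,
) -> "object":
    """Mean integrated trajectory error per mis-polarization probability,
    averaged over paired replicate seeds (same base SFS and MCMC stream for
    every rho)."""
    import pandas as pd

    from .scenarios import run_polarization_experiment

    scn = scenario("constant", n=n, l=l)
    frames = []
    for j in range(n_seeds):
        mcmc_j = MCMCConfig(
            iterations=iterations, replicates=1, seed=seed * 1000 + j,
            target_samples=1000, store_probs=False,
        )
        df = run_polarization_experiment(
            scn, rho_grid=rhos, mcmc=mcmc_j, seed=seed * 100 + j
        )
        df["seed"] = j
        frames.append(df)
    all_runs = pd.concat(frames, ignore_index=True)
    return all_runs.groupby("rho", as_index=False)["deviation"].mean()


def folded_polarization_invariance(
    rho: float = 0.05, seed: int = 0, n: int = 20, l: int = 200_000,
    iterations: int = 2_000,
) -> bool:
    """Folding erases polarization: the folded spectra of the clean and
    perturbed data are identical, so folded inference (same seed) returns
    bit-identical traces."""
    scn = scenario("constant", n=n, l=l)
    theta_true = scenario_to_theta(scn)
    sfs = simulate_sfs(theta_true, l, np.random.default_rng([seed, 3]))
    perturbed = apply_polarization_error(sfs, rho, seed=seed + 11)
    folded_clean = fold_spectrum(sfs)
    folded_pert = fold_spectrum(perturbed)
    if folded_clean.counts != folded_pert.counts:
        return False
    mcmc = MCMCConfig(iterations=iterations, replicates=1, seed=seed,
                      target_samples=500, store_probs=False)
    spec = PriorSpec(PriorFamily.GMRF1)
    t1 = run_mcmc(folded_clean, spec, mcmc=mcmc)
    t2 = run_mcmc(folded_pert, spec, mcmc=mcmc)
    return all(a.equals(b) for a, b in zip(t1.replicates, t2.replicates))


def model_selection_margin(
    n_seeds: int = 10,
    iterations: int = 6_000,
    seed: int = 0,
    n: int = 20,
    l: int = 1_000_000,
) -> np.ndarray:
    """Per-seed LPCV margin of HSMRF1 over the best constant-capable family
    (GMRF1 / IID uniform) on constant-truth data.

    A positive mean beyond Monte-Carlo noise would mean the horseshoe prior
    is spuriously preferred on data without jumps.
    """
    scn = scenario("constant", n=n, l=l)
    theta_true = scenario_to_theta(scn)
    margins = np.empty(n_seeds)
    families = [PriorFamily.HSMRF1, PriorFamily.GMRF1, PriorFamily.IID_UNIFORM]
    for j in range(n_seeds):
        sfs = simulate_sfs(theta_true, l, np.random.default_rng([seed, 17, j]))
        scores = {}
        for fam in families:
            mcmc = MCMCConfig(
                iterations=iterations, replicates=1, seed=seed * 1000 + j,
                target_samples=1000,
            )
            trace = run_mcmc(sfs, PriorSpec(fam), mcmc=mcmc)
            scores[fam] = lpcv(trace).score
        margins[j] = scores[PriorFamily.HSMRF1] - max(
            scores[PriorFamily.GMRF1], scores[PriorFamily.IID_UNIFORM]
        )
    return margins
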