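"""Metropolis-within-Gibbs sampler over the prior-family state space.

The posterior is proportional to the composite multinomial likelihood times
the family's prior.  One *iteration* is a sweep: every scheduled move is
applied once (single-parameter multiplier moves once per coordinate), namely

* per-coordinate log-scale multiplier proposals with the multiplicative
  Hastings correction, auto-tuned towards 0.44 acceptance during burn-in;
* a joint up-down rescaling of all size-valued parameters (target 0.23);
* family-specific moves: skyline group-boundary shifts, reversible-jump
  equality toggles and inert-value refreshes;
* occasionally, an independence redraw from the prior (Hastings ratio equals
  the likelihood ratio, since the prior proposal cancels the prior density).

Invalid states (log-likelihood ``-inf``) are certain rejections; auto-tuning
stops at the end of burn-in so the retained chain is a fixed Markov kernel.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import CompositeLikelihood, LikelihoodConfig
from .priors import Family, PriorSpec, make_family
from .sfs_io import SiteFrequencySpectrum

__all__ = [
    "MCMCConfig",
    "PosteriorTrace",
    "run_mcmc",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.  ``iterations`` counts sweeps; ``thin`` defaults to
    whatever retains about ``target_samples`` draws per replicate."""

    iterations: int = 500_000
    replicates: int = 4
    burnin_fraction: float = 0.1
    thin: int | None = None
    seed: int = 0
    target_samples: int = 2000
    tuning_window: int = 50
    prior_redraw_weight: float = 0.1
    store_probs: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.burnin_fraction <= 0.5:
            raise ValueError("burnin_fraction must be in [0, 0.5]")
        if self.thin is not None and self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.iterations < 1 or self.replicates < 1:
            raise ValueError("iterations and replicates must be positive")

    def resolved_thin(self) -> int:
        if self.thin is not None:
            return self.thin
        kept = self.iterations - self.burnin_iterations()
        return max(1, kept // self.target_samples)

    def burnin_iterations(self) -> int:
        return int(self.iterations * self.burnin_fraction)


@dataclass
class PosteriorTrace:
    """Thinned post-burn-in samples, one DataFrame per replicate run.

    Columns: ``Iteration``, ``Posterior``, ``Likelihood``, ``Prior``,
    ``theta_2 .. theta_n``, family hyperparameter columns, and (when stored)
    the conditioned site-class probabilities ``p_<class>`` that the
    leave-one-out cross-validation score is computed from.
    ``modeled_counts`` are the observed counts aligned with the p columns.
    """

    replicates: list[pd.DataFrame]
    n: int
    prior_spec: PriorSpec
    like_config: LikelihoodConfig
    p_columns: list[str]
    modeled_counts: np.ndarray
    seed: int
    acceptance: list[dict[str, float]] = field(default_factory=list)

    @property
    def theta_columns(self) -> list[str]:
        return [f"theta_{k}" for k in range(2, self.n + 1)]

    def pooled(self) -> pd.DataFrame:
        return pd.concat(self.replicates, ignore_index=True)

    def theta_samples(self) -> np.ndarray:
        return self.pooled()[self.theta_columns].to_numpy()

    def p_samples(self) -> np.ndarray:
        if not self.p_columns:
            raise ValueError("trace was run with store_probs=False")
        return self.pooled()[self.p_columns].to_numpy()

    def p_samples_per_replicate(self) -> list[np.ndarray]:
        return [df[self.p_columns].to_numpy() for df in self.replicates]

    def write(self, directory, prefix: str = "trace") -> list[str]:
        """One TSV per replicate, loadable by standard trace viewers."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for r, df in enumerate(self.replicates):
            path = directory / f"{prefix}_run{r + 1}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(
                    f"# stairbayes trace: prior={self.prior_spec.family.value} "
                    f"seed={self.seed} replicate={r + 1}\n"
                )
                df.to_csv(fh, sep="\t", index=False)
            paths.append(str(path))
        return paths


class _Tuner:
    """Robbins-Monro style adaptation of a multiplier-move window."""

    def __init__(self, lam: float, target: float):
        self.lam = lam
        self.target = target
        self.tries = 0
        self.accepts = 0

    def record(self, accepted: bool) -> None:
        self.tries += 1
        self.accepts += accepted

    def adapt(self) -> None:
        if self.tries == 0:
            return
        rate = self.accepts / self.tries
        self.lam *= math.exp(0.7 * (rate - self.target))
        self.lam = min(max(self.lam, 1e-3), 20.0)
        self.tries = 0
        self.accepts = 0


class _ReplicateSampler:
    def __init__(
        self,
        fam: Family,
        lik: CompositeLikelihood,
        config: MCMCConfig,
        rng: np.random.Generator,
    ):
        self.fam = fam
        self.lik = lik
        self.config = config
        self.rng = rng
        self.tuners: dict = {}
        self.joint_tuner = _Tuner(0.3, 0.23)
        self.accept_counts: dict[str, list[int]] = {}
        self._init_state()

    # -- initialization ----------------------------------------------------
    def _init_state(self) -> None:
        for _ in range(1000):
            state = self.fam.sample_state(self.rng)
            lp = self.fam.log_density(state)
            ll = self.lik(self.fam.theta_from_state(state))
            if np.isfinite(lp + ll):
                self.state, self.lp, self.ll = state, lp, ll
                return
        state = self._moment_start()
        if state is not None:
            lp = self.fam.log_density(state)
            ll = self.lik(self.fam.theta_from_state(state))
            if np.isfinite(lp + ll):
                logger.info("prior initialization failed; using moment start")
                self.state, self.lp, self.ll = state, lp, ll
                return
        raise RuntimeError(
            "could not initialize the chain: the likelihood is -inf for 1000 "
            "prior draws and the Watterson-style moment start; try a prior "
            "with smaller theta support"
        )

    def _moment_start(self):
        """Watterson-style start: all theta equal to S / (l * sum 1/i)."""
        sfs = self.lik.sfs
        l_total = sfs.total_sites
        if l_total is None or l_total == 0:
            return None
        harm = np.sum(1.0 / np.arange(1, sfs.n))
        value = max(sfs.segregating_sites / (l_total * harm), 1e-10)
        return _state_from_constant(self.fam, value)

    # -- moves -------------------------------------------------------------
    def _metropolis(self, new_state, log_hastings: float, theta_changed: bool,
                    name: str) -> bool:
        new_lp = self.fam.log_density(new_state)
        if not np.isfinite(new_lp):
            self._count(name, False)
            return False
        new_ll = (
            self.lik(self.fam.theta_from_state(new_state))
            if theta_changed
            else self.ll
        )
        log_ratio = (new_lp + new_ll) - (self.lp + self.ll) + log_hastings
        accept = np.isfinite(new_ll) and (
            log_ratio >= 0.0 or math.log(self.rng.random()) < log_ratio
        )
        if accept:
            self.state, self.lp, self.ll = new_state, new_lp, new_ll
        self._count(name, accept)
        return accept

    def _count(self, name: str, accepted: bool) -> None:
        tries = self.accept_counts.setdefault(name, [0, 0])
        tries[0] += 1
        tries[1] += accepted

    def sweep(self, tuning: bool) -> None:
        fam, rng = self.fam, self.rng
        theta_keys = set(fam.theta_keys)
        for key in (*fam.positive_keys, *fam.log_scale_keys):
            value = self.state[key]
            theta_changed = key in theta_keys
            additive = key in fam.log_scale_keys
            if np.ndim(value) == 0:
                self._scale_move(key, None, theta_changed, tuning, additive)
            else:
                for idx in range(len(value)):
                    self._scale_move(key, idx, theta_changed, tuning, additive)
        self._joint_move(tuning)
        for new_state, log_h in fam.special_moves(self.state, rng):
            self._metropolis(new_state, log_h, True, "special")
        if rng.random() < self.config.prior_redraw_weight:
            self._prior_redraw()

    def _scale_move(self, key, idx, theta_changed: bool, tuning: bool,
                    additive: bool = False) -> None:
        """Log-scale multiplier proposal; for log-stored parameters the same
        move is an additive shift of the log value (identical Hastings)."""
        tuner = self.tuners.setdefault((key, idx), _Tuner(1.0, 0.44))
        u = self.rng.random()
        delta = tuner.lam * (u - 0.5)
        new_state = dict(self.state)
        if idx is None:
            old = float(self.state[key])
            new_state[key] = old + delta if additive else old * math.exp(delta)
        else:
            arr = self.state[key].copy()
            if additive:
                arr[idx] += delta
            else:
                arr[idx] *= math.exp(delta)
            new_state[key] = arr
        accepted = self._metropolis(new_state, delta, theta_changed, f"scale_{key}")
        if tuning:
            tuner.record(accepted)

    def _joint_move(self, tuning: bool) -> None:
        tuner = self.joint_tuner
        u = self.rng.random()
        delta = tuner.lam * (u - 0.5)
        new_state = dict(self.state)
        dim = 0
        for key in self.fam.theta_keys:
            if key in self.fam.log_scale_keys:
                new_state[key] = self.state[key] + delta
            else:
                new_state[key] = self.state[key] * math.exp(delta)
            dim += np.size(self.state[key])
        accepted = self._metropolis(new_state, dim * delta, True, "joint_scale")
        if tuning:
            tuner.record(accepted)

    def _prior_redraw(self) -> None:
        """Independence proposal from the prior: the prior densities cancel,
        leaving the likelihood ratio."""
        new_state = self.fam.sample_state(self.rng)
        new_lp = self.fam.log_density(new_state)
        if not np.isfinite(new_lp):
            self._count("prior_redraw", False)
            return
        new_ll = self.lik(self.fam.theta_from_state(new_state))
        log_ratio = new_ll - self.ll
        accept = np.isfinite(new_ll) and (
            log_ratio >= 0.0 or math.log(self.rng.random()) < log_ratio
        )
        if accept:
            self.state, self.lp, self.ll = new_state, new_lp, new_ll
        self._count("prior_redraw", accept)

    def adapt(self) -> None:
        for tuner in self.tuners.values():
            tuner.adapt()
        self.joint_tuner.adapt()

    def acceptance_rates(self) -> dict[str, float]:
        return {
            name: (acc / tries if tries else float("nan"))
            for name, (tries, acc) in self.accept_counts.items()
        }


def _state_from_constant(fam: Family, value: float) -> dict:
    """A family state whose theta vector is constant at ``value``."""
    from . import priors as _p

    L = fam.L
    if isinstance(fam, _p.BSPGrouped):
        b = fam.b
        sizes = np.full(b, L // b, dtype=np.int64)
        sizes[: L - sizes.sum()] += 1
        return {"group_sizes": sizes, "group_values": np.full(b, value)}
    if isinstance(fam, _p.RJ):
        return {
            "values": np.full(L, value),
            "equal": np.zeros(L - 1, dtype=bool),
        }
    if isinstance(fam, _p.IGR):
        return {"ln_s": np.full(L, math.log(value)), "m": value, "v": fam.v_mean}
    if isinstance(fam, _p._MRF):
        state: dict = {"ln_s": np.full(L, math.log(value))}
        if isinstance(fam, _p.HSMRF):
            state["local"] = np.ones(L - 1)
            if fam.estimate_scale:
                state["gamma"] = fam.gamma0
        elif fam.estimate_scale:
            state["xi"] = fam.xi0
        return state
    state = {"s": np.full(L, value)}
    if isinstance(fam, _p.UCLN):
        state.update(mu=value, sigma=fam.sigma_mean)
    return state


def _p_column_names(lik: CompositeLikelihood) -> list[str]:
    from .likelihood import Conditioning

    n = lik.n
    folded = lik.sfs.folded
    top = n // 2 if folded else n - 1
    cond = lik.config.conditioning
    if cond is Conditioning.NONE:
        classes = list(range(0, top + 1))
    elif cond is Conditioning.NO_MONOMORPHIC:
        classes = list(range(1, top + 1))
    else:
        classes = list(range(2, top + 1)) if folded else list(range(2, n - 1))
    return [f"p_{i}" for i in classes]


def run_mcmc(
    sfs: SiteFrequencySpectrum,
    prior: PriorSpec,
    like_config: LikelihoodConfig | None = None,
    mcmc: MCMCConfig = MCMCConfig(),
) -> PosteriorTrace:
    """Sample the posterior over the prior family's state; deterministic for
    a given ``mcmc.seed``, with per-replicate streams kept separate."""
    if like_config is None:
        like_config = LikelihoodConfig.for_sfs(sfs)
    lik = CompositeLikelihood(sfs, like_config)
    thin = mcmc.resolved_thin()
    burnin = mcmc.burnin_iterations()
    p_cols = _p_column_names(lik) if mcmc.store_probs else []
    theta_cols = [f"theta_{k}" for k in range(2, sfs.n + 1)]

    replicate_frames = []
    acceptance = []
    for r in range(mcmc.replicates):
        rng = np.random.default_rng([mcmc.seed % (2**31), r])
        fam = make_family(prior, sfs.n)
        sampler = _ReplicateSampler(fam, lik, mcmc, rng)
        rows = []
        for it in range(mcmc.iterations):
            tuning = it < burnin
            sampler.sweep(tuning)
            if tuning and (it + 1) % mcmc.tuning_window == 0:
                sampler.adapt()
            if it >= burnin and (it - burnin) % thin == 0:
                theta = fam.theta_from_state(sampler.state)
                row = [it, sampler.lp + sampler.ll, sampler.ll, sampler.lp]
                row.extend(theta)
                hyper = fam.hyper_columns(sampler.state)
                row.extend(hyper.values())
                if mcmc.store_probs:
                    row.extend(lik.class_probabilities(theta).p)
                rows.append(row)
        hyper_cols = list(fam.hyper_columns(sampler.state).keys())
        columns = (
            ["Iteration", "Posterior", "Likelihood", "Prior"]
            + theta_cols
            + hyper_cols
            + p_cols
        )
        frame = pd.DataFrame(rows, columns=columns)
        replicate_frames.append(frame)
        acceptance.append(sampler.acceptance_rates())
        logger.info(
            "replicate %d/%d: %d retained samples, acceptance %s",
            r + 1,
            mcmc.replicates,
            len(frame),
            sampler.acceptance_rates(),
        )

    return PosteriorTrace(
        replicates=replicate_frames,
        n=sfs.n,
        prior_spec=prior,
        like_config=like_config,
        p_columns=p_cols,
        modeled_counts=lik.counts.copy(),
        seed=mcmc.seed,
        acceptance=acceptance,
    )


def effective_sample_size(
    trace: PosteriorTrace | np.ndarray, param: str | None = None
) -> dict[str, float]:
    """Autocorrelation-based ESS plus the across-replicate potential scale
    reduction (R-hat), via ArviZ.

    ``trace`` is either a :class:`PosteriorTrace` (with ``param`` naming a
    column) or a raw sample array of shape ``(draws,)`` or
    ``(chains, draws)``.
    """
    import arviz as az

    if isinstance(trace, PosteriorTrace):
        if param is None:
            raise ValueError("name the trace column to analyse")
        chains = np.stack([df[param].to_numpy() for df in trace.replicates])
    else:
        chains = np.atleast_2d(np.asarray(trace, dtype=float))
    if chains.shape[1] < 100:
        raise ValueError("need at least 100 retained samples per replicate")
    if np.allclose(chains, chains[..., :1]):
        warnings.warn(
            "trace is constant; ESS is reported as the number of samples "
            "but the chain is degenerate",
            stacklevel=2,
        )
        return {"ess": float(chains.size), "rhat": float("nan")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(chains))
        rhat = float(az.rhat(chains)) if chains.shape[0] > 1 else float("nan")
    return {"ess": ess, "rhat": rhat}
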