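"""Prior models on the per-interval scaled population sizes ``theta_k``.

Nine families, spanning the no-shrinkage to strict-shrinkage continuum used
for Bayesian skyline plots:

* ``IID_UNIFORM`` — theta_i ~ Uniform(0, 0.1), independently.
* ``UCLN`` — uncorrelated lognormal: a shared median ``mu ~ Loguniform`` and
  log-scale SD ``sigma ~ Exponential(mean 3H)``; theta_i ~ Lognormal.
* ``IGR`` — independent gamma rates: shared mean ``m ~ Loguniform`` and
  variance ``v ~ Exponential(mean 0.01)``; theta_i ~ Gamma(m^2/v, rate m/v).
* ``BSP_GROUPED`` — Bayesian-skyline grouping: ``b`` groups of consecutive
  intervals share one value; group sizes flat (>= 1 each), group values
  autocorrelated exponential (each group's mean is the previous value).
* ``RJ`` — reversible-jump grouping: each interval equals its predecessor
  with probability ``beta`` or draws a fresh Uniform(0, 0.1) value.
* ``GMRF1`` / ``GMRF2`` — Gaussian Markov random field: first or second
  differences of ``ln theta`` are Normal(0, xi).
* ``HSMRF1`` / ``HSMRF2`` — Horseshoe MRF: per-step scales
  ``gamma * xi_i`` with local ``xi_i ~ HalfCauchy(0, 1)``, allowing abrupt
  jumps between periods of stasis.

Markov chains (BSP, RJ, MRF) are anchored at the most recent interval
(``k = n``) and run backwards in time by default; ``orientation="past"``
anchors at ``k = 2`` instead.  The anchored element carries a Uniform(0, 0.1)
base prior.  MRF densities include the ``d ln theta -> d theta`` Jacobian so
that ``exp(log_prior_density)`` is a proper density on theta-space.

``H = 0.587405`` is the log-scale SD whose lognormal 95% central interval
spans exactly one order of magnitude; it calibrates the UCLN hyperprior and
the default GMRF global scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

__all__ = [
    "PriorFamily",
    "PriorSpec",
    "PriorState",
    "lognormal_interval_sd",
    "H",
    "default_group_count",
    "sample_prior",
    "log_prior_density",
    "make_family",
    "FAMILY_ORDER",
]

LOG_2PI = math.log(2.0 * math.pi)

# floor for generative draws of theta: extreme hyperparameter draws (e.g. a
# gamma shape of 1e-14 under the IGR hyperpriors) produce values that
# underflow double precision to 0, where the log-density degenerates; the
# floor keeps draw and density consistent at the smallest normal double
_THETA_FLOOR = 2.2250738585072014e-308


def lognormal_interval_sd(orders_of_magnitude: float = 1.0) -> float:
    """Log-scale SD whose lognormal 95% central interval spans the given
    number of orders of magnitude: ``ln(10^o) / (2 z_0.975)``."""
    return float(
        orders_of_magnitude * math.log(10.0) / (2.0 * norm.ppf(0.975))
    )


H = 0.587405  # lognormal_interval_sd(1.0), rounded as conventionally quoted


class PriorFamily(str, Enum):
    IID_UNIFORM = "IID_UNIFORM"
    UCLN = "UCLN"
    IGR = "IGR"
    BSP_GROUPED = "BSP_GROUPED"
    RJ = "RJ"
    GMRF1 = "GMRF1"
    GMRF2 = "GMRF2"
    HSMRF1 = "HSMRF1"
    HSMRF2 = "HSMRF2"


FAMILY_ORDER = [f for f in PriorFamily]

# sampled-hyperparameter count per family, used as the complexity tie-break
# in model selection (fewer = simpler)
N_SAMPLED_HYPERS = {
    PriorFamily.IID_UNIFORM: 0,
    PriorFamily.GMRF1: 0,
    PriorFamily.GMRF2: 0,
    PriorFamily.UCLN: 2,
    PriorFamily.IGR: 2,
    PriorFamily.BSP_GROUPED: 1,
    PriorFamily.RJ: 1,
    PriorFamily.HSMRF1: 3,
    PriorFamily.HSMRF2: 3,
}


def default_group_count(m: int) -> int:
    """Default number of skyline groups, ``round(2m / 4)`` (round-half-even),
    floored at 1 — a priori about four coalescent intervals per group."""
    if m < 1:
        raise ValueError("need at least one diploid individual")
    return max(1, round(2 * m / 4))


@dataclass(frozen=True)
class PriorSpec:
    """Identity and fixed hyperparameters of one prior family.

    ``hyperparams`` overrides family defaults: ``uniform_max`` (0.1),
    ``loguniform_bounds`` ((1e-10, 1.0)), ``sigma_mean`` (3H), ``v_mean``
    (0.01), ``b`` (group count; default round(2m/4)), ``beta`` (0.5),
    ``xi`` (GMRF global scale; default H / sqrt(n - 2)), ``gamma`` (0.021),
    ``orientation`` ("present" or "past").
    """

    family: PriorFamily
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", PriorFamily(self.family))

    def get(self, key: str, default):
        return self.hyperparams.get(key, default)


@dataclass
class PriorState:
    """A realisation of theta (ordered ``k = 2..n``) plus the family's sampled
    hyperparameters (internal representation; see each family's docstring)."""

    theta: np.ndarray
    hypers: dict[str, Any]


# ---------------------------------------------------------------------------
# hand-inlined log-densities (scipy.stats is the oracle in the test suite;
# these run inside the MCMC hot loop)

def _log_uniform01(x, upper: float) -> float:
    x = np.atleast_1d(x)
    if np.any(x <= 0.0) or np.any(x >= upper):
        return -np.inf
    return -x.size * math.log(upper)


def _log_loguniform(x: float, a: float, b: float) -> float:
    if not a < x < b:
        return -np.inf
    return -math.log(x) - math.log(math.log(b / a))


def _log_exponential_mean(x: float, mean: float) -> float:
    if x <= 0.0:
        return -np.inf
    return -math.log(mean) - x / mean


def _log_normal(x, loc, scale) -> float:
    z = (np.asarray(x) - loc) / scale
    return float(np.sum(-0.5 * z * z - np.log(scale) - 0.5 * LOG_2PI))


def _log_halfcauchy(x, scale: float) -> float:
    x = np.atleast_1d(x)
    if np.any(x <= 0.0):
        return -np.inf
    return float(
        np.sum(math.log(2.0 / math.pi) - math.log(scale) - np.log1p((x / scale) ** 2))
    )


# ---------------------------------------------------------------------------

class Family:
    """One prior family instantiated for a given sample size.

    The internal state is a dict of numpy arrays; ``theta_from_state``
    assembles the ``k = 2..n`` vector.  ``positive_keys`` lists state entries
    updated by multiplicative scale moves, ``theta_keys`` the entries rescaled
    by the joint up-down move.  Sequence-valued entries are stored in *chain
    order* (anchored end first).
    """

    #: state keys receiving per-coordinate multiplier moves
    positive_keys: tuple[str, ...] = ("s",)
    #: state keys stored on the log scale (multiplier moves become additive
    #: there, with the same Hastings term)
    log_scale_keys: tuple[str, ...] = ()
    #: state keys jointly rescaled by the up-down move
    theta_keys: tuple[str, ...] = ("s",)

    def __init__(self, spec: PriorSpec, n: int):
        if n < 2:
            raise ValueError("n must be >= 2")
        self.spec = spec
        self.n = n
        self.L = n - 1
        self.upper = float(spec.get("uniform_max", 0.1))
        self.orientation = spec.get("orientation", "present")
        if self.orientation not in ("present", "past"):
            raise ValueError("orientation must be 'present' or 'past'")

    # -- chain order <-> theta order -------------------------------------
    def theta_from_state(self, state: dict) -> np.ndarray:
        s = self.sequence(state)
        return s[::-1].copy() if self.orientation == "present" else s.copy()

    def sequence(self, state: dict) -> np.ndarray:
        return state["s"]

    # -- density ----------------------------------------------------------
    def log_density(self, state: dict) -> float:
        parts = self.log_density_components(state)
        return parts["theta"] + parts["hypers"]

    def log_density_components(self, state: dict) -> dict[str, float]:
        raise NotImplementedError

    def sample_state(self, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    # -- trace output ------------------------------------------------------
    def hyper_columns(self, state: dict) -> dict[str, float]:
        return {}

    # -- extra (family-specific) MCMC moves --------------------------------
    def special_moves(self, state: dict, rng: np.random.Generator):
        """Yield (new_state, log_hastings) proposals beyond generic scaling."""
        return []


class IIDUniform(Family):
    """theta_i ~ Uniform(0, upper), i.i.d.  State: {"s"}."""

    def sample_state(self, rng):
        return {"s": rng.uniform(0.0, self.upper, self.L)}

    def log_density_components(self, state):
        return {"theta": _log_uniform01(state["s"], self.upper), "hypers": 0.0}


class UCLN(Family):
    """Uncorrelated lognormal.  State: {"s", "mu", "sigma"}; ``mu`` is the
    lognormal median (log-scale location ``ln mu``)."""

    positive_keys = ("s", "mu", "sigma")

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.lu_bounds = spec.get("loguniform_bounds", (1e-10, 1.0))
        self.sigma_mean = float(spec.get("sigma_mean", 3.0 * H))

    def sample_state(self, rng):
        a, b = self.lu_bounds
        mu = math.exp(rng.uniform(math.log(a), math.log(b)))
        sigma = rng.exponential(self.sigma_mean)
        s = np.maximum(np.exp(rng.normal(math.log(mu), sigma, self.L)), _THETA_FLOOR)
        return {"s": s, "mu": mu, "sigma": sigma}

    def log_density_components(self, state):
        mu, sigma = float(state["mu"]), float(state["sigma"])
        hy = _log_loguniform(mu, *self.lu_bounds) + _log_exponential_mean(
            sigma, self.sigma_mean
        )
        if not np.isfinite(hy):
            return {"theta": -np.inf, "hypers": hy}
        s = state["s"]
        if np.any(s <= 0.0):
            return {"theta": -np.inf, "hypers": hy}
        ln_s = np.log(s)
        th = _log_normal(ln_s, math.log(mu), sigma) - float(ln_s.sum())
        return {"theta": th, "hypers": hy}

    def hyper_columns(self, state):
        return {"ucln_mu": float(state["mu"]), "ucln_sigma": float(state["sigma"])}


class IGR(Family):
    """Independent gamma rates.  State: {"ln_s", "m", "v"}; theta_i ~
    Gamma(shape m^2/v, rate m/v) so E = m, Var = v.

    The hyperpriors routinely give shapes far below 1, where gamma draws
    underflow double precision; theta is therefore stored as ln theta (the
    generative draw uses the Gamma(shape+1) * U^(1/shape) representation on
    the log scale), while the reported density stays the theta-space density
    evaluated from ln theta without round-tripping through exp.
    """

    positive_keys = ("m", "v")
    log_scale_keys = ("ln_s",)
    theta_keys = ("ln_s",)

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.lu_bounds = spec.get("loguniform_bounds", (1e-10, 1.0))
        self.v_mean = float(spec.get("v_mean", 0.01))

    def sequence(self, state):
        return np.maximum(np.exp(state["ln_s"]), _THETA_FLOOR)

    def sample_state(self, rng):
        a, b = self.lu_bounds
        m = math.exp(rng.uniform(math.log(a), math.log(b)))
        v = rng.exponential(self.v_mean)
        shape = m * m / v
        # X = scale * G * U^(1/shape) with G ~ Gamma(shape + 1) is an exact
        # Gamma(shape) draw whose log never underflows
        g = rng.gamma(shape + 1.0, 1.0, self.L)
        ln_s = (
            math.log(v / m)
            + np.log(g)
            + np.log(rng.uniform(size=self.L)) / shape
        )
        return {"ln_s": ln_s, "m": m, "v": v}

    def log_density_components(self, state):
        m, v = float(state["m"]), float(state["v"])
        hy = _log_loguniform(m, *self.lu_bounds) + _log_exponential_mean(v, self.v_mean)
        if not np.isfinite(hy):
            return {"theta": -np.inf, "hypers": hy}
        ln_s = state["ln_s"]
        shape, rate = m * m / v, m / v
        with np.errstate(over="ignore"):
            s = np.exp(ln_s)  # underflow to 0 is fine inside -rate*s
        if np.any(np.isinf(s)):
            return {"theta": -np.inf, "hypers": hy}
        th = float(
            np.sum(
                shape * math.log(rate)
                - gammaln(shape)
                + (shape - 1.0) * ln_s
                - rate * s
            )
        )
        return {"theta": th, "hypers": hy}

    def hyper_columns(self, state):
        return {"igr_m": float(state["m"]), "igr_v": float(state["v"])}


class BSPGrouped(Family):
    """Grouped skyline.  State: {"group_sizes", "group_values"} in chain
    order (group 0 anchored at the present by default).  Sizes are a flat
    composition of ``n - 1`` into ``b`` parts (each >= 1); values follow
    the autocorrelated exponential chain with a Uniform(0, upper) anchor.
    """

    positive_keys = ("group_values",)
    theta_keys = ("group_values",)

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.b = int(spec.get("b", default_group_count(n // 2)))
        if not 1 <= self.b <= self.L:
            raise ValueError(f"group count b={self.b} must be in 1..{self.L}")
        # flat over compositions of L into b positive parts
        self.log_size_prob = -(
            gammaln(self.L) - gammaln(self.b) - gammaln(self.L - self.b + 1)
        )

    def sequence(self, state):
        return np.repeat(state["group_values"], state["group_sizes"])

    def sample_state(self, rng):
        if self.b == 1:
            sizes = np.array([self.L])
        else:
            cuts = np.sort(rng.choice(self.L - 1, self.b - 1, replace=False)) + 1
            sizes = np.diff(np.concatenate([[0], cuts, [self.L]]))
        values = np.empty(self.b)
        values[0] = rng.uniform(0.0, self.upper)
        for j in range(1, self.b):
            values[j] = rng.exponential(values[j - 1])
        return {"group_sizes": sizes.astype(np.int64), "group_values": values}

    def log_density_components(self, state):
        sizes = state["group_sizes"]
        values = state["group_values"]
        if sizes.sum() != self.L or np.any(sizes < 1) or sizes.size != self.b:
            return {"theta": -np.inf, "hypers": -np.inf}
        th = _log_uniform01(values[:1], self.upper)
        if np.isfinite(th) and self.b > 1:
            if np.any(values[1:] <= 0.0):
                th = -np.inf
            else:
                th += float(
                    np.sum(-np.log(values[:-1]) - values[1:] / values[:-1])
                )
        return {"theta": th, "hypers": float(self.log_size_prob)}

    def hyper_columns(self, state):
        return {"bsp_groups": float(state["group_sizes"].size)}

    def special_moves(self, state, rng):
        # shift one interval across a random group boundary
        if self.b < 2:
            return []
        j = int(rng.integers(self.b - 1))  # boundary between group j and j+1
        sizes = state["group_sizes"].copy()
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1 and sizes[j] > 1:
            sizes[j] -= 1
            sizes[j + 1] += 1
        elif direction == -1 and sizes[j + 1] > 1:
            sizes[j] += 1
            sizes[j + 1] -= 1
        else:
            return []
        new = dict(state)
        new["group_sizes"] = sizes
        return [(new, 0.0)]


class RJ(Family):
    """Reversible-jump grouping in a saturated state space.

    State: {"values": L Uniform(0, upper) values, "equal": L-1 booleans}.
    ``equal[j]`` ties chain element ``j + 1`` to its predecessor; the tied
    element's entry in ``values`` is inert and keeps its Uniform base prior
    as a pseudo-prior, so the equality toggle is an ordinary fixed-dimension
    Metropolis move (unit Jacobian) and the marginal over active values is
    the reversible-jump prior.
    """

    positive_keys = ("values",)
    theta_keys = ("values",)

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.beta = float(spec.get("beta", 0.5))
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie strictly between 0 and 1")

    def sequence(self, state):
        values, equal = state["values"], state["equal"]
        s = values.copy()
        for j in range(1, self.L):
            if equal[j - 1]:
                s[j] = s[j - 1]
        return s

    def sample_state(self, rng):
        return {
            "values": rng.uniform(0.0, self.upper, self.L),
            "equal": rng.random(self.L - 1) < self.beta,
        }

    def log_density_components(self, state):
        th = _log_uniform01(state["values"], self.upper)
        eq = state["equal"]
        hy = float(
            np.sum(np.where(eq, math.log(self.beta), math.log1p(-self.beta)))
        )
        return {"theta": th, "hypers": hy}

    def indicator_log_prob(self, state) -> float:
        return self.log_density_components(state)["hypers"]

    def n_groups(self, state) -> int:
        return 1 + int(np.sum(~state["equal"]))

    def hyper_columns(self, state):
        return {"rj_groups": float(self.n_groups(state))}

    def special_moves(self, state, rng):
        moves = []
        if self.L > 1:
            j = int(rng.integers(self.L - 1))
            new = dict(state)
            eq = state["equal"].copy()
            eq[j] = not eq[j]
            new["equal"] = eq
            moves.append((new, 0.0))
            # refresh one inert value from its base prior (Gibbs when tied)
            tied = np.flatnonzero(state["equal"])
            if tied.size:
                k = int(rng.choice(tied)) + 1
                new2 = dict(state)
                vals = state["values"].copy()
                vals[k] = rng.uniform(0.0, self.upper)
                new2["values"] = vals
                moves.append((new2, 0.0))
        return moves


class _MRF(Family):
    """Shared machinery for GMRF/HSMRF of order 1 and 2.

    Theta is stored as ln theta: half-Cauchy local scales (HSMRF) put real
    prior mass on log-steps of thousands, far outside the exp-representable
    range, so both the generative draw and the density work on the log scale
    (the reported density remains the theta-space density, anchor included).
    """

    order = 1
    log_scale_keys = ("ln_s",)
    theta_keys = ("ln_s",)
    positive_keys: tuple[str, ...] = ()

    def __init__(self, spec, n):
        super().__init__(spec, n)
        if self.L < 2:
            raise ValueError("MRF priors need at least two intervals (n >= 3)")
        self.log_upper = math.log(self.upper)

    def sequence(self, state):
        with np.errstate(over="ignore"):
            return np.clip(np.exp(state["ln_s"]), _THETA_FLOOR, 8.9e307)

    def _increment_means(self, ln_s: np.ndarray) -> np.ndarray:
        """Conditional mean of ln s_j for j = 1..L-1 given predecessors."""
        if self.order == 1:
            return ln_s[:-1]
        means = np.empty(self.L - 1)
        means[0] = ln_s[0]
        means[1:] = 2.0 * ln_s[1:-1] - ln_s[:-2]
        return means

    def _sample_log_sequence(self, rng, scales: np.ndarray) -> np.ndarray:
        ln_s = np.empty(self.L)
        ln_s[0] = math.log(rng.uniform(0.0, self.upper))
        for j in range(1, self.L):
            if self.order == 1 or j == 1:
                mean = ln_s[j - 1]
            else:
                mean = 2.0 * ln_s[j - 1] - ln_s[j - 2]
            ln_s[j] = rng.normal(mean, scales[j - 1])
        return ln_s


class GMRF(_MRF):
    """Gaussian MRF with a single global scale ``xi`` (fixed by default to
    H / sqrt(n - 2): the prior 95% interval of the end-to-end log-size ratio
    spans one order of magnitude).  State: {"ln_s"} (+ {"xi"} when
    estimated)."""

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.estimate_scale = bool(spec.get("estimate_scale", False))
        self.xi0 = float(spec.get("xi", H / math.sqrt(max(n - 2, 1))))

    @property
    def positive_keys(self):
        return ("xi",) if self.estimate_scale else ()

    def _xi(self, state):
        return float(state["xi"]) if self.estimate_scale else self.xi0

    def sample_state(self, rng):
        state = {}
        xi = self.xi0
        if self.estimate_scale:
            xi = self.xi0 * abs(rng.standard_cauchy())
            state["xi"] = xi
        state["ln_s"] = self._sample_log_sequence(rng, np.full(self.L - 1, xi))
        return state

    def log_density_components(self, state):
        hy = 0.0
        if self.estimate_scale:
            hy = _log_halfcauchy(state["xi"], self.xi0)
        xi = self._xi(state)
        ln_s = state["ln_s"]
        if ln_s[0] >= self.log_upper or xi <= 0.0:
            return {"theta": -np.inf, "hypers": hy}
        z = (ln_s[1:] - self._increment_means(ln_s)) / xi
        th = (
            -math.log(self.upper)
            - 0.5 * float(z @ z)
            - (self.L - 1) * (math.log(xi) + 0.5 * LOG_2PI)
            - float(ln_s[1:].sum())  # d ln(theta) -> d theta Jacobian
        )
        return {"theta": th, "hypers": hy}

    def hyper_columns(self, state):
        return {"gmrf_xi": self._xi(state)} if self.estimate_scale else {}


class GMRF2(GMRF):
    order = 2


class HSMRF(_MRF):
    """Horseshoe MRF: step ``j`` has scale ``gamma * local_j`` with
    ``local_j ~ HalfCauchy(0, 1)`` (equivalently, per-step scales
    HalfCauchy(0, gamma); gamma = 0.021 by default).  State:
    {"ln_s", "local"} (+ {"gamma"} when estimated)."""

    def __init__(self, spec, n):
        super().__init__(spec, n)
        self.estimate_scale = bool(spec.get("estimate_scale", False))
        self.gamma0 = float(spec.get("gamma", 0.021))

    @property
    def positive_keys(self):
        return ("local", "gamma") if self.estimate_scale else ("local",)

    def _gamma(self, state):
        return float(state["gamma"]) if self.estimate_scale else self.gamma0

    def sample_state(self, rng):
        state = {}
        gamma = self.gamma0
        if self.estimate_scale:
            gamma = self.gamma0 * abs(rng.standard_cauchy())
            state["gamma"] = gamma
        local = np.abs(rng.standard_cauchy(self.L - 1))
        state["local"] = local
        state["ln_s"] = self._sample_log_sequence(rng, gamma * local)
        return state

    def log_density_components(self, state):
        local = state["local"]
        if local.min() <= 0.0:
            return {"theta": -np.inf, "hypers": -np.inf}
        hy = (self.L - 1) * math.log(2.0 / math.pi) - float(
            np.log1p(local * local).sum()
        )
        if self.estimate_scale:
            hy += _log_halfcauchy(state["gamma"], self.gamma0)
        gamma = self._gamma(state)
        ln_s = state["ln_s"]
        if not np.isfinite(hy) or ln_s[0] >= self.log_upper or gamma <= 0.0:
            return {"theta": -np.inf, "hypers": hy}
        scales = gamma * local
        z = (ln_s[1:] - self._increment_means(ln_s)) / scales
        th = (
            -math.log(self.upper)
            - 0.5 * float(z @ z)
            - float(np.log(scales).sum())
            - 0.5 * (self.L - 1) * LOG_2PI
            - float(ln_s[1:].sum())
        )
        return {"theta": th, "hypers": hy}

    def hyper_columns(self, state):
        cols = {
            f"hsmrf_local_{j + 1}": float(v) for j, v in enumerate(state["local"])
        }
        if self.estimate_scale:
            cols["hsmrf_gamma"] = self._gamma(state)
        return cols


class HSMRF2(HSMRF):
    order = 2


_FAMILY_CLASSES = {
    PriorFamily.IID_UNIFORM: IIDUniform,
    PriorFamily.UCLN: UCLN,
    PriorFamily.IGR: IGR,
    PriorFamily.BSP_GROUPED: BSPGrouped,
    PriorFamily.RJ: RJ,
    PriorFamily.GMRF1: GMRF,
    PriorFamily.GMRF2: GMRF2,
    PriorFamily.HSMRF1: HSMRF,
    PriorFamily.HSMRF2: HSMRF2,
}


def make_family(spec: PriorSpec, n: int) -> Family:
    return _FAMILY_CLASSES[PriorFamily(spec.family)](spec, n)


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> PriorState:
    """Exact ancestral draw from the family's generative description."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fam = make_family(spec, n)
    state = fam.sample_state(rng)
    return PriorState(theta=fam.theta_from_state(state), hypers=state)


def log_prior_density(spec: PriorSpec, state: PriorState, n: int | None = None) -> float:
    """Joint log-density of theta and the sampled hyperparameters."""
    if n is None:
        n = len(state.theta) + 1
    fam = make_family(spec, n)
    return fam.log_density(state.hypers)
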