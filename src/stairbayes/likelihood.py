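"""Composite multinomial likelihood of an SFS under piecewise-constant sizes.

The model assigns one scaled population size ``theta_k = 4 N_k mu`` to the
coalescent interval during which ``k`` ancestral lineages remain
(``k = 2..n``; ``k = n`` is the most recent interval).  With the expected
interval durations, the probability that a random site carries the derived
allele in ``i`` of the ``n`` samples is

    p_i = sum_{k=2}^{n} Pr(k, i | n) * theta_k / (k - 1),

where ``Pr(k, i | n)`` is the probability that one of the ``k`` ancestral
lineages has exactly ``i`` sampled descendants (a ratio of binomial
coefficients due to Fu 1995).  Sites are treated as independent, so the
likelihood of the observed class counts is multinomial.  The monomorphic
probability ``p0`` is either the complement ``1 - sum p_i`` or the no-mutation
probability of the expected total tree length, ``exp(-sum theta_k/(k-1))``
(the polymorphic classes are then rescaled to ``1 - p0``).

Because at most one mutation per site is assumed, ``sum p_i >= 1`` marks a
parameter vector as invalid; the log-likelihood is then ``-inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .sfs_io import MONOMORPHIC, SINGLETONS, SiteFrequencySpectrum

__all__ = [
    "P0Method",
    "Conditioning",
    "SiteClassProbabilities",
    "LikelihoodConfig",
    "lineage_descendant_prob",
    "descendant_prob_table",
    "polymorphic_probs",
    "monomorphic_prob",
    "fold_probs",
    "site_class_probabilities",
    "log_composite_likelihood",
    "CompositeLikelihood",
]


class P0Method(str, Enum):
    COMPLEMENT = "complement"
    TREE_LENGTH = "tree_length"


class Conditioning(str, Enum):
    NONE = "none"
    NO_MONOMORPHIC = "no_monomorphic"
    NO_MONO_NO_SINGLETONS = "no_mono_no_singletons"


@dataclass(frozen=True)
class SiteClassProbabilities:
    """Class probabilities for the modeled frequency classes.

    ``p`` covers the polymorphic classes 1..n-1 (or folded 1..n//2);
    ``p0`` is present when monomorphic sites are modeled.  ``valid`` is
    False exactly when ``sum p_i >= 1`` under the complement method.
    """

    p: np.ndarray
    p0: float | None
    valid: bool


@dataclass(frozen=True)
class LikelihoodConfig:
    p0_method: P0Method = P0Method.COMPLEMENT
    conditioning: Conditioning = Conditioning.NONE

    @staticmethod
    def for_sfs(sfs: SiteFrequencySpectrum, p0_method=P0Method.COMPLEMENT):
        """Choose the conditioning implied by the spectrum's masked classes."""
        if SINGLETONS in sfs.masked_classes:
            cond = Conditioning.NO_MONO_NO_SINGLETONS
        elif MONOMORPHIC in sfs.masked_classes:
            cond = Conditioning.NO_MONOMORPHIC
        else:
            cond = Conditioning.NONE
        return LikelihoodConfig(p0_method=P0Method(p0_method), conditioning=cond)


def lineage_descendant_prob(k: int, i: int, n: int) -> float:
    """Probability that a lineage has ``i`` sampled descendants while ``k``
    ancestral lineages of the ``n`` samples remain: C(n-i-1, k-2) / C(n-1, k-1)
    for ``n-i+1 >= k >= 2`` and ``n >= i >= 1``, else 0.  Log-space for large n.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (2 <= k <= n - i + 1 and 1 <= i <= n):
        return 0.0
    log_num = gammaln(n - i) - gammaln(k - 1) - gammaln(n - i - k + 2)
    log_den = gammaln(n) - gammaln(k) - gammaln(n - k + 1)
    return float(np.exp(log_num - log_den))


@lru_cache(maxsize=32)
def descendant_prob_table(n: int) -> np.ndarray:
    """Weighted table ``W[i-1, k-2] = Pr(k, i | n) / (k - 1)``.

    ``p = W @ theta`` gives the polymorphic class probabilities; the table
    depends only on ``n`` and is cached (the hot path: repeated likelihood
    evaluations are O(n^2) table-vector products).
    """
    ii = np.arange(1, n)[:, None]  # derived count i = 1..n-1
    kk = np.arange(2, n + 1)[None, :]  # lineage count k = 2..n
    with np.errstate(invalid="ignore"):
        log_num = gammaln(n - ii) - gammaln(kk - 1) - gammaln(n - ii - kk + 2)
    log_den = gammaln(n) - gammaln(kk) - gammaln(n - kk + 1)
    table = np.exp(log_num - log_den)
    table[(kk > n - ii + 1)] = 0.0
    table = np.where(np.isfinite(table), table, 0.0)
    table /= kk - 1
    table.setflags(write=False)
    return table


def _theta_array(theta, n: int | None = None) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if th.ndim != 1 or th.size < 1:
        raise ValueError("theta must be a 1-d vector (theta_2..theta_n)")
    if n is not None and th.size != n - 1:
        raise ValueError(f"theta length {th.size} does not match n={n}")
    if np.any(th <= 0) or not np.all(np.isfinite(th)):
        raise ValueError("every theta_k must be positive and finite")
    return th


def polymorphic_probs(theta) -> SiteClassProbabilities:
    """Unfolded class probabilities ``p_1..p_{n-1}`` from ``theta_2..theta_n``."""
    th = _theta_array(theta)
    n = th.size + 1
    p = descendant_prob_table(n) @ th
    return SiteClassProbabilities(p=p, p0=None, valid=bool(p.sum() < 1.0))


def monomorphic_prob(theta, method: P0Method | str = P0Method.COMPLEMENT) -> float:
    """Probability of an invariant site, by either derivation."""
    th = _theta_array(theta)
    n = th.size + 1
    method = P0Method(method)
    if method is P0Method.TREE_LENGTH:
        weights = 1.0 / (np.arange(2, n + 1) - 1.0)
        return float(np.exp(-np.dot(th, weights)))
    probs = polymorphic_probs(th)
    if not probs.valid:
        raise ValueError("sum of polymorphic probabilities >= 1: p0 undefined "
                         "under the complement method")
    return float(1.0 - probs.p.sum())


def fold_probs(p: np.ndarray, n: int) -> np.ndarray:
    """Fold unfolded class probabilities: ``p_i^F = p_i + p_{n-i}`` for
    ``i < n/2``; the middle class (even ``n``) is unchanged."""
    p = np.asarray(p, dtype=float)
    if p.size != n - 1:
        raise ValueError(f"expected {n - 1} unfolded probabilities, got {p.size}")
    half = n // 2
    folded = [p[i - 1] + p[n - i - 1] for i in range(1, half + (n % 2))]
    if n % 2 == 0:
        folded.append(p[half - 1])
    return np.asarray(folded)


def site_class_probabilities(
    theta,
    n: int,
    config: LikelihoodConfig = LikelihoodConfig(),
    folded: bool = False,
) -> SiteClassProbabilities:
    """Modeled class probabilities after p0 handling, folding and conditioning.

    Returns probabilities over exactly the modeled classes, in count order:
    conditioning NONE prepends ``p0``; NO_MONOMORPHIC covers the polymorphic
    classes; NO_MONO_NO_SINGLETONS drops classes 1 and n-1 (folded: the merged
    class 1).  The returned vector sums to 1 when valid.
    """
    if config.conditioning is Conditioning.NO_MONO_NO_SINGLETONS and n < 4:
        raise ValueError(
            "conditioning on no singletons needs n >= 4: at n < 4 every "
            "polymorphic class is a singleton class"
        )
    th = _theta_array(theta, n)
    p = descendant_prob_table(n) @ th
    s = p.sum()
    if config.p0_method is P0Method.COMPLEMENT:
        if s >= 1.0:
            return SiteClassProbabilities(p=p, p0=None, valid=False)
        p0 = 1.0 - s
    else:
        weights = 1.0 / (np.arange(2, n + 1) - 1.0)
        p0 = float(np.exp(-np.dot(th, weights)))
        p = p * ((1.0 - p0) / s)
    if folded:
        p = fold_probs(p, n)
    cond = config.conditioning
    if cond is Conditioning.NONE:
        out = np.concatenate([[p0], p])
        return SiteClassProbabilities(p=out, p0=float(p0), valid=True)
    if cond is Conditioning.NO_MONOMORPHIC:
        out = p / (1.0 - p0)
        return SiteClassProbabilities(p=out, p0=None, valid=True)
    # no monomorphic, no singletons
    if folded:
        denom = 1.0 - p0 - p[0]
        out = p[1:] / denom
    else:
        denom = 1.0 - p0 - p[0] - p[-1]
        out = p[1:-1] / denom
    if denom <= 0.0:
        return SiteClassProbabilities(p=p, p0=None, valid=False)
    return SiteClassProbabilities(p=out, p0=None, valid=True)


def _modeled_counts(sfs: SiteFrequencySpectrum, cond: Conditioning) -> np.ndarray:
    counts = np.asarray(sfs.counts, dtype=float)
    if cond is Conditioning.NONE:
        if sfs.monomorphic_count is None:
            raise ValueError(
                "conditioning 'none' needs a known monomorphic count; mask "
                "the monomorphic class or supply the total length"
            )
        return np.concatenate([[sfs.monomorphic_count], counts])
    if cond is Conditioning.NO_MONOMORPHIC:
        return counts
    # singletons excluded: observed singleton counts must have been masked
    if sfs.folded:
        excluded, kept = counts[:1], counts[1:]
    else:
        excluded, kept = counts[[0, -1]], counts[1:-1]
    if np.any(excluded > 0):
        raise ValueError(
            "conditioning excludes the singleton classes but the spectrum has "
            "nonzero singleton counts; mask them first (mask_spectrum)"
        )
    return kept


def log_composite_likelihood(
    sfs: SiteFrequencySpectrum,
    theta,
    config: LikelihoodConfig = LikelihoodConfig(),
) -> float:
    """Log multinomial probability of the observed class counts.

    ``ln l! + sum xi_i ln p_i - sum ln xi_i!`` over the modeled classes, with
    factorials via log-gamma.  Returns 0 for an empty spectrum (no sites) and
    ``-inf`` for an invalid ``theta`` (``sum p_i >= 1`` under the complement
    p0 method).
    """
    counts = _modeled_counts(sfs, config.conditioning)
    total = counts.sum()
    if total == 0:
        return 0.0
    probs = site_class_probabilities(theta, sfs.n, config, folded=sfs.folded)
    if not probs.valid:
        return -np.inf
    p = probs.p
    log_coef = gammaln(total + 1.0) - gammaln(counts + 1.0).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(p), 0.0)
    if not np.all(np.isfinite(terms)):
        return -np.inf
    return float(log_coef + terms.sum())


class CompositeLikelihood:
    """Precomputed workspace for repeated likelihood evaluations on one SFS.

    Caches the descendant-probability table, the modeled count vector and the
    constant multinomial coefficient so that each evaluation is a table-vector
    product plus a dot product — independent of the number of SNPs.
    """

    def __init__(self, sfs: SiteFrequencySpectrum,
                 config: LikelihoodConfig = LikelihoodConfig()):
        self.sfs = sfs
        self.config = config
        self.n = sfs.n
        self.counts = _modeled_counts(sfs, config.conditioning)
        self.total = self.counts.sum()
        self.table = descendant_prob_table(self.n)
        self._tl_weights = 1.0 / (np.arange(2, self.n + 1) - 1.0)
        self.log_coef = float(
            gammaln(self.total + 1.0) - gammaln(self.counts + 1.0).sum()
        )
        # class probabilities are strictly positive for any valid theta, so
        # the dot product below never sees log(0) with a nonzero count
        if config.conditioning is Conditioning.NONE:
            self._counts0 = float(self.counts[0])
            self._counts_poly = self.counts[1:]
        else:
            self._counts0 = 0.0
            self._counts_poly = self.counts

    def class_probabilities(self, theta) -> SiteClassProbabilities:
        return site_class_probabilities(
            theta, self.n, self.config, folded=self.sfs.folded
        )

    def __call__(self, theta: np.ndarray) -> float:
        if self.total == 0:
            return 0.0
        # extreme proposals can overflow to inf here; they fail the sum
        # constraint below, so the overflow is just a rejected state
        with np.errstate(over="ignore"):
            p = self.table @ theta
            s = p.sum()
        if not np.isfinite(s):
            return -np.inf
        cfg = self.config
        if cfg.p0_method is P0Method.COMPLEMENT:
            if s >= 1.0:
                return -np.inf
            p0 = 1.0 - s
        else:
            p0 = np.exp(-np.dot(theta, self._tl_weights))
            p = p * ((1.0 - p0) / s)
        if p0 <= 0.0 or p.min() <= 0.0:
            return -np.inf
        if self.sfs.folded:
            p = fold_probs(p, self.n)
        cond = cfg.conditioning
        if cond is Conditioning.NONE:
            ll = self._counts0 * math.log(p0) + float(self._counts_poly @ np.log(p))
        elif cond is Conditioning.NO_MONOMORPHIC:
            ll = float(self._counts_poly @ np.log(p)) - self.total * math.log(1.0 - p0)
        else:
            if self.sfs.folded:
                denom = 1.0 - p0 - p[0]
                kept = p[1:]
            else:
                denom = 1.0 - p0 - p[0] - p[-1]
                kept = p[1:-1]
            if denom <= 0.0:
                return -np.inf
            ll = float(self._counts_poly @ np.log(kept)) - self.total * math.log(denom)
        return self.log_coef + ll
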