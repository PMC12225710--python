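"""Leave-one-out cross-validation from stored posterior class probabilities.

The log posterior cross-validation (LPCV) score sums, over sites, the log of
the harmonic mean over MCMC samples of the site's class probability:

    LPCV = sum_i ln [ (1/K) sum_k 1 / p(X_i | theta_k) ]^{-1}.

Sites within a frequency class are exchangeable, so the per-site sum
collapses to a count-weighted sum over the (at most n) modeled classes —
the whole computation is a cheap post-hoc pass over the stored trace.
Harmonic means are evaluated as ``-logsumexp(-ln p) + ln K`` for stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mcmc import PosteriorTrace
from .priors import N_SAMPLED_HYPERS, PriorFamily
from .sfs_io import SiteFrequencySpectrum

__all__ = ["LPCVResult", "lpcv", "select_best"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LPCVResult:
    """LPCV score (log scale) with per-class contributions.

    ``per_class`` maps p-column name to its count-weighted contribution;
    contributions sum exactly to ``score``.  ``per_replicate`` holds the
    stability diagnostic computed from each replicate run alone.
    """

    model: str
    score: float
    per_class: dict[str, float]
    per_replicate: tuple[float, ...]
    K: int
    conditioning: str
    family: PriorFamily | None = None

    def __post_init__(self) -> None:
        total = sum(self.per_class.values())
        if np.isfinite(self.score) and not np.isclose(total, self.score):
            raise ValueError("per-class contributions must sum to the score")


def _lpcv_from_probs(p: np.ndarray, counts: np.ndarray, columns) -> tuple[float, dict]:
    K = p.shape[0]
    per_class: dict[str, float] = {}
    score = 0.0
    for j, name in enumerate(columns):
        if counts[j] == 0:
            per_class[name] = 0.0
            continue
        pj = p[:, j]
        if np.any(pj <= 0.0):
            warnings.warn(
                f"stored probability for class {name} is zero with observed "
                "count > 0; LPCV is -inf",
                stacklevel=3,
            )
            per_class[name] = -np.inf
            score = -np.inf
            continue
        # ln harmonic mean = -(logsumexp(-ln p) - ln K)
        log_hm = -(logsumexp(-np.log(pj)) - np.log(K))
        contrib = float(counts[j] * log_hm)
        per_class[name] = contrib
        score += contrib
    return score, per_class


def lpcv(
    trace: PosteriorTrace,
    sfs: SiteFrequencySpectrum | None = None,
    model: str | None = None,
) -> LPCVResult:
    """LPCV score of one fitted model from its stored p vectors.

    The stored probabilities already follow the conditioning used during
    sampling, and the trace carries the matching modeled counts; ``sfs`` is
    only accepted for a consistency check on the sample size.
    """
    if sfs is not None and sfs.n != trace.n:
        raise ValueError(f"sfs has n={sfs.n} but trace has n={trace.n}")
    p = trace.p_samples()
    counts = trace.modeled_counts
    score, per_class = _lpcv_from_probs(p, counts, trace.p_columns)
    per_rep = tuple(
        _lpcv_from_probs(rep, counts, trace.p_columns)[0]
        for rep in trace.p_samples_per_replicate()
    )
    family = trace.prior_spec.family
    return LPCVResult(
        model=model or family.value,
        score=score,
        per_class=per_class,
        per_replicate=per_rep,
        K=p.shape[0],
        conditioning=trace.like_config.conditioning.value,
        family=family,
    )


def lpcv_from_frame(
    frame,
    sfs: SiteFrequencySpectrum,
    conditioning="none",
    model: str = "model",
) -> LPCVResult:
    """LPCV from a trace table (e.g. a written trace TSV re-read).

    Uses the stored ``p_<class>`` columns together with the spectrum's
    counts under the stated conditioning; the conditioning must match the
    one used during sampling (checked against the number of p columns).
    """
    from .likelihood import Conditioning, _modeled_counts

    conditioning = Conditioning(conditioning)
    p_cols = [c for c in frame.columns if c.startswith("p_")]
    if not p_cols:
        raise ValueError("trace table has no stored p_<class> columns")
    counts = _modeled_counts(sfs, conditioning)
    if len(counts) != len(p_cols):
        raise ValueError(
            f"{len(p_cols)} stored probability columns do not match "
            f"{len(counts)} modeled classes under conditioning "
            f"{conditioning.value!r}"
        )
    p = frame[p_cols].to_numpy()
    score, per_class = _lpcv_from_probs(p, counts, p_cols)
    return LPCVResult(
        model=model,
        score=score,
        per_class=per_class,
        per_replicate=(score,),
        K=p.shape[0],
        conditioning=conditioning.value,
    )


def _complexity(result: LPCVResult) -> int:
    if result.family is not None:
        return N_SAMPLED_HYPERS[result.family]
    return 0


def select_best(results) -> str:
    """Model id with the highest LPCV; ties go to the simpler family."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("model selection needs at least two LPCV results")
    conditionings = {r.conditioning for r in results}
    if len(conditionings) > 1:
        raise ValueError(
            f"LPCV scores under different conditionings are not comparable: "
            f"{sorted(conditionings)}"
        )
    best = max(results, key=lambda r: r.score)
    tied = [r for r in results if r.score == best.score]
    if len(tied) > 1:
        tied.sort(key=_complexity)
        logger.warning(
            "LPCV tie between %s; choosing %s (fewer sampled hyperparameters)",
            [r.model for r in tied],
            tied[0].model,
        )
        best = tied[0]
    return best.model


def comparison_table(results) -> "object":
    """Ranked model-comparison report as a DataFrame (model, LPCV, K,
    per-replicate scores)."""
    import pandas as pd

    rows = [
        {
            "model": r.model,
            "lpcv": r.score,
            "K": r.K,
            **{f"lpcv_rep{j + 1}": v for j, v in enumerate(r.per_replicate)},
        }
        for r in sorted(results, key=lambda r: -r.score)
    ]
    return pd.DataFrame(rows)
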