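"""Bayesian percent-spliced-in (PSI) estimation and pairwise Bayes factors.

The model is a deliberately simple conjugate stand-in for full MCMC isoform
inference: inclusion/exclusion read counts for a two-isoform event are treated
as binomial draws with a Beta prior on PSI.  The posterior is then
``Beta(inclusion + alpha, exclusion + beta)`` and the evidence for a change in
PSI between two samples is the closed-form Beta-binomial marginal likelihood
ratio of the two-PSI model against the shared-PSI model.

Downstream analyses consume only the posterior mean, the 95% credible
interval, the sign of delta-PSI and the indicator BF > threshold, so the
conjugate model is exact for everything the pipeline needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .events import PairwiseComparison, PsiEstimate

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 20
BF_CAP = 1e12


class InsufficientReadsError(ValueError):
    """Raised when an event has fewer reads than ``min_reads``."""


def estimate_psi(
    inclusion: int,
    exclusion: int,
    *,
    event_id: str = "",
    sample_id: str = "",
    alpha: float = 1.0,
    beta: float = 1.0,
    min_reads: int = DEFAULT_MIN_READS,
) -> PsiEstimate:
    """Posterior PSI summary from inclusion/exclusion read counts.

    Raises :class:`InsufficientReadsError` (with a logged reason) when
    ``inclusion + exclusion < min_reads``; events are skipped explicitly,
    never silently dropped.
    """
    if inclusion < 0 or exclusion < 0:
        raise ValueError("read counts must be non-negative")
    total = inclusion + exclusion
    if total < min_reads:
        msg = (
            f"event {event_id or '<anon>'} sample {sample_id or '<anon>'}: "
            f"{total} reads < min_reads={min_reads}; skipped"
        )
        logger.info(msg)
        raise InsufficientReadsError(msg)
    a = inclusion + alpha
    b = exclusion + beta
    mean = a / (a + b)
    lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
    return PsiEstimate(
        event_id=event_id,
        sample_id=sample_id,
        inclusion_count=inclusion,
        exclusion_count=exclusion,
        psi_mean=float(mean),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def _log_evidence(inc: np.ndarray, exc: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Log Beta-binomial marginal likelihood (binomial coefficients dropped;
    they are identical in the shared- and independent-PSI models and cancel
    in the ratio)."""
    return betaln(inc + alpha, exc + beta) - betaln(alpha, beta)


def log_bayes_factor_counts(
    inc_a, exc_a, inc_b, exc_b, *, alpha: float = 1.0, beta: float = 1.0
) -> np.ndarray:
    """Vectorised natural-log Bayes factor for PSI_a != PSI_b vs shared PSI."""
    inc_a = np.asarray(inc_a, dtype=float)
    exc_a = np.asarray(exc_a, dtype=float)
    inc_b = np.asarray(inc_b, dtype=float)
    exc_b = np.asarray(exc_b, dtype=float)
    m1 = _log_evidence(inc_a, exc_a, alpha, beta) + _log_evidence(inc_b, exc_b, alpha, beta)
    m0 = _log_evidence(inc_a + inc_b, exc_a + exc_b, alpha, beta)
    return m1 - m0


def bayes_factor(
    a: PsiEstimate,
    b: PsiEstimate,
    *,
    alpha: float = 1.0,
    beta: float = 1.0,
    n_mc: int = 0,
    seed: int | None = None,
) -> PairwiseComparison:
    """Evidence that PSI differs between two samples of the same event.

    The Bayes factor compares the model in which each sample has its own PSI
    (each with a ``Beta(alpha, beta)`` prior) against the null in which both
    share one PSI.  The computation is closed form; ``n_mc``/``seed`` are
    accepted for interface compatibility with non-conjugate extensions and
    ignored here.  BFs are capped at ``1e12`` and flagged.
    """
    if a.event_id != b.event_id:
        raise ValueError(f"event mismatch: {a.event_id!r} vs {b.event_id!r}")
    log_bf = float(
        log_bayes_factor_counts(
            a.inclusion_count, a.exclusion_count, b.inclusion_count, b.exclusion_count,
            alpha=alpha, beta=beta,
        )
    )
    if log_bf > np.log(BF_CAP):
        bf, capped = BF_CAP, True
    else:
        bf, capped = float(np.exp(log_bf)), False
    return PairwiseComparison(
        event_id=a.event_id,
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        delta_psi=b.psi_mean - a.psi_mean,
        bayes_factor=bf,
        bf_capped=capped,
    )


@dataclass
class SkippedEvent:
    event_id: str
    sample_id: str
    reason: str


def psi_table(
    counts: pd.DataFrame,
    *,
    alpha: float = 1.0,
    beta: float = 1.0,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[pd.DataFrame, list[SkippedEvent]]:
    """Estimate PSI for a tidy counts table.

    ``counts`` needs columns ``event_id, sample_id, inclusion, exclusion``.
    Returns the PSI table and the list of skipped (low-coverage) rows.
    """
    rows, skipped = [], []
    for rec in counts.itertuples(index=False):
        try:
            est = estimate_psi(
                int(rec.inclusion), int(rec.exclusion),
                event_id=str(rec.event_id), sample_id=str(rec.sample_id),
                alpha=alpha, beta=beta, min_reads=min_reads,
            )
        except InsufficientReadsError as exc:
            skipped.append(SkippedEvent(str(rec.event_id), str(rec.sample_id), str(exc)))
            continue
        rows.append(
            (est.event_id, est.sample_id, est.inclusion_count, est.exclusion_count,
             est.psi_mean, est.ci_low, est.ci_high)
        )
    out = pd.DataFrame(
        rows,
        columns=["event_id", "sample_id", "inclusion", "exclusion",
                 "psi_mean", "ci_low", "ci_high"],
    )
    return out, skipped


def pairwise_comparisons(
    psi: pd.DataFrame,
    *,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> pd.DataFrame:
    """All unordered sample-pair comparisons per event.

    Output columns: event_id, sample_a, sample_b, delta_psi, bayes_factor.
    ``delta_psi`` is oriented b minus a with samples in table order.
    """
    frames = []
    for event_id, grp in psi.groupby("event_id", sort=False):
        inc = grp["inclusion"].to_numpy(dtype=float)
        exc = grp["exclusion"].to_numpy(dtype=float)
        mean = grp["psi_mean"].to_numpy(dtype=float)
        sids = grp["sample_id"].to_numpy()
        i, j = np.triu_indices(len(grp), k=1)
        log_bf = log_bayes_factor_counts(inc[i], exc[i], inc[j], exc[j],
                                         alpha=alpha, beta=beta)
        bf = np.exp(np.minimum(log_bf, np.log(BF_CAP)))
        frames.append(pd.DataFrame({
            "event_id": event_id, "sample_a": sids[i], "sample_b": sids[j],
            "delta_psi": mean[j] - mean[i], "bayes_factor": bf,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["event_id", "sample_a", "sample_b", "delta_psi", "bayes_factor"])
    return pd.concat(frames, ignore_index=True)
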