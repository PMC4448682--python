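"""Time-course monotonicity statistics for splicing (or expression) changes.

For one event measured across time-ordered samples, every pair of samples
from *different* time points contributes a pairwise comparison (delta-PSI and
a Bayes factor).  The statistic

    delta = #{significant increases over time} - #{significant decreases}

counts comparisons with BF above a threshold, oriented later-minus-earlier.
Its significance is assessed against a permutation null: the sample-to-time
assignment is permuted jointly (replicate structure dissolved), delta is
recomputed per permutation, and the monotonicity Z-score is

    MZ = (delta - mu) / sigma

with mu, sigma the null mean and standard deviation.  Large |MZ| indicates a
consistent monotone trend in PSI over the time course.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .events import MonotonicityResult

DEFAULT_BF_THRESHOLD = 5.0
#: monotonicity-Z calling thresholds by event class (strict >)
DEFAULT_MZ_THRESHOLDS = {"SE": 1.8, "TandemUTR": 1.6, "ALE": 1.5}


class MissingPairsError(ValueError):
    def __init__(self, pairs: list[tuple[str, str]]):
        self.pairs = pairs
        super().__init__(f"missing sample-pair comparisons: {sorted(pairs)}")


def _pair_matrix(
    comparisons: pd.DataFrame,
    samples: list[str],
    bf_threshold: float,
) -> np.ndarray:
    """Antisymmetric matrix M with M[i, j] = +-1 if the (i, j) comparison is
    significant with delta-PSI oriented j-minus-i, else 0."""
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    m = np.zeros((n, n))
    for rec in comparisons.itertuples(index=False):
        a, b = idx[rec.sample_a], idx[rec.sample_b]
        if rec.bayes_factor > bf_threshold:
            s = np.sign(rec.delta_psi)  # delta_psi = b minus a; 0 counts in neither tally
            m[a, b] = s
            m[b, a] = -s
    return m


def _delta_from_matrix(m: np.ndarray, times: np.ndarray) -> int:
    sgn = np.sign(times[None, :] - times[:, None])
    return int(round(0.5 * float(np.sum(m * sgn))))


def _check_pairs(
    comparisons: pd.DataFrame,
    time_order: Mapping[str, int],
    *,
    cross_time_only: bool,
) -> None:
    have = {frozenset((r.sample_a, r.sample_b)) for r in comparisons.itertuples(index=False)}
    samples = sorted(time_order)
    missing = []
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if cross_time_only and time_order[a] == time_order[b]:
                continue
            if frozenset((a, b)) not in have:
                missing.append((a, b))
    if missing:
        raise MissingPairsError(missing)


def delta_statistic(
    comparisons: pd.DataFrame,
    time_order: Mapping[str, int],
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
) -> int:
    """Signed count of significant PSI changes oriented later-minus-earlier.

    ``comparisons`` needs columns ``sample_a, sample_b, delta_psi,
    bayes_factor`` covering every pair of samples from different time points
    (missing pairs raise :class:`MissingPairsError` listing them).
    Comparisons with BF > threshold and delta-PSI exactly zero count in
    neither tally.
    """
    _check_pairs(comparisons, time_order, cross_time_only=True)
    samples = sorted(time_order)
    m = _pair_matrix(comparisons, samples, bf_threshold)
    times = np.array([time_order[s] for s in samples], dtype=float)
    return _delta_from_matrix(m, times)


def _null_deltas_sampled(
    m: np.ndarray,
    times: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    if groups is None:
        perms = np.array([rng.permutation(times) for _ in range(n_perm)])
    else:
        perms = np.tile(times, (n_perm, 1))
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            for p in range(n_perm):
                perms[p, idx] = perms[p, idx][rng.permutation(len(idx))]
    sgn = np.sign(perms[:, None, :] - perms[:, :, None])
    return 0.5 * np.einsum("ij,pij->p", m, sgn)


def _null_deltas_exhaustive(m: np.ndarray, times: np.ndarray) -> np.ndarray:
    from sympy.utilities.iterables import multiset_permutations

    out = []
    for perm in multiset_permutations(list(times)):
        out.append(_delta_from_matrix(m, np.array(perm, dtype=float)))
    return np.array(out, dtype=float)


def monotonicity_z(
    event_id: str,
    comparisons: pd.DataFrame,
    time_order: Mapping[str, int],
    *,
    n_perm: int = 100,
    seed: int | None = 0,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    method: str = "sample",
    replicate_of: Mapping[str, object] | None = None,
) -> MonotonicityResult:
    """Permutation monotonicity Z-score for one event.

    ``comparisons`` must cover *all* unordered sample pairs (same-time pairs
    included): a permutation can assign any two samples to different time
    points, so every pairwise comparison can enter the null.  The observed
    delta uses only cross-time pairs, as always.

    The default null permutes the sample-to-time assignment jointly over all
    samples (replicate structure dissolved — the maximal-entropy exchangeable
    null).  Passing ``replicate_of`` (sample -> replicate line) restricts
    permutations to within each replicate line instead.

    ``method="exhaustive"`` enumerates every distinct assignment of the time
    labels instead of sampling; feasible for small sample counts and used as
    the exact reference.  With ``method="sample"`` the null is ``n_perm``
    uniform draws (the study design used 100).

    A null with zero variance (no comparison significant under any
    labelling, or a constant delta) yields MZ = 0 flagged ``degenerate_null``.
    """
    if len(set(time_order.values())) < 2:
        raise ValueError("need at least two distinct time points")
    if len(time_order) < 2:
        raise ValueError("need at least two samples")
    _check_pairs(comparisons, time_order, cross_time_only=False)
    samples = sorted(time_order)
    m = _pair_matrix(comparisons, samples, bf_threshold)
    times = np.array([time_order[s] for s in samples], dtype=float)
    observed = _delta_from_matrix(m, times)

    if method == "exhaustive":
        if replicate_of is not None:
            raise ValueError("within-replicate permutation is sampling-only")
        deltas = _null_deltas_exhaustive(m, times)
        mu = float(deltas.mean())
        sd = float(deltas.std(ddof=0))
        n_used = len(deltas)
    elif method == "sample":
        rng = np.random.default_rng(seed)
        groups = None
        if replicate_of is not None:
            labels = {replicate_of[s] for s in samples}
            lut = {lab: i for i, lab in enumerate(sorted(labels, key=str))}
            groups = np.array([lut[replicate_of[s]] for s in samples])
        deltas = _null_deltas_sampled(m, times, n_perm, rng, groups)
        mu = float(deltas.mean())
        sd = float(deltas.std(ddof=1)) if n_perm > 1 else 0.0
        n_used = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")

    if sd == 0.0:
        return MonotonicityResult(event_id, observed, mu, 0.0, 0.0, n_used, "degenerate_null")
    return MonotonicityResult(event_id, observed, mu, sd, (observed - mu) / sd, n_used)


def monotonicity_table(
    comparisons: pd.DataFrame,
    time_order: Mapping[str, int],
    *,
    n_perm: int = 100,
    seed: int = 0,
    bf_threshold: float = DEFAULT_BF_THRESHOLD,
    method: str = "sample",
) -> pd.DataFrame:
    """Monotonicity results for every event in a pooled comparison table.

    Each event gets an independent, seed-derived permutation stream so the
    table is reproducible and order-independent.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (event_id, grp), child in zip(
        comparisons.groupby("event_id", sort=True), ss.spawn(comparisons["event_id"].nunique())
    ):
        res = monotonicity_z(
            str(event_id), grp, time_order,
            n_perm=n_perm, seed=child, bf_threshold=bf_threshold, method=method,
        )
        rows.append((res.event_id, res.delta, res.null_mean, res.null_sd,
                     res.mz, res.n_perm, res.flag))
    return pd.DataFrame(
        rows, columns=["event_id", "delta", "mu", "sigma", "mz", "n_perm", "flag"]
    )


def call_monotonic(
    results: pd.DataFrame,
    mz_threshold: float | Mapping[str, float] | None = None,
    event_classes: Mapping[str, str] | None = None,
    default_threshold: float = 1.8,
) -> pd.DataFrame:
    """Events with |MZ| strictly above their class threshold.

    ``mz_threshold`` may be one number or a per-class mapping (defaults:
    SE 1.8, TandemUTR 1.6, ALE 1.5).  Comparison is strict, so MZ equal to
    the threshold is not called.  Returns the called subset with a
    ``direction`` column ("up"/"down").
    """
    if mz_threshold is None:
        mz_threshold = DEFAULT_MZ_THRESHOLDS
    df = results.copy()
    if isinstance(mz_threshold, Mapping):
        classes = (
            df["event_id"].map(event_classes).fillna("SE")
            if event_classes is not None
            else pd.Series("SE", index=df.index)
        )
        thr = classes.map(lambda c: mz_threshold.get(c, default_threshold)).astype(float)
    else:
        thr = pd.Series(float(mz_threshold), index=df.index)
    called = df[df["mz"].abs() > thr.values].copy()
    called["direction"] = np.where(called["mz"] > 0, "up", "down")
    return called
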