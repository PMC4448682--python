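"""Gene expression estimation and cross-sample scaling.

Expression per gene is reads per kilobase of constitutive sequence per
million mapped reads (RPKM-style); cross-sample comparability uses
median-ratio size factors (the geometric-mean reference scaling familiar
from count-based differential expression), a deliberate simplification of
trimmed-mean normalization.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def counts_matrix(gene_counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy (gene_id, sample_id, count) rows to a genes x samples matrix."""
    return gene_counts.pivot(index="gene_id", columns="sample_id", values="count")


def rpkm(counts: pd.DataFrame, gene_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Reads per kb of gene model per million mapped reads, per sample."""
    lengths_kb = pd.Series({g: gene_lengths[g] / 1000.0 for g in counts.index})
    millions = counts.sum(axis=0) / 1e6
    return counts.div(lengths_kb, axis=0).div(millions, axis=1)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (genes with any zero count
    are excluded from the reference)."""
    log_counts = np.log(counts.replace(0, np.nan))
    ref = log_counts.mean(axis=1)
    ratios = log_counts.sub(ref, axis=0)
    return np.exp(ratios.median(axis=0, skipna=True))


def normalize_median_ratio(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(median_ratio_size_factors(counts), axis=1)


def endpoint_log_change(
    counts: pd.DataFrame,
    time_order: Mapping[str, int],
    base: str = "e",
) -> pd.Series:
    """Per-gene log expression change, endpoint mean over control mean.

    Counts are median-ratio scaled first; samples at the maximal time-point
    ordinal are the endpoint, ordinal 0 the control.  ``base`` "e" gives
    natural log (for the potency model), "2" gives log2 (for grouped
    expression-change displays).
    """
    norm = normalize_median_ratio(counts)
    t_max = max(time_order.values())
    end_cols = [s for s in norm.columns if time_order[s] == t_max]
    ctl_cols = [s for s in norm.columns if time_order[s] == 0]
    if not end_cols or not ctl_cols:
        raise ValueError("need samples at both the control and endpoint time points")
    ratio = norm[end_cols].mean(axis=1) / norm[ctl_cols].mean(axis=1)
    logs = np.log(ratio)
    return logs / np.log(2) if base == "2" else logs
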