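"""CELF1/MBNL1 co-binding analysis in 3' UTRs.

Includes expression-binned co-target enrichment, motif-anchored binding-site
localization within CLIP clusters, nearest cross-protein distance
distributions with two randomized nulls, the distance-shift (modified KS)
test, proximal/distal pair expression comparison, and developmental grouping
by relative site abundance.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import BindingSite

#: binding motifs (DNA 4mers, matched case-insensitively on the sense strand
#: of the mature transcript), from in vitro binding data
CELF1_MOTIFS = ("TGTT", "ATGT", "TTGT", "TGTC", "GTGT",
                "TGTA", "GTTT", "TGTG", "GTCT", "TTTT")
MBNL1_MOTIFS = ("GCTT", "CGCT", "TGCT", "GCGC", "CCGC", "CTGC",
                "GCTA", "ACGC", "CGCA", "AGCT", "TTGC", "CAGC")

DEFAULT_MOTIFS = {"CELF1": CELF1_MOTIFS, "MBNL1": MBNL1_MOTIFS}


def locate_binding_sites(
    cluster_seq: str,
    protein: str,
    gene_id: str,
    cluster_offset: int = 0,
    motifs: Mapping[str, Sequence[str]] | None = None,
) -> list[BindingSite]:
    """Point binding locations for a protein within one CLIP cluster.

    All motif-hit start positions (offsets within the 3' UTR,
    ``cluster_offset`` + in-cluster position) are returned; if no motif
    occurs in the cluster, a single site at the cluster midpoint is returned
    with source ``cluster_center``.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    motif_list = motifs.get(protein)
    if not motif_list:
        raise ValueError(f"no motifs configured for protein {protein!r}")
    seq = cluster_seq.upper().replace("U", "T")
    hits = sorted({
        i
        for m in motif_list
        for i in range(len(seq) - len(m) + 1)
        if seq[i:i + len(m)] == m
    })
    if hits:
        return [BindingSite(protein, gene_id, cluster_offset + i, "motif_in_cluster")
                for i in hits]
    center = cluster_offset + len(seq) // 2
    return [BindingSite(protein, gene_id, center, "cluster_center")]


def cobinding_enrichment(
    celf_targets: Iterable[str],
    mbnl_targets: Iterable[str],
    expression: pd.Series,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Expression-controlled enrichment of shared CELF1/MBNL1 targets.

    Genes (the index of ``expression``) are split into ``n_bins``
    equal-occupancy expression bins; within each bin the expected number of
    co-targets under independence is n * (a/n) * (b/n).  The pooled ratio is
    the mean of per-bin observed/expected ratios (bins with zero expectation
    skipped), and significance is Fisher's exact test on the pooled 2x2
    table.  Target sets should already be restricted to genes with at least
    the configured minimum number of CLIP clusters per factor (default 2 in
    the study design).
    """
    genes = expression.index
    if n_bins > len(genes):
        raise ValueError(f"n_bins={n_bins} exceeds {len(genes)} genes")
    celf = set(celf_targets) & set(genes)
    mbnl = set(mbnl_targets) & set(genes)
    ranks = expression.rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False)
    rows = []
    for b in range(n_bins):
        members = set(genes[bins == b])
        n = len(members)
        a = len(celf & members)
        m = len(mbnl & members)
        obs = len(celf & mbnl & members)
        exp = n * (a / n) * (m / n) if n else 0.0
        rows.append({"bin": b, "n_genes": n, "n_celf": a, "n_mbnl": m,
                     "observed": obs, "expected": exp,
                     "ratio": obs / exp if exp > 0 else np.nan})
    table = pd.DataFrame(rows)
    ratios = table["ratio"].dropna()
    pooled = float(ratios.mean()) if len(ratios) else np.nan
    both = len(celf & mbnl)
    celf_only = len(celf - mbnl)
    mbnl_only = len(mbnl - celf)
    neither = len(genes) - both - celf_only - mbnl_only
    _, fisher_p = stats.fisher_exact([[both, celf_only], [mbnl_only, neither]])
    return table, {"pooled_ratio": pooled, "fisher_p": float(fisher_p),
                   "observed_total": float(both)}


def _sites_by_gene(sites: Iterable[BindingSite]) -> dict[str, dict[str, list[int]]]:
    by_gene: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for s in sites:
        by_gene[s.gene_id][s.protein].append(s.position)
    return by_gene


def _nearest_cross_distances(
    pos_a: Sequence[int], pos_b: Sequence[int], mode: str
) -> list[int]:
    a = np.asarray(sorted(pos_a))
    b = np.asarray(sorted(pos_b))
    d_ab = [int(np.min(np.abs(b - p))) for p in a]
    d_ba = [int(np.min(np.abs(a - p))) for p in b]
    if mode == "all_nearest":
        return d_ab + d_ba
    if mode == "per_utr_min":
        return [min(d_ab + d_ba)]
    raise ValueError(f"unknown mode {mode!r}")


def min_distance_distribution(
    sites: Iterable[BindingSite],
    utr_lengths: Mapping[str, int],
    proteins: tuple[str, str] = ("CELF1", "MBNL1"),
    mode: str = "all_nearest",
    null: str | None = None,
    seed: int | None = 0,
) -> dict[str, object]:
    """Nearest cross-protein binding distances per 3' UTR.

    For each site of either protein the distance to the nearest site of the
    other protein is recorded (``mode="all_nearest"``; ``"per_utr_min"``
    keeps one minimum per UTR).  UTRs carrying sites for only one protein
    are excluded and counted.  Nulls: ``random_placement`` redraws positions
    uniformly within the UTR preserving per-protein site counts;
    ``identity_shuffle`` permutes protein labels over the fixed positions.
    """
    rng = np.random.default_rng(seed)
    pa, pb = proteins
    distances: list[int] = []
    n_excluded = 0
    for gene, per_prot in sorted(_sites_by_gene(sites).items()):
        pos_a, pos_b = per_prot.get(pa, []), per_prot.get(pb, [])
        if not pos_a or not pos_b:
            n_excluded += 1
            continue
        if null == "random_placement":
            L = utr_lengths[gene]
            pos_a = rng.integers(0, L, size=len(pos_a)).tolist()
            pos_b = rng.integers(0, L, size=len(pos_b)).tolist()
        elif null == "identity_shuffle":
            pooled = list(pos_a) + list(pos_b)
            labels = [pa] * len(pos_a) + [pb] * len(pos_b)
            rng.shuffle(labels)
            pos_a = [p for p, l in zip(pooled, labels) if l == pa]
            pos_b = [p for p, l in zip(pooled, labels) if l == pb]
            if not pos_a or not pos_b:
                n_excluded += 1
                continue
        elif null is not None:
            raise ValueError(f"unknown null {null!r}")
        distances.extend(_nearest_cross_distances(pos_a, pos_b, mode))
    return {"distances": np.array(distances), "n_excluded_utrs": n_excluded}


def distance_shift_test(
    observed: Sequence[float],
    null: Sequence[float],
    alpha: float = 0.01,
) -> dict[str, float]:
    """Two-sample KS test with a median-shift confirmation.

    A "proximity" call requires both a KS p-value below ``alpha`` and a
    negative median shift (observed median below null median) — the
    operational form of confirming a true shift in medians on the
    cumulative distributions.
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if len(obs) < 2 or len(nul) < 2:
        raise ValueError("need at least two distances per sample")
    ks = stats.ks_2samp(obs, nul)
    shift = float(np.median(obs) - np.median(nul))
    return {"ks_statistic": float(ks.statistic), "p": float(ks.pvalue),
            "median_shift": shift,
            "proximity_call": bool(ks.pvalue < alpha and shift < 0)}


def proximal_pair_expression(
    pairs: pd.DataFrame,
    cutoff: float = 50.0,
) -> pd.DataFrame:
    """Expression change for genes with one site per protein, split at the
    distance cutoff (proximal means distance <= cutoff).

    ``pairs`` needs columns ``gene_id, distance, log2_change``.  Two-sided
    rank-sum test between the groups.
    """
    prox = pairs[pairs["distance"] <= cutoff]
    dist = pairs[pairs["distance"] > cutoff]
    if len(prox) and len(dist):
        p = float(stats.mannwhitneyu(prox["log2_change"], dist["log2_change"],
                                     alternative="two-sided").pvalue)
    else:
        p = np.nan
    return pd.DataFrame([
        {"group": f"proximal(<={cutoff:g})", "n": len(prox),
         "mean_log2_change": float(prox["log2_change"].mean()) if len(prox) else np.nan,
         "p_ranksum": p},
        {"group": f"distal(>{cutoff:g})", "n": len(dist),
         "mean_log2_change": float(dist["log2_change"].mean()) if len(dist) else np.nan,
         "p_ranksum": p},
    ])


def expression_comparison_table(
    counts: pd.DataFrame,
    min_fold: float = 1.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise expression-change comparisons shaped for the monotonicity
    module (expression stands in for PSI).

    ``counts`` is tidy with columns ``gene_id, sample_id, count``.  For each
    gene and unordered sample pair, ``delta_psi`` holds the log2 ratio
    (b over a, pseudocount 1) and ``bayes_factor`` a significance indicator
    (10 above / 0 below the downstream BF > 5 threshold): a comparison is
    significant when the fold change is at least ``min_fold`` and a binomial
    test of the two counts against an equal split rejects at ``alpha``.
    """
    rows = []
    for gene, grp in counts.groupby("gene_id", sort=True):
        recs = list(zip(grp["sample_id"], grp["count"].astype(int)))
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                (sa, ca), (sb, cb) = recs[i], recs[j]
                lfc = float(np.log2((cb + 1) / (ca + 1)))
                fold_ok = abs(lfc) >= np.log2(min_fold)
                p = stats.binomtest(cb, ca + cb, 0.5).pvalue if ca + cb else 1.0
                sig = fold_ok and p < alpha
                rows.append((gene, sa, sb, lfc, 10.0 if sig else 0.0))
    return pd.DataFrame(
        rows, columns=["event_id", "sample_a", "sample_b", "delta_psi", "bayes_factor"]
    )


def development_grouping(
    genes: pd.DataFrame,
    mz_filter: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Developmental expression change grouped by relative CELF/MBNL binding
    and proximal-pair presence.

    ``genes`` needs columns ``gene_id, n_celf, n_mbnl, has_proximal_pair,
    log2_change, expression_mz``.  Only genes with |expression MZ| above the
    filter enter.  Groups are CELF>MBNL / equal / MBNL>CELF crossed with
    proximal-pair presence; all group pairs are compared by two-sample KS
    test.  Empty groups are flagged.
    """
    sel = genes[genes["expression_mz"].abs() > mz_filter].copy()
    def rel(row) -> str:
        if row.n_celf > row.n_mbnl:
            return "CELF>MBNL"
        if row.n_celf < row.n_mbnl:
            return "MBNL>CELF"
        return "CELF=MBNL"
    sel["group"] = [
        f"{rel(r)}|{'proximal' if r.has_proximal_pair else 'no_proximal'}"
        for r in sel.itertuples(index=False)
    ]
    summary = (
        sel.groupby("group")["log2_change"]
        .agg(n="size", mean_log2_change="mean")
        .reset_index()
    )
    summary["flag"] = np.where(summary["n"] < 2, "low_n", "")
    groups = {g: grp["log2_change"].to_numpy() for g, grp in sel.groupby("group")}
    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            if len(groups[ga]) < 2 or len(groups[gb]) < 2:
                rows.append((ga, gb, np.nan, np.nan, "low_n"))
                continue
            ks = stats.ks_2samp(groups[ga], groups[gb])
            rows.append((ga, gb, float(ks.statistic), float(ks.pvalue), ""))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "ks_statistic", "p", "flag"])
    return summary, tests
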