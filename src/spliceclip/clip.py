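"""Crosslinking/immunoprecipitation (CLIP) read and cluster analysis.

Covers duplicate collapsing, coverage-based cluster calling, pentamer
enrichment Z-scores against resampled control regions, crosslink-induced
substitution (CIS) profiling with positional information content, windowed
density correlation between samples, and anchor-relative meta-density and
positional score (e.g. conservation) profiles.

Genomic coordinates are 0-based half-open.  A "genome" is a plain mapping of
chromosome name to an upper-case DNA string.  Sequence-level statistics are
reported in the RNA alphabet (T -> U) since binding is to RNA.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .events import ClipCluster, ClipRead, Interval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# read collapsing and cluster calling
# ---------------------------------------------------------------------------

def collapse_reads(reads: Iterable[ClipRead]) -> list[ClipRead]:
    """Collapse identical mapped sequences to a single read.

    Two reads are identical when coordinates, strand and substitution profile
    all agree (same mapped position and same substitutions implies the same
    read sequence).  Order of first occurrence is preserved.
    """
    seen: set[tuple] = set()
    out = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand, r.substitutions)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def coverage_array(
    reads: Sequence[ClipRead], chrom: str, strand: str, lo: int, hi: int
) -> np.ndarray:
    """Per-base read coverage on one strand of ``chrom`` over [lo, hi)."""
    cov = np.zeros(hi - lo, dtype=np.int64)
    for r in reads:
        if r.chrom != chrom or r.strand != strand:
            continue
        s, e = max(r.start, lo), min(r.end, hi)
        if s < e:
            cov[s - lo] += 1
            if e - lo < len(cov):
                cov[e - lo] -= 1
            # tail beyond hi is clipped by the min above
    np.cumsum(cov, out=cov)
    return cov


def call_clusters(
    reads: Sequence[ClipRead],
    min_height: int = 3,
    max_gap: int = 0,
) -> list[ClipCluster]:
    """Maximal runs of per-base coverage >= ``min_height`` per chrom/strand.

    Runs separated by at most ``max_gap`` sub-threshold bases are merged.
    Reads should already be collapsed.
    """
    by_cs: dict[tuple[str, str], list[ClipRead]] = defaultdict(list)
    for r in reads:
        by_cs[(r.chrom, r.strand)].append(r)
    clusters = []
    for (chrom, strand), rs in sorted(by_cs.items()):
        lo = min(r.start for r in rs)
        hi = max(r.end for r in rs)
        cov = coverage_array(rs, chrom, strand, lo, hi)
        above = cov >= min_height
        runs = _runs(above)
        merged = _merge_runs(runs, max_gap)
        for s, e in merged:
            clusters.append(
                ClipCluster(
                    chrom=chrom, start=lo + s, end=lo + e, strand=strand,
                    read_count=sum(1 for r in rs if r.start < lo + e and r.end > lo + s),
                    max_height=int(cov[s:e].max()),
                )
            )
    return clusters


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe <= max_gap:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def cluster_sequence(cluster: ClipCluster, genome: Mapping[str, str]) -> str:
    """Transcript-sense sequence of a cluster (DNA alphabet)."""
    seq = genome[cluster.chrom][cluster.start:cluster.end].upper()
    return revcomp(seq) if cluster.strand == "-" else seq


# ---------------------------------------------------------------------------
# kmer enrichment
# ---------------------------------------------------------------------------

def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGU", repeat=k)]


def kmer_count_vector(seqs: Iterable[str], k: int) -> pd.Series:
    """Overlapping kmer counts over RNA-alphabet sequences (Ns skipped)."""
    kmers = _all_kmers(k)
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers), dtype=np.int64)
    for seq in seqs:
        s = to_rna(seq)
        for i in range(len(s) - k + 1):
            j = index.get(s[i:i + k])
            if j is not None:
                counts[j] += 1
    return pd.Series(counts, index=kmers)


def kmer_enrichment_z(
    cluster_seqs: Sequence[str],
    control_seqs: Sequence[str],
    k: int = 5,
    n_resample: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-kmer enrichment Z of cluster sequences vs resampled controls.

    For each of ``n_resample`` draws, ``len(cluster_seqs)`` control regions
    are sampled with replacement from the control pool and kmer frequencies
    computed; Z = (f_cluster - mean f_control) / SD f_control.  Control
    regions should be matched in count and length distribution to the
    clusters (sampled from the same 3' UTR universe).  Kmers absent from
    every resample get Z = 0 with a ``zero_variance`` flag.
    """
    if min(len(s) for s in list(cluster_seqs) + list(control_seqs)) < k:
        raise ValueError(f"k={k} exceeds the shortest region length")
    rng = np.random.default_rng(seed)
    fc_counts = kmer_count_vector(cluster_seqs, k)
    f_cluster = fc_counts / max(fc_counts.sum(), 1)

    per_ctrl = np.stack([kmer_count_vector([s], k).to_numpy() for s in control_seqs])
    n = len(cluster_seqs)
    freqs = np.zeros((n_resample, per_ctrl.shape[1]))
    for b in range(n_resample):
        pick = rng.integers(0, len(control_seqs), size=n)
        tot = per_ctrl[pick].sum(axis=0)
        freqs[b] = tot / max(tot.sum(), 1)
    mu = freqs.mean(axis=0)
    sd = freqs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (f_cluster.to_numpy() - mu) / sd
    flag = np.where(sd == 0, "zero_variance", "")
    z = np.where(sd == 0, 0.0, z)
    return pd.DataFrame(
        {"kmer": f_cluster.index, "z": z, "f_cluster": f_cluster.to_numpy(),
         "f_control_mean": mu, "f_control_sd": sd, "flag": flag}
    ).sort_values("z", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# crosslink-induced substitutions
# ---------------------------------------------------------------------------

def cis_profile(
    reads: Sequence[ClipRead],
    genome: Mapping[str, str],
    min_cov: int = 10,
) -> pd.DataFrame:
    """Per-position substitution frequency in CLIP reads vs the genome.

    For every strand-specific genomic position covered by at least
    ``min_cov`` reads: CIS frequency = substituted reads / covering reads.
    ``ref_base`` is reported in transcript sense (complemented on minus
    strand).  Positions below ``min_cov`` are excluded.
    """
    cov: dict[tuple[str, int, str], int] = defaultdict(int)
    sub: dict[tuple[str, int, str], int] = defaultdict(int)
    for r in reads:
        for pos in range(r.start, r.end):
            cov[(r.chrom, pos, r.strand)] += 1
        for off, _ref, _alt in r.substitutions:
            sub[(r.chrom, r.start + off, r.strand)] += 1
    rows = []
    for (chrom, pos, strand), c in cov.items():
        if c < min_cov:
            continue
        base = genome[chrom][pos].upper()
        if strand == "-":
            base = base.translate(_COMPLEMENT)
        rows.append((chrom, pos, strand, base, c, sub.get((chrom, pos, strand), 0)))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "ref_base", "coverage", "substituted"]
    )
    df["cis_freq"] = df["substituted"] / df["coverage"]
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def info_content_by_cis(
    reads: Sequence[ClipRead],
    genome: Mapping[str, str],
    bins: Sequence[float] = (0.0, 0.01, 0.05, 0.15, 1.0001),
    min_cov: int = 10,
    flank: int = 5,
) -> pd.DataFrame:
    """Flanking-base information content around guanines binned by CIS rate.

    Guanine positions (transcript sense) are grouped into CIS-frequency bins;
    for each bin and sense-oriented offset in [-flank, +flank] the genomic
    base composition is tallied and its relative entropy versus the uniform
    distribution reported in bits.  Columns: bin label, offset, information
    content, per-base fractions (RNA alphabet), and the number of positions.
    """
    prof = cis_profile(reads, genome, min_cov=min_cov)
    gs = prof[prof["ref_base"] == "G"]
    edges = np.asarray(bins, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
    rows = []
    for i, label in enumerate(labels):
        sel = gs[(gs["cis_freq"] >= edges[i]) & (gs["cis_freq"] < edges[i + 1])]
        if sel.empty:
            continue
        for off in range(-flank, flank + 1):
            counts = {b: 0 for b in "ACGU"}
            n = 0
            for rec in sel.itertuples(index=False):
                step = off if rec.strand == "+" else -off
                gpos = rec.pos + step
                seq = genome[rec.chrom]
                if not (0 <= gpos < len(seq)):
                    continue
                base = seq[gpos].upper()
                if rec.strand == "-":
                    base = base.translate(_COMPLEMENT)
                base = "U" if base == "T" else base
                if base in counts:
                    counts[base] += 1
                    n += 1
            if n == 0:
                continue
            p = np.array([counts[b] for b in "ACGU"], dtype=float) / n
            nz = p[p > 0]
            info = float(np.sum(nz * np.log2(nz * 4)))
            rows.append((label, off, info, *(counts[b] / n for b in "ACGU"), n))
    return pd.DataFrame(
        rows,
        columns=["cis_bin", "offset", "info_bits",
                 "frac_A", "frac_C", "frac_G", "frac_U", "n_positions"],
    )


# ---------------------------------------------------------------------------
# density correlation and meta profiles
# ---------------------------------------------------------------------------

def _sense_start(read: ClipRead) -> int:
    return read.start if read.strand == "+" else read.end - 1


def _start_index(reads: Sequence[ClipRead]) -> dict[tuple[str, str], np.ndarray]:
    """Sorted sense-start positions per (chrom, strand) for fast region queries."""
    by_cs: dict[tuple[str, str], list[int]] = defaultdict(list)
    for r in reads:
        by_cs[(r.chrom, r.strand)].append(_sense_start(r))
    return {k: np.sort(np.array(v, dtype=np.int64)) for k, v in by_cs.items()}


def _region_window_counts_idx(
    index: Mapping[tuple[str, str], np.ndarray],
    region: tuple[str, int, int, str],
    window: int,
) -> np.ndarray:
    chrom, start, end, strand = region
    n_win = (end - start + window - 1) // window
    pos = index.get((chrom, strand))
    if pos is None or len(pos) == 0:
        return np.zeros(n_win, dtype=np.int64)
    lo, hi = np.searchsorted(pos, [start, end])
    sel = pos[lo:hi]
    offs = sel - start if strand == "+" else end - 1 - sel
    return np.bincount(offs // window, minlength=n_win)[:n_win]


def _region_window_counts(
    reads: Sequence[ClipRead], region: tuple[str, int, int, str], window: int
) -> np.ndarray:
    return _region_window_counts_idx(_start_index(reads), region, window)


def density_correlation(
    reads_a: Sequence[ClipRead],
    reads_b: Sequence[ClipRead],
    regions: Sequence[tuple[str, int, int, str]],
    window: int = 5,
    pseudocount: float = 1.0,
) -> float:
    """Pearson correlation of log windowed read-start densities.

    Densities are read-start counts per ``window``-nt window across the shared
    region universe (e.g. all expressed 3' UTRs); windows with zero counts in
    both samples are excluded; counts get a pseudocount before log.
    """
    idx_a, idx_b = _start_index(reads_a), _start_index(reads_b)
    va, vb = [], []
    for region in regions:
        va.append(_region_window_counts_idx(idx_a, region, window))
        vb.append(_region_window_counts_idx(idx_b, region, window))
    a = np.concatenate(va).astype(float)
    b = np.concatenate(vb).astype(float)
    keep = (a > 0) | (b > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than two informative windows")
    la, lb = np.log(a[keep] + pseudocount), np.log(b[keep] + pseudocount)
    if la.std() == 0 or lb.std() == 0:
        raise ValueError("zero-variance density vector")
    return float(np.corrcoef(la, lb)[0, 1])


def meta_density(
    reads: Sequence[ClipRead],
    regions: Sequence[tuple[str, int, int, str]],
    anchor: str = "utr_scaled",
    n_bins: int = 100,
    flank: int = 100,
    n_boot: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Mean read-start density at anchor-relative positions across regions.

    Anchors: ``utr_scaled`` length-normalizes each region to ``n_bins``
    relative bins; ``pas_offset`` aligns on the 3' end of each region (the
    cleavage/polyadenylation position, offset 0 = last UTR base, positive =
    downstream); ``splice_site_offset`` aligns on the 5' end.  Returns mean
    density and a bootstrap 95% band over regions.
    """
    rng = np.random.default_rng(seed)
    index = _start_index(reads)
    mats = []
    for region in regions:
        chrom, start, end, strand = region
        if anchor == "utr_scaled":
            counts = _region_window_counts_idx(index, region, 1).astype(float)
            L = len(counts)
            edges = np.linspace(0, L, n_bins + 1)
            binned = np.array(
                [counts[int(edges[i]):max(int(edges[i + 1]), int(edges[i]) + 1)].mean()
                 for i in range(n_bins)]
            )
            mats.append(binned)
        elif anchor in ("pas_offset", "splice_site_offset"):
            # offset 0 at the anchor; index i corresponds to offset i - flank
            if strand == "+":
                anchor_pos = end - 1 if anchor == "pas_offset" else start
            else:
                anchor_pos = start if anchor == "pas_offset" else end - 1
            pos = index.get((chrom, strand), np.empty(0, dtype=np.int64))
            lo, hi = np.searchsorted(pos, [anchor_pos - flank, anchor_pos + flank + 1])
            sel = pos[lo:hi]
            offs = sel - anchor_pos if strand == "+" else anchor_pos - sel
            offs = offs[(offs >= -flank) & (offs < flank)]
            mats.append(np.bincount(offs + flank, minlength=2 * flank).astype(float))
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
    mat = np.stack(mats)
    mean = mat.mean(axis=0)
    if n_boot > 0 and len(regions) > 1:
        boots = np.stack([
            mat[rng.integers(0, len(mat), size=len(mat))].mean(axis=0)
            for _ in range(n_boot)
        ])
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    else:
        lo = hi = mean
    if anchor == "utr_scaled":
        positions = np.arange(n_bins)
    else:
        positions = np.arange(-flank, flank)
    return pd.DataFrame({"position": positions, "mean_density": mean,
                         "ci_low": lo, "ci_high": hi})


def positional_score_profile(
    groups: Mapping[str, Sequence[tuple[str, int, int, str]]],
    scores: Mapping[str, np.ndarray],
    window: int = 5,
    n_boot: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Group-wise positional means of a per-base score track (e.g.
    conservation), averaged in ``window``-nt windows, with bootstrap SEM.

    All regions must have equal length (callers extract fixed anchor-relative
    windows).  Regions are oriented 5'->3' in transcript sense.
    """
    rng = np.random.default_rng(seed)
    out = []
    for group, regions in groups.items():
        mats = []
        for chrom, start, end, strand in regions:
            v = np.asarray(scores[chrom][start:end], dtype=float)
            if strand == "-":
                v = v[::-1]
            mats.append(v)
        lengths = {len(v) for v in mats}
        if len(lengths) != 1:
            raise ValueError(f"group {group!r} regions differ in length: {sorted(lengths)}")
        mat = np.stack(mats)
        L = mat.shape[1]
        n_win = L // window
        wmat = mat[:, : n_win * window].reshape(len(mat), n_win, window).mean(axis=2)
        mean = wmat.mean(axis=0)
        if n_boot > 0 and len(mat) > 1:
            boots = np.stack([
                wmat[rng.integers(0, len(wmat), size=len(wmat))].mean(axis=0)
                for _ in range(n_boot)
            ])
            sem = boots.std(axis=0, ddof=1)
        else:
            sem = np.zeros(n_win)
        for i in range(n_win):
            out.append((group, i * window, mean[i], sem[i]))
    return pd.DataFrame(out, columns=["group", "window_start", "mean_score", "sem"])


def stratified_match(
    candidates: pd.DataFrame,
    reference: pd.DataFrame,
    covariates: Sequence[str],
    n_strata: int = 5,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sample control rows matched to a reference on quantile strata.

    Each covariate is cut into ``n_strata`` quantile bins computed on the
    pooled data; candidates are drawn (with replacement when a stratum is
    short) to match the reference's joint stratum occupancy.
    """
    rng = np.random.default_rng(seed)
    pooled = pd.concat([candidates[list(covariates)], reference[list(covariates)]])
    keys_c, keys_r = [], []
    for cov in covariates:
        edges = np.unique(np.quantile(pooled[cov], np.linspace(0, 1, n_strata + 1)))
        keys_c.append(np.digitize(candidates[cov], edges[1:-1]))
        keys_r.append(np.digitize(reference[cov], edges[1:-1]))
    strat_c = pd.Series(list(zip(*keys_c)), index=candidates.index)
    strat_r = pd.Series(list(zip(*keys_r)), index=reference.index)
    picks = []
    for stratum, n_needed in strat_r.value_counts().items():
        pool = candidates.index[strat_c == stratum]
        if len(pool) == 0:
            pool = candidates.index  # fall back to the whole pool
        replace = len(pool) < n_needed
        picks.extend(rng.choice(pool, size=n_needed, replace=replace))
    return candidates.loc[picks]
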