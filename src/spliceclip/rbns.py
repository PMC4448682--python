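"""RNA Bind-n-Seq kmer enrichment analysis.

Random RNA oligos (40mers) are equilibrated with a tagged protein; pulldown
and input libraries are sequenced, and per-kmer enrichment is

    R(kmer) = frequency in pulldown / frequency in input

with a pseudocount of 1 on counts before forming frequencies.  Kmers are
classified by the Z-score of R across all 4^k kmers (weak [1,2), medium
[2,3), strong >=3), and the invariance of the protein's specificity across
competitor concentrations is summarized by pairwise rank correlations of R
vectors and per-kmer relative changes.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import RbnsExperiment


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGU", repeat=k)]


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGU"):
    _BASE_CODE[ord(_b)] = _i
_BASE_CODE[ord("T")] = _BASE_CODE[ord("U")]


def encode_reads(reads: Sequence[str]) -> np.ndarray:
    """Equal-length, N-free reads as a (n, L) uint8 array of base codes."""
    joined = "".join(reads).upper().encode()
    arr = _BASE_CODE[np.frombuffer(joined, dtype=np.uint8)]
    return arr.reshape(len(reads), -1)


def kmer_code_matrix(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer kmer codes for every window of every encoded read."""
    n, L = arr.shape
    codes = np.zeros((n, L - k + 1), dtype=np.int64)
    for i in range(k):
        codes += arr[:, i:L - k + 1 + i].astype(np.int64) * 4 ** (k - 1 - i)
    return codes


def count_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(codes.ravel(), minlength=4 ** k)


def count_kmers(reads: Iterable[str], k: int = 6) -> pd.Series:
    """Overlapping kmer counts across reads (RNA alphabet; Ns skipped).

    A read of length L contributes L - k + 1 kmer tokens (fewer when it
    contains N).  Equal-length N-free read sets take a vectorised path.
    """
    kmers = all_kmers(k)
    reads = list(reads)
    if reads and len({len(r) for r in reads}) == 1 and not any(
            "N" in r.upper() for r in reads):
        arr = encode_reads(reads)
        counts = count_kmer_codes(kmer_code_matrix(arr, k), k)
        return pd.Series(counts, index=kmers, name="count")
    index = {km: i for i, km in enumerate(kmers)}
    counts = np.zeros(len(kmers), dtype=np.int64)
    for read in reads:
        s = read.upper().replace("T", "U")
        for i in range(len(s) - k + 1):
            j = index.get(s[i:i + k])
            if j is not None:
                counts[j] += 1
    return pd.Series(counts, index=kmers, name="count")


def make_experiment(
    input_reads: Iterable[str],
    pulldown_reads: Iterable[str],
    condition: str = "0nM",
    k: int = 6,
    read_length: int = 40,
) -> RbnsExperiment:
    return RbnsExperiment(
        condition=condition,
        input_counts=count_kmers(input_reads, k).to_dict(),
        pulldown_counts=count_kmers(pulldown_reads, k).to_dict(),
        read_length=read_length,
        k=k,
    )


def rbns_r(experiment: RbnsExperiment, pseudocount: float = 1.0) -> pd.Series:
    """Per-kmer enrichment R = pulldown frequency / input frequency.

    With the pseudocount disabled, kmers absent from the input get R = NaN
    (flagged undefined by the caller); the default pseudocount of 1 keeps
    every R finite.
    """
    kmers = all_kmers(experiment.k)
    inp = np.array([experiment.input_counts.get(km, 0) for km in kmers], dtype=float)
    pul = np.array([experiment.pulldown_counts.get(km, 0) for km in kmers], dtype=float)
    if inp.sum() == 0 or pul.sum() == 0:
        raise ValueError("both libraries must be non-empty")
    inp += pseudocount
    pul += pseudocount
    f_in = inp / inp.sum()
    f_pd = pul / pul.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(f_in > 0, f_pd / f_in, np.nan)
    return pd.Series(r, index=kmers, name="R")


def classify_kmers(r: pd.Series) -> pd.DataFrame:
    """Class per kmer from the Z-score of R over all kmers.

    Bands are half-open: weak [1,2), medium [2,3), strong [3, inf); Z below
    1 is "other".  A zero-variance R distribution leaves Z undefined; all
    kmers are then "other" with a flag.
    """
    mu = float(r.mean())
    sd = float(r.std(ddof=0))
    if sd == 0:
        return pd.DataFrame({"kmer": r.index, "R": r.to_numpy(),
                             "z": 0.0, "klass": "other", "flag": "zero_variance"})
    z = (r - mu) / sd
    klass = pd.cut(
        z, bins=[-np.inf, 1, 2, 3, np.inf],
        labels=["other", "weak", "medium", "strong"], right=False,
    ).astype(str)
    return pd.DataFrame({"kmer": r.index, "R": r.to_numpy(),
                         "z": z.to_numpy(), "klass": klass.to_numpy(), "flag": ""})


def specificity_invariance(
    experiments: Sequence[RbnsExperiment],
    reference_kmers: Iterable[str] = (),
    tolerance: float = 0.10,
    pseudocount: float = 1.0,
) -> dict[str, object]:
    """Invariance of binding specificity across competitor concentrations.

    Returns the R table (kmer x condition), pairwise Spearman correlations
    of R vectors, and flags for any reference-class kmer (e.g. the known
    CELF1-binding set) whose R changes by more than ``tolerance`` relative
    to its value in the first experiment.
    """
    if len(experiments) < 2:
        raise ValueError("need at least two experiments to compare")
    table = pd.DataFrame({e.condition: rbns_r(e, pseudocount) for e in experiments})
    conds = list(table.columns)
    rows = []
    for i, ca in enumerate(conds):
        for cb in conds[i + 1:]:
            rho, _ = stats.spearmanr(table[ca], table[cb])
            rows.append((ca, cb, float(rho)))
    corr = pd.DataFrame(rows, columns=["condition_a", "condition_b", "spearman_rho"])
    flags = []
    ref = [km for km in reference_kmers if km in table.index]
    base = conds[0]
    for km in ref:
        r0 = table.loc[km, base]
        for c in conds[1:]:
            rel = abs(table.loc[km, c] - r0) / r0 if r0 > 0 else np.inf
            if rel > tolerance:
                flags.append({"kmer": km, "condition": c,
                              "relative_change": float(rel)})
    max_change = max((f["relative_change"] for f in flags), default=0.0)
    return {"r_table": table, "pairwise_correlation": corr,
            "flags": flags, "max_reference_change": max_change}
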