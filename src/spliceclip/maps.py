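"""RNA-map style analyses relating binding to splicing outcome, and
cross-perturbation comparisons of regulation (overlap enrichment, direction
concordance, correlation of delta-PSI, reading-frame preservation)."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BINDING_REGIONS = ("exon", "upstream_intron_1kb", "downstream_intron_1kb")


def repressed_fraction_by_binding(
    events: pd.DataFrame,
    mz_thresholds: Sequence[float] = (1.0, 1.5, 2.0),
) -> pd.DataFrame:
    """Fraction of responsive exons repressed, with vs without binding.

    ``events`` needs columns ``event_id, mz, delta_psi_endpoint, bound``
    (boolean: CLIP cluster in the region under study).  An event is
    "repressed" iff its endpoint PSI is below control (delta_psi_endpoint,
    oriented endpoint minus control, < 0).  At each monotonicity threshold
    the bound-group repressed count is tested against the unbound-group
    repressed fraction as the null rate (binomial test, two-sided).  Empty
    cells are flagged and untested.
    """
    rows = []
    for thr in mz_thresholds:
        sel = events[events["mz"].abs() > thr]
        for bound in (True, False):
            grp = sel[sel["bound"] == bound]
            n = len(grp)
            rep = int((grp["delta_psi_endpoint"] < 0).sum())
            rows.append({"mz_threshold": thr, "bound": bound, "n": n,
                         "n_repressed": rep,
                         "fraction_repressed": rep / n if n else np.nan,
                         "flag": "" if n else "empty_group"})
    out = pd.DataFrame(rows)
    # binomial p for the bound cell against the unbound fraction at each threshold
    pvals = []
    for rec in out.itertuples(index=False):
        if not rec.bound or rec.n == 0:
            pvals.append(np.nan)
            continue
        null = out[(out["mz_threshold"] == rec.mz_threshold) & (~out["bound"])]
        null_frac = float(null["fraction_repressed"].iloc[0])
        if not np.isfinite(null_frac) or null_frac in (0.0, 1.0):
            null_frac = min(max(null_frac if np.isfinite(null_frac) else 0.5, 1e-9), 1 - 1e-9)
        pvals.append(stats.binomtest(rec.n_repressed, rec.n, null_frac).pvalue)
    out["p_binomial"] = pvals
    return out


def overlap_enrichment(
    regulated_a: Iterable[str],
    regulated_b: Iterable[str],
    universe: Iterable[str],
) -> dict[str, float]:
    """Observed/expected overlap of two regulated-event sets.

    Expected overlap assumes independence: |U| * (|A|/|U|) * (|B|/|U|).
    """
    u = set(universe)
    a = set(regulated_a) & u
    b = set(regulated_b) & u
    if not u:
        raise ValueError("empty universe")
    observed = len(a & b)
    expected = len(u) * (len(a) / len(u)) * (len(b) / len(u))
    ratio = observed / expected if expected > 0 else np.nan
    return {"observed": float(observed), "expected": float(expected), "ratio": float(ratio)}


def direction_concordance(
    delta_a: Mapping[str, float],
    delta_b: Mapping[str, float],
) -> dict[str, float]:
    """Fraction of shared regulated events changing in the same direction.

    Events with delta-PSI of zero in either comparison are excluded.  The
    two-sided exact binomial test uses a null frequency of 0.5.
    """
    shared = [e for e in delta_a if e in delta_b
              and delta_a[e] != 0 and delta_b[e] != 0]
    if not shared:
        raise ValueError("no shared events with nonzero changes")
    same = sum(1 for e in shared if np.sign(delta_a[e]) == np.sign(delta_b[e]))
    p = stats.binomtest(same, len(shared), 0.5).pvalue
    return {"n": float(len(shared)), "n_same": float(same),
            "fraction_same": same / len(shared), "p_binomial": float(p)}


def correlation_monotonic(
    delta_a: Mapping[str, float],
    delta_b: Mapping[str, float],
    selected: Iterable[str],
) -> dict[str, object]:
    """Spearman correlation of delta-PSI over selected (monotonic) events,
    with per-quadrant counts of the scatter."""
    events = [e for e in selected if e in delta_a and e in delta_b]
    if len(events) < 3:
        raise ValueError("need at least 3 shared selected events")
    xa = np.array([delta_a[e] for e in events])
    xb = np.array([delta_b[e] for e in events])
    rho, p = stats.spearmanr(xa, xb)
    quad = {
        "up_up": int(((xa > 0) & (xb > 0)).sum()),
        "up_down": int(((xa > 0) & (xb < 0)).sum()),
        "down_up": int(((xa < 0) & (xb > 0)).sum()),
        "down_down": int(((xa < 0) & (xb < 0)).sum()),
    }
    return {"rho": float(rho), "p": float(p), "n": len(events), "quadrants": quad}


def frame_preservation(
    exon_lengths: Sequence[int],
    background_rate: float = 0.44,
) -> dict[str, float]:
    """Count and fraction of exons whose length is a multiple of 3.

    Tested one-sided (greater) against the supplied background preservation
    rate among alternative exons by exact binomial test.
    """
    lengths = list(exon_lengths)
    if not lengths:
        raise ValueError("no exons supplied")
    if not 0 < background_rate < 1:
        raise ValueError("background rate must be in (0, 1)")
    preserved = sum(1 for L in lengths if L % 3 == 0)
    p = stats.binomtest(preserved, len(lengths), background_rate,
                        alternative="greater").pvalue
    return {"n": float(len(lengths)), "n_preserved": float(preserved),
            "fraction_preserved": preserved / len(lengths), "p_binomial": float(p)}
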