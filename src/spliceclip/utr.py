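"""Alternative 3' UTR isoform analysis and per-site potency models.

Tandem UTR events have a "core" region shared by both isoforms and an
"extension" present only in the distal-PAS isoform; ALE events have two
mutually exclusive last exons.  Binding in these regions is related to
isoform shifts and to gene-level expression change through a log-linear
model: log(expression change) is proportional to

    tandem:  n_core * b_core  +  n_extension * psi_extension * b_extension
    ALE:     (n_ale1 * psi_ale1 + n_ale2 * psi_ale2) * b_ale

where psi_* are the isoform fractions in the control condition (site exposure
precedes regulation) and the b coefficients are per-site effects on natural-
log expression.  Coefficients are estimated by least squares with no
intercept (the model is proportional) and reported both on the log scale and
as percent change per site, (1 - e^b) * 100, so a negative coefficient reads
as percent down-regulation per site.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .events import PotencyFit

#: cluster-density bin edges (clusters per kb of 3' UTR)
DENSITY_BIN_EDGES = (0.0, 1.0, 2.0, 4.0)


def percent_per_site(coef: float) -> float:
    """Convert a natural-log per-site coefficient to percent change per site."""
    return (1.0 - float(np.exp(coef))) * 100.0


def percent_to_coef(percent: float) -> float:
    """Inverse of :func:`percent_per_site` (exact round-trip)."""
    return float(np.log(1.0 - percent / 100.0))


def shift_fraction_table(
    events: pd.DataFrame,
    bin_col: str,
    shift_col: str = "delta_psi_distal",
    min_bin_n: int = 3,
) -> pd.DataFrame:
    """Per-bin fraction of events shifting toward the proximal isoform.

    ``events`` should already be filtered to significant monotone events
    (class thresholds: tandem UTR MZ > 1.6, ALE MZ > 1.5).  ``shift_col``
    holds the change in distal-isoform fraction (endpoint minus control);
    negative values mean a shift toward proximal PAS usage.  Each bin gets
    an exact two-sided binomial test against 0.5 (equal likelihood of a
    long- or short-isoform shift); bins with fewer than ``min_bin_n``
    events are flagged low-n.
    """
    rows = []
    for bin_label, grp in events.groupby(bin_col, sort=True):
        shifts = grp[shift_col]
        nz = shifts[shifts != 0]
        n = len(nz)
        prox = int((nz < 0).sum())
        p = stats.binomtest(prox, n, 0.5).pvalue if n else np.nan
        rows.append({bin_col: bin_label, "n": n, "n_proximal": prox,
                     "fraction_proximal": prox / n if n else np.nan,
                     "p_binomial": p,
                     "flag": "low_n" if n < min_bin_n else ""})
    return pd.DataFrame(rows)


def assign_density_bins(
    density_per_kb: pd.Series,
    edges: Sequence[float] = DENSITY_BIN_EDGES,
) -> pd.Series:
    """Cluster-density bins {0, (0,1], (1,2], (2,4], >4} per kb."""
    def label(d: float) -> str:
        if d == 0:
            return "0"
        prev = edges[0]
        for e in edges[1:]:
            if d <= e:
                return f"({prev:g},{e:g}]"
            prev = e
        return f">{edges[-1]:g}"
    return density_per_kb.map(label)


def expression_change_by_bins(
    log2_change: pd.Series,
    bins: pd.Series,
    reference_bin: str = "0",
) -> pd.DataFrame:
    """Mean log2 expression change per binding bin, tested against the
    zero-cluster bin by two-sided rank-sum test."""
    df = pd.DataFrame({"change": log2_change, "bin": bins}).dropna()
    if reference_bin not in set(df["bin"]):
        raise ValueError(f"reference bin {reference_bin!r} absent")
    ref = df.loc[df["bin"] == reference_bin, "change"].to_numpy()
    rows = []
    for bin_label, grp in df.groupby("bin", sort=True):
        vals = grp["change"].to_numpy()
        if bin_label == reference_bin:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(vals, ref, alternative="two-sided").pvalue)
        rows.append({"bin": bin_label, "n": len(vals),
                     "mean_log2_change": float(vals.mean()), "p_ranksum": p})
    return pd.DataFrame(rows)


def _ols_potency(X: pd.DataFrame, y: np.ndarray) -> PotencyFit:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        zero = [c for c in X.columns if np.allclose(X[c], 0)]
        dup = [c for c in X.columns if c not in zero]
        bad = zero if zero else dup
        raise ValueError(f"rank-deficient design; collinear/empty columns: {bad}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    coefs = {c: float(fit.params[c]) for c in X.columns}
    conf = {c: (float(ci.loc[c, 0]), float(ci.loc[c, 1])) for c in X.columns}
    pct = {c: percent_per_site(v) for c, v in coefs.items()}
    pct_ci = {c: tuple(sorted((percent_per_site(hi), percent_per_site(lo))))
              for c, (lo, hi) in conf.items()}
    resid_sd = float(np.sqrt(fit.scale)) if fit.df_resid > 0 else 0.0
    return PotencyFit(
        coefficients=coefs, conf_int=conf,
        percent_per_site=pct, percent_ci=pct_ci,
        n_genes=len(y), residual_sd=resid_sd,
    )


def fit_potency_tandem(
    genes: pd.DataFrame,
    *,
    intercept: bool = False,
    min_genes: int = 10,
) -> PotencyFit:
    """Per-site potency for tandem-UTR core and extension binding.

    ``genes`` needs columns ``n_core, n_extension, psi_extension,
    log_change`` (natural log of endpoint/control normalized expression).
    """
    if len(genes) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(genes)}")
    X = pd.DataFrame({
        "core": genes["n_core"].astype(float),
        "extension": (genes["n_extension"] * genes["psi_extension"]).astype(float),
    })
    if intercept:
        X.insert(0, "intercept", 1.0)
    return _ols_potency(X, genes["log_change"].to_numpy(dtype=float))


def fit_potency_ale(
    genes: pd.DataFrame,
    *,
    intercept: bool = False,
    min_genes: int = 10,
) -> PotencyFit:
    """Single shared per-site potency for alternative-last-exon binding.

    ``genes`` needs columns ``n_ale1, psi_ale1, n_ale2, psi_ale2,
    log_change``.  The design has one column: n1*psi1 + n2*psi2.
    """
    if len(genes) < min_genes:
        raise ValueError(f"need >= {min_genes} genes, got {len(genes)}")
    X = pd.DataFrame({
        "ale": (genes["n_ale1"] * genes["psi_ale1"]
                + genes["n_ale2"] * genes["psi_ale2"]).astype(float),
    })
    if intercept:
        X.insert(0, "intercept", 1.0)
    return _ols_potency(X, genes["log_change"].to_numpy(dtype=float))


def isoform_shift_vs_development(
    shift_a: Mapping[str, float],
    shift_b: Mapping[str, float],
) -> dict[str, float]:
    """Spearman correlation of isoform shifts across two contrasts, over
    events present in both (callers apply per-contrast MZ thresholds)."""
    events = [e for e in shift_a if e in shift_b]
    if len(events) < 3:
        raise ValueError("need at least 3 shared events")
    xa = np.array([shift_a[e] for e in events])
    xb = np.array([shift_b[e] for e in events])
    rho, p = stats.spearmanr(xa, xb)
    return {"rho": float(rho), "p": float(p), "n": float(len(events))}
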