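"""End-to-end orchestration of the synthetic-data analysis pipeline.

``run_all`` executes simulate -> psi -> mz -> clip -> maps -> utr -> cobind
-> rbns on a single YAML-style config, writing every stage artifact as
plain-text TSV/BED/GFF3/FASTA plus a markdown report.  Every output carries
the config hash and seed; a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clip as clip_mod
from . import cobinding, expression, io, maps, monotonicity, psi, rbns, utr
from .events import ClipCluster
from .synthetic import (
    Annotation, SimulationConfig, simulate_annotation, simulate_clip_reads,
    simulate_rbns_reads, simulate_timecourse_counts,
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {},
    "thresholds": {
        "bf": 5.0,
        "mz_se": 1.8,
        "mz_tandem": 1.6,
        "mz_ale": 1.5,
        "mz_development": 1.4,
        "mz_expression": 0.5,
        "distance_cutoff": 50,
        "min_reads": 20,
        "min_clusters": 2,
    },
    "clip": {"min_height": 3, "max_gap": 0, "kmer_k": 5, "n_resample": 50},
    "monotonicity": {"n_perm": 100},
    "rbns": {
        "n_reads": 100000,
        "concentrations": ["0nM", "64nM", "130nM", "250nM", "1000nM"],
    },
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge a YAML config file over the defaults, validating the schema."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    user: dict[str, Any] = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        user = _deep_merge(user, dict(overrides))
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            known = set(cfg[key]) if key != "simulation" else None
            for k2 in val:
                if known is not None and k2 not in known:
                    raise ConfigError(f"unknown key {key}.{k2}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "simulation" in user:
        valid = set(SimulationConfig.__dataclass_fields__)
        for k2 in user["simulation"]:
            if k2 not in valid:
                raise ConfigError(f"unknown key simulation.{k2}")
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# cluster/region helpers
# ---------------------------------------------------------------------------

def clusters_in_interval(
    clusters: Sequence[ClipCluster], chrom: str, interval: tuple[int, int], strand: str
) -> list[ClipCluster]:
    s, e = interval
    return [c for c in clusters
            if c.chrom == chrom and c.strand == strand and c.start < e and c.end > s]


def build_utr_profiles(
    annotation: Annotation,
    clusters: Sequence[ClipCluster],
    psi_control: Mapping[str, float],
) -> pd.DataFrame:
    """Per-gene binding profile: cluster counts per UTR region, density per
    kb, and control-condition isoform fractions."""
    rows = []
    for gene in annotation.genes:
        rec: dict[str, Any] = {"gene_id": gene.gene_id, "utr_type": gene.utr_type}
        total = 0
        if gene.utr_type == "tandem":
            for region, col in (("core", "n_core"), ("extension", "n_extension")):
                n = len(clusters_in_interval(clusters, gene.chrom,
                                             gene.regions[region], gene.strand))
                rec[col] = n
                total += n
            rec["n_ale1"] = rec["n_ale2"] = 0
            rec["psi_extension"] = psi_control.get(f"{gene.gene_id}_UTR", np.nan)
            rec["psi_ale1"] = rec["psi_ale2"] = np.nan
        else:
            for region, col in (("ale1", "n_ale1"), ("ale2", "n_ale2")):
                n = len(clusters_in_interval(clusters, gene.chrom,
                                             gene.regions[region], gene.strand))
                rec[col] = n
                total += n
            rec["n_core"] = rec["n_extension"] = 0
            p1 = psi_control.get(f"{gene.gene_id}_UTR", np.nan)
            rec["psi_ale1"] = p1
            rec["psi_ale2"] = 1.0 - p1 if np.isfinite(p1) else np.nan
            rec["psi_extension"] = np.nan
        rec["cluster_density_per_kb"] = total / (gene.utr_length / 1000.0)
        rows.append(rec)
    return pd.DataFrame(rows)


def _psi_means(psi_df: pd.DataFrame, time_order: Mapping[str, int],
               ordinal: int) -> pd.Series:
    cols = [s for s in psi_df["sample_id"].unique() if time_order[s] == ordinal]
    sel = psi_df[psi_df["sample_id"].isin(cols)]
    return sel.groupby("event_id")["psi_mean"].mean()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_all(cfg: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run every stage on synthetic data; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    thr = cfg["thresholds"]
    summary: dict[str, Any] = {"config_hash": chash, "seed": seed}

    # --- simulate ---------------------------------------------------------
    sim_kwargs = dict(cfg["simulation"])
    sim_kwargs.setdefault("seed", seed)
    sim = SimulationConfig(**sim_kwargs)
    annotation = simulate_annotation(sim)
    io.write_genome_fasta(annotation.genome, out / "genome.fa")
    io.write_annotation_gff3(annotation, out / "annotation.gff3")
    io.write_events_tsv(annotation.events, out / "events.tsv")
    splice_counts, gene_counts, time_order = simulate_timecourse_counts(annotation)
    _tsv(splice_counts, out / "splice_counts.tsv")
    _tsv(gene_counts, out / "gene_counts.tsv")
    (out / "time_order.json").write_text(
        json.dumps(time_order, indent=2, sort_keys=True))

    # --- psi --------------------------------------------------------------
    psi_df, skipped = psi.psi_table(splice_counts, min_reads=int(thr["min_reads"]))
    _tsv(psi_df, out / "psi.tsv")
    comparisons = psi.pairwise_comparisons(psi_df)
    _tsv(comparisons, out / "comparisons.tsv")
    summary["n_events"] = int(psi_df["event_id"].nunique())
    summary["n_skipped_low_reads"] = len(skipped)

    # --- mz ---------------------------------------------------------------
    mz_df = monotonicity.monotonicity_table(
        comparisons, time_order,
        n_perm=int(cfg["monotonicity"]["n_perm"]), seed=seed + 10,
        bf_threshold=float(thr["bf"]),
    )
    _tsv(mz_df, out / "mz.tsv")
    classes = {ev.event_id: ev.event_class for ev in annotation.events}
    called = monotonicity.call_monotonic(
        mz_df,
        {"SE": float(thr["mz_se"]), "TandemUTR": float(thr["mz_tandem"]),
         "ALE": float(thr["mz_ale"])},
        event_classes=classes,
    )
    _tsv(called, out / "called_monotonic.tsv")
    summary["n_called_monotonic"] = len(called)

    # --- clip -------------------------------------------------------------
    clip_cfg = cfg["clip"]
    clusters_by_protein: dict[str, list[ClipCluster]] = {}
    for protein in ("CELF1", "MBNL1"):
        reads, _ = simulate_clip_reads(annotation, protein=protein)
        collapsed = clip_mod.collapse_reads(reads)
        io.write_clip_bed(collapsed, out / f"clip_{protein}.bed",
                          out / f"clip_{protein}.subs.tsv")
        clusters = clip_mod.call_clusters(
            collapsed, min_height=int(clip_cfg["min_height"]),
            max_gap=int(clip_cfg["max_gap"]))
        io.write_clusters_bed(clusters, out / f"clusters_{protein}.bed")
        clusters_by_protein[protein] = clusters
    celf_clusters = clusters_by_protein["CELF1"]
    summary["n_celf_clusters"] = len(celf_clusters)

    utr_regions = []
    for gene in annotation.genes:
        first = "core" if gene.utr_type == "tandem" else "ale1"
        last = "extension" if gene.utr_type == "tandem" else "ale2"
        lo = min(gene.regions[first][0], gene.regions[last][0])
        hi = max(gene.regions[first][1], gene.regions[last][1])
        utr_regions.append((gene.chrom, lo, hi, gene.strand))
    cluster_seqs = [clip_mod.cluster_sequence(c, annotation.genome)
                    for c in celf_clusters if c.end - c.start >= int(clip_cfg["kmer_k"])]
    if cluster_seqs:
        rng = np.random.default_rng(seed + 20)
        controls = []
        for s in cluster_seqs:
            chrom, lo, hi, strand = utr_regions[int(rng.integers(0, len(utr_regions)))]
            L = len(s)
            if hi - lo <= L:
                start = lo
            else:
                start = int(rng.integers(lo, hi - L))
            ctrl = ClipCluster(chrom, start, start + L, strand, 0, 0)
            controls.append(clip_mod.cluster_sequence(ctrl, annotation.genome))
        kz = clip_mod.kmer_enrichment_z(
            cluster_seqs, controls, k=int(clip_cfg["kmer_k"]),
            n_resample=int(clip_cfg["n_resample"]), seed=seed + 21)
        _tsv(kz, out / "kmer_z.tsv")
        summary["top_kmer"] = str(kz.iloc[0]["kmer"])
    celf_reads = io.read_clip_bed(out / "clip_CELF1.bed", out / "clip_CELF1.subs.tsv")
    cis_info = clip_mod.info_content_by_cis(celf_reads, annotation.genome, min_cov=5)
    _tsv(cis_info, out / "cis_info.tsv")
    meta = clip_mod.meta_density(celf_reads, utr_regions, anchor="utr_scaled",
                                 seed=seed + 22)
    _tsv(meta, out / "meta_density_utr.tsv")

    # --- maps -------------------------------------------------------------
    ctl_psi = _psi_means(psi_df, time_order, 0)
    end_psi = _psi_means(psi_df, time_order, max(time_order.values()))
    se_events = [ev for ev in annotation.events if ev.event_class == "SE"]
    mz_by_event = mz_df.set_index("event_id")["mz"]
    rows = []
    for ev in se_events:
        if ev.event_id not in mz_by_event.index or ev.event_id not in end_psi.index:
            continue
        bound = bool(clusters_in_interval(celf_clusters, ev.chrom,
                                          ev.intervals["exon"], ev.strand))
        rows.append({"event_id": ev.event_id, "mz": mz_by_event[ev.event_id],
                     "delta_psi_endpoint": end_psi[ev.event_id] - ctl_psi[ev.event_id],
                     "bound": bound, "exon_length": ev.exon_length})
    se_df = pd.DataFrame(rows)
    rep_table = maps.repressed_fraction_by_binding(se_df)
    _tsv(rep_table, out / "repressed_by_binding.tsv")
    background_rate = float((se_df["exon_length"] % 3 == 0).mean())
    called_se = se_df[se_df["mz"].abs() > float(thr["mz_se"])]
    if len(called_se) and 0 < background_rate < 1:
        frame = maps.frame_preservation(called_se["exon_length"].tolist(),
                                        background_rate=background_rate)
    else:
        frame = {"n": 0.0, "n_preserved": 0.0,
                 "fraction_preserved": float("nan"), "p_binomial": float("nan")}
    summary["frame_preserved_fraction"] = frame["fraction_preserved"]

    # --- utr --------------------------------------------------------------
    counts_mat = expression.counts_matrix(gene_counts)
    log_change = expression.endpoint_log_change(counts_mat, time_order, base="e")
    log2_change = log_change / np.log(2)
    profiles = build_utr_profiles(annotation, celf_clusters, ctl_psi.to_dict())
    profiles = profiles.merge(
        log_change.rename("log_change"), left_on="gene_id", right_index=True)
    profiles["log2_change"] = profiles["log_change"] / np.log(2)
    _tsv(profiles, out / "utr_profiles.tsv")

    bins = utr.assign_density_bins(profiles.set_index("gene_id")["cluster_density_per_kb"])
    expr_bins = utr.expression_change_by_bins(
        profiles.set_index("gene_id")["log2_change"], bins)
    _tsv(expr_bins, out / "expression_by_density_bin.tsv")

    tandem = profiles[profiles["utr_type"] == "tandem"].dropna(
        subset=["psi_extension", "log_change"])
    ale = profiles[profiles["utr_type"] == "ale"].dropna(
        subset=["psi_ale1", "log_change"])
    potency_rows = []
    try:
        fit_t = utr.fit_potency_tandem(tandem)
        for name in ("core", "extension"):
            potency_rows.append({
                "model": "tandem", "term": name,
                "coef": fit_t.coefficients[name],
                "percent_per_site": fit_t.percent_per_site[name],
                "ci_low": fit_t.percent_ci[name][0],
                "ci_high": fit_t.percent_ci[name][1],
                "n_genes": fit_t.n_genes})
        summary["potency_core_pct"] = fit_t.percent_per_site["core"]
        summary["potency_extension_pct"] = fit_t.percent_per_site["extension"]
    except ValueError as exc:
        potency_rows.append({"model": "tandem", "term": f"error: {exc}"})
    try:
        fit_a = utr.fit_potency_ale(ale)
        potency_rows.append({
            "model": "ale", "term": "ale",
            "coef": fit_a.coefficients["ale"],
            "percent_per_site": fit_a.percent_per_site["ale"],
            "ci_low": fit_a.percent_ci["ale"][0],
            "ci_high": fit_a.percent_ci["ale"][1],
            "n_genes": fit_a.n_genes})
        summary["potency_ale_pct"] = fit_a.percent_per_site["ale"]
    except ValueError as exc:
        potency_rows.append({"model": "ale", "term": f"error: {exc}"})
    _tsv(pd.DataFrame(potency_rows), out / "potency_fits.tsv")

    called_utr = set(called["event_id"]) if len(called) else set()
    tandem_events = tandem[tandem["gene_id"].map(
        lambda g: f"{g}_UTR" in called_utr)].copy()
    if len(tandem_events):
        tandem_events["delta_psi_distal"] = tandem_events["gene_id"].map(
            lambda g: end_psi.get(f"{g}_UTR", np.nan) - ctl_psi.get(f"{g}_UTR", np.nan))
        tandem_events["ext_minus_core"] = (
            tandem_events["n_extension"] - tandem_events["n_core"]).clip(-3, 3)
        shift = utr.shift_fraction_table(tandem_events, "ext_minus_core")
        _tsv(shift, out / "tandem_shift_fractions.tsv")

    # --- cobind -----------------------------------------------------------
    min_clusters = int(thr["min_clusters"])
    expr_level = expression.normalize_median_ratio(counts_mat)[
        [s for s in counts_mat.columns if time_order[s] == 0]].mean(axis=1)
    targets = {}
    for protein, clusters in clusters_by_protein.items():
        per_gene = {}
        for gene in annotation.genes:
            first = "core" if gene.utr_type == "tandem" else "ale1"
            last = "extension" if gene.utr_type == "tandem" else "ale2"
            lo = min(gene.regions[first][0], gene.regions[last][0])
            hi = max(gene.regions[first][1], gene.regions[last][1])
            per_gene[gene.gene_id] = len(clusters_in_interval(
                clusters, gene.chrom, (lo, hi), gene.strand))
        targets[protein] = {g for g, n in per_gene.items() if n >= min_clusters}
    n_bins = min(10, max(2, len(expr_level) // 6))
    cb_table, cb_summary = cobinding.cobinding_enrichment(
        targets["CELF1"], targets["MBNL1"], expr_level, n_bins=n_bins)
    _tsv(cb_table, out / "cobinding_bins.tsv")
    summary["cobinding_pooled_ratio"] = cb_summary["pooled_ratio"]

    sites = []
    utr_lengths = {}
    for gene in annotation.genes:
        if gene.utr_type != "tandem":
            continue
        utr_lengths[gene.gene_id] = gene.utr_length
        for protein, clusters in clusters_by_protein.items():
            for region in ("core", "extension"):
                for c in clusters_in_interval(clusters, gene.chrom,
                                              gene.regions[region], gene.strand):
                    seq = clip_mod.cluster_sequence(c, annotation.genome)
                    sense_5p = c.start if gene.strand == "+" else c.end - 1
                    off = max(gene.utr_offset(sense_5p), 0)
                    sites.extend(cobinding.locate_binding_sites(
                        seq, protein, gene.gene_id, cluster_offset=off))
    obs = cobinding.min_distance_distribution(sites, utr_lengths)
    rnd = cobinding.min_distance_distribution(
        sites, utr_lengths, null="random_placement", seed=seed + 30)
    if len(obs["distances"]) >= 2 and len(rnd["distances"]) >= 2:
        shift_test = cobinding.distance_shift_test(obs["distances"], rnd["distances"])
        summary["distance_median_shift"] = shift_test["median_shift"]
        pd.DataFrame([shift_test]).to_csv(out / "distance_shift.tsv",
                                          sep="\t", index=False, float_format="%.6g")
    dist_df = pd.DataFrame({"distance": obs["distances"]})
    _tsv(dist_df, out / "distances_observed.tsv")

    expr_comp = cobinding.expression_comparison_table(gene_counts)
    expr_mz = monotonicity.monotonicity_table(
        expr_comp, time_order, n_perm=int(cfg["monotonicity"]["n_perm"]),
        seed=seed + 31)
    _tsv(expr_mz, out / "expression_mz.tsv")

    # --- rbns -------------------------------------------------------------
    rb_cfg = cfg["rbns"]
    experiments = []
    for i, conc in enumerate(rb_cfg["concentrations"]):
        inp, pull = simulate_rbns_reads(
            annotation.truth.rbns_affinities, concentration=str(conc),
            n_reads=int(rb_cfg["n_reads"]), seed=seed + 40 + i)
        if i == 0:
            io.write_reads_fasta(inp[:1000], out / "rbns_input_head.fa")
            io.write_reads_fasta(pull[:1000], out / "rbns_pulldown_head.fa")
        experiments.append(rbns.make_experiment(inp, pull, condition=str(conc)))
    r0 = rbns.rbns_r(experiments[0])
    classes_df = rbns.classify_kmers(r0)
    _tsv(classes_df.sort_values("R", ascending=False).head(200),
         out / "rbns_top_kmers.tsv")
    aff = annotation.truth.rbns_affinities
    strong = sorted(aff, key=aff.get, reverse=True)[:20]
    inv = rbns.specificity_invariance(experiments, reference_kmers=strong)
    _tsv(inv["pairwise_correlation"], out / "rbns_invariance.tsv")
    summary["rbns_top_kmer"] = str(r0.idxmax())
    summary["rbns_min_pairwise_rho"] = float(
        inv["pairwise_correlation"]["spearman_rho"].min())

    # --- report -----------------------------------------------------------
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report = [
        "# spliceclip pipeline report",
        f"- config hash: `{chash}`",
        f"- seed: {seed}",
        f"- events analysed: {summary['n_events']}"
        f" (monotonic calls: {summary['n_called_monotonic']})",
        f"- CELF1 CLIP clusters: {summary['n_celf_clusters']}",
        f"- top cluster 5mer: {summary.get('top_kmer', 'n/a')}",
        f"- frame-preserved fraction of called exons:"
        f" {summary['frame_preserved_fraction']:.3f}",
        f"- tandem potency (core/extension % per site):"
        f" {summary.get('potency_core_pct', float('nan')):.2f}"
        f" / {summary.get('potency_extension_pct', float('nan')):.2f}",
        f"- ALE potency (% per site): {summary.get('potency_ale_pct', float('nan')):.2f}",
        f"- co-binding pooled observed/expected:"
        f" {summary['cobinding_pooled_ratio']:.2f}",
        f"- top RBNS 6mer: {summary['rbns_top_kmer']}"
        f" (min pairwise rho {summary['rbns_min_pairwise_rho']:.3f})",
    ]
    (out / "report.md").write_text("\n".join(report) + "\n")
    return summary
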