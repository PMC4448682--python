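# spliceclip

Analysis toolkit for studying how RNA-binding proteins — the CELF and MBNL
families in particular — antagonistically control alternative splicing, 3′
UTR isoform choice and mRNA abundance, built around induction time-course
RNA-seq, CLIP-seq binding data and RNA Bind-n-Seq (RBNS) in vitro binding
assays. Everything runs on synthetic data with known ground truth, so every
statistic in the pipeline can be validated against what was planted.

It is intended for computational biologists who want a tested, reusable
implementation of this family of analyses: time-course monotonicity calling
for splicing changes, binding-vs-regulation "RNA maps", per-binding-site
potency models for mRNA down-regulation, co-binding statistics with
randomized nulls, and kmer-level RBNS enrichment.

## The statistics at the core

**Ψ and Bayes factors.** For a two-isoform event with inclusion/exclusion
read counts, Ψ (percent spliced in) has a conjugate posterior
Beta(inc + α, exc + β). For a pair of samples the Bayes factor compares the
two-Ψ model against a shared-Ψ null via the closed-form Beta-binomial
evidence ratio; BF > 5 marks a significant change.

**Monotonicity Z-score.** Over a time course, order the samples and compare
every pair from different time points. With

δ = #{significant ΔΨ > 0, later − earlier} − #{significant ΔΨ < 0},

permuting the sample→time assignment yields a null distribution of δ, and

MZ = (δ − μ) / σ.

|MZ| above a class threshold (cassette exons 1.8, tandem UTRs 1.6,
alternative last exons 1.5) calls an event as monotonically regulated.

**Potency model.** For tandem 3′ UTRs, log(expression change) is modelled as
proportional to n_core·β_core + n_extension·Ψ_extension·β_extension; for ALE
pairs, (n₁·Ψ₁ + n₂·Ψ₂)·β. Least squares with no intercept; coefficients are
reported as percent change per site, (1 − e^β)·100.

**Co-binding and distances.** Shared CELF1/MBNL1 3′ UTR targets are counted
within equal-occupancy expression bins against an independence expectation;
binding-site proximity is tested by a two-sample KS test on nearest
cross-protein motif distances against random-placement and label-shuffle
nulls, with a median-shift confirmation.

**RBNS.** Per-kmer enrichment R = pulldown frequency / input frequency
(pseudocount 1); kmers are classed weak/medium/strong at R Z-scores of
[1,2), [2,3), ≥3; invariance of specificity across competitor
concentrations is summarized by pairwise Spearman correlations of R vectors.

## Worked example

```python
from spliceclip.maps import frame_preservation
res = frame_preservation([3]*124 + [4]*82, background_rate=0.44)
print(res)
# {'n': 206.0, 'n_preserved': 124.0,
#  'fraction_preserved': 0.6019417475728155,
#  'p_binomial': 2.1806676417938837e-06}
```

Of 206 dual-responsive cassette exons, 124 (60%) preserve the translational
reading frame — significantly more than the 44% background rate among
alternative exons (one-sided exact binomial, p ≈ 2·10⁻⁶), the signature of
regulation that shapes protein isoforms rather than transcript levels.

Recovering planted binding-site potencies from the generator:

```python
import pandas as pd
from spliceclip.synthetic import SimulationConfig, simulate_annotation
from spliceclip.utr import fit_potency_tandem

ann = simulate_annotation(SimulationConfig(
    n_genes=500, frac_tandem=1.0, noise_sd=0.2, seed=11))
rows = [{"n_core": ann.truth.site_count(g.gene_id, "core"),
         "n_extension": ann.truth.site_count(g.gene_id, "extension"),
         "psi_extension": float(ann.truth.psi_trajectories[f"{g.gene_id}_UTR"][0]),
         "log_change": ann.truth.log_expression_change[g.gene_id]}
        for g in ann.genes]
fit = fit_potency_tandem(pd.DataFrame(rows))
print({k: round(v, 2) for k, v in fit.percent_per_site.items()})
# {'core': 6.85, 'extension': 0.51}
```

The generator plants 6.9% down-regulation per core site and 2.7% per
extension site (scaled by isoform usage). At noise SD 0.2 the core potency
is recovered precisely (6.85, 95% CI [5.80, 7.88]); the smaller extension
effect is weakly identified at this sample size — its CI is wide — and is
recovered to machine precision when the noise is turned off.

## Command line

```sh
spliceclip simulate --seed 1 --outdir out/        # synthetic dataset
spliceclip run-all  --seed 1 --outdir out/        # every stage + report
spliceclip psi --counts out/splice_counts.tsv --outdir out/
spliceclip mz --comparisons out/comparisons.tsv \
    --time-order out/time_order.json --out out/mz.tsv
spliceclip clip --bed out/clip_CELF1.bed --subs out/clip_CELF1.subs.tsv \
    --out out/clusters.bed
spliceclip maps --indir out/    # RNA map + frame preservation
spliceclip utr --indir out/     # UTR profiles + potency fits
spliceclip cobind --indir out/  # co-binding enrichment + distances
```

`run-all` writes TSV/BED/GFF3/FASTA artifacts plus `report.md` and
`summary.json`, all stamped with the config hash and seed; reruns with the
same config are byte-identical.

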