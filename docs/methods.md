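# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices taken where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Ψ estimation and Bayes factors

Inclusion/exclusion read counts for a two-isoform event are modelled as
binomial draws with success probability Ψ and a Beta(α, β) prior (default
α = β = 1). The posterior is Beta(inc + α, exc + β); the point estimate is
the posterior mean and the interval is the equal-tailed 95% credible
interval. Events with fewer than `min_reads` (default 20) total reads are
skipped with a logged reason, never silently dropped.

The Bayes factor for a change in Ψ between two samples is the Beta-binomial
evidence ratio of the model with independent Ψ per sample against the
shared-Ψ model. Binomial coefficients are identical under both models and
cancel, so the ratio is computed from log-Beta functions only; it is exact,
needs no Monte Carlo, and is capped at 10¹² (flagged) to avoid numerical
infinities at extreme counts. This conjugate model is a declared
simplification of full MCMC isoform inference: downstream statistics consume
only the BF > 5 indicator, the sign of ΔΨ and the posterior means, for which
the two-model evidence ratio is sufficient. Read-to-isoform assignment
ambiguity is not modelled; counts arrive pre-assigned.

A calibration property is enforced by test: with a shared Ψ drawn from the
prior and paired binomial counts at depth 50, P(BF > 5) < 0.1; with a true
ΔΨ of 0.3 at depth 200, P(BF > 5) > 0.9.

## Monotonicity statistic

For one event, all unordered pairs of samples are compared. The observed
statistic counts only pairs from different time points, oriented
later-minus-earlier:

    δ = #{BF > 5 and ΔΨ > 0} − #{BF > 5 and ΔΨ < 0}.

Significant comparisons with ΔΨ exactly zero enter neither tally. The null
permutes the sample→time assignment uniformly (without replacement from the
label multiset) and recomputes δ; MZ = (δ − μ)/σ from the permutation mean
and SD. Implementation detail: with M the antisymmetric matrix of signed
significance indicators over sample pairs, δ(τ) = ½·Σᵢⱼ Mᵢⱼ·sign(τⱼ − τᵢ),
which vectorizes over permutations.

Design choices:

- **Joint vs within-replicate permutation.** The default dissolves
  replicate structure and permutes all samples jointly — the
  maximal-entropy exchangeable null. A within-replicate mode
  (`replicate_of=`) permutes time labels only within each replicate line,
  for designs where replicate lines differ systematically.
- **Degenerate nulls.** If the null SD is zero (no comparison significant
  under any labelling), MZ is set to 0 and flagged `degenerate_null`; such
  events are never called.
- **Exact mode.** `method="exhaustive"` enumerates all distinct assignments
  of the time-label multiset; it is the reference for correctness tests at
  small sample counts. Sampled mode uses the study design's 100
  permutations by default (SD with ddof = 1; the exhaustive mode uses the
  full-population SD).
- **Thresholds are strict** (BF > 5, |MZ| > threshold), so a score exactly
  at the threshold is not called. Class defaults: cassette exons 1.8,
  tandem UTRs 1.6, ALEs 1.5; all configurable.

The permutation null makes MZ conservative at low depth: with nothing
significant under any labelling the event is flagged rather than scored.
Type-I calibration (the fraction of constant-Ψ events called at
|MZ| ≥ 1.8 over 2 000 events) is computed by the acceptance script.

## CLIP analysis

Reads are collapsed by identical mapped sequence — same coordinates, strand
and substitution profile. Clusters are maximal per-strand runs of per-base
coverage ≥ `min_height` (default 3), merging runs separated by ≤ `max_gap`
(default 0) sub-threshold bases. These parameters are package defaults, not
literature values, and are exposed in the config.

Pentamer enrichment compares kmer frequencies in cluster sequences to
`n_resample` (default 100) resamples of length-matched control regions drawn
from the same 3′ UTR universe; Z = (f_cluster − mean f_control)/SD f_control.
Kmers absent from every resample are flagged `zero_variance` with Z = 0.
A stratified-matching helper (`stratified_match`) draws control sets matched
on expression and length quantile strata.

Crosslink-induced substitutions (CIS): for each strand-specific position
covered by ≥ `min_cov` reads (default 10), the CIS frequency is the fraction
of covering reads carrying a substitution there. Guanine positions (in
transcript sense; complemented on the minus strand) are binned by CIS
frequency, and for each bin the genomic base composition at sense offsets
−5…+5 is tallied; information content is the relative entropy against the
uniform base distribution, in bits. The generator plants crosslinks at the
central G of UGU contexts, so the top CIS bin should show a U bias at −1 —
the property the tests assert.

Density profiles use read 5′-end (sense start) counts, not coverage, with a
pseudocount of 1 before log for the between-sample Pearson correlation in
5-nt windows; windows empty in both samples are excluded. Note that this
correlation is only meaningful at reasonable density — at ≪1 read per
window, excluding double-zero windows induces spurious negative
correlation, so callers should restrict to expressed regions. Meta-density
profiles support three anchors: length-normalized UTR bins, PAS-relative
offsets and splice-site-relative offsets, with a bootstrap 95% band over
regions.

All coordinates are 0-based half-open internally; BED output stays 0-based,
GFF3 output is 1-based inclusive.

## RNA maps and cross-perturbation comparisons

An event is "repressed" iff its endpoint posterior-mean Ψ (replicate
average) is below the control average. The binding-vs-repression table
tests, at each MZ threshold, the bound group's repressed count against the
unbound group's repressed fraction as the null rate (binomial). Overlap
enrichment across perturbations uses the independence expectation
|U|·(|A|/|U|)·(|B|/|U|); direction concordance is an exact two-sided
binomial test against 0.5 with zero-ΔΨ events excluded; frame preservation
(length divisible by 3) is tested one-sided (greater) against a supplied
background rate, following the directional claim it supports. Raw p-values
are reported without multiple-testing correction, matching how such tables
are conventionally read; a BH column can be added at the report level
without affecting calls.

## 3′ UTR isoform analysis and potency model

Tandem-UTR events expose a core region (shared by both isoforms) and an
extension (distal-PAS isoform only); ALE events expose two mutually
exclusive last exons. Isoform shifts are summarized as the change in the
distal-isoform fraction; per-bin proximal-shift fractions are tested against
0.5 by exact binomial, with bins under 3 events flagged.

The potency model is fit by least squares with **no intercept** — the model
is stated as proportional; an intercept option exists for robustness
checks. Covariates use the **control-condition** isoform fractions, the
reading under which site exposure precedes regulation. "log expression
change" is the natural log of endpoint/control mean normalized expression,
so percent-per-site conversions use (1 − e^β)·100 and round-trip exactly.
Rank-deficient designs (e.g. all-zero site counts) raise an error naming the
offending columns. Confidence intervals come from the OLS standard errors;
their 90%+ empirical coverage at noise SD 0.2 is verified by simulation in
the acceptance suite. Expression normalization across samples uses
median-ratio size factors (geometric-mean reference), a deliberate
simplification of trimmed-mean scaling; with a handful of samples from one
protocol the two agree closely.

Cluster-density bins for dose-response displays are {0, (0,1], (1,2],
(2,4], >4} clusters per kb of UTR.

## Co-binding analysis

Binding sites are located by scanning cluster sequences for the known DNA
4mer motif sets (CELF1: TGTT, ATGT, TTGT, TGTC, GTGT, TGTA, GTTT, TGTG,
GTCT, TTTT; MBNL1: GCTT, CGCT, TGCT, GCGC, CCGC, CTGC, GCTA, ACGC, CGCA,
AGCT, TTGC, CAGC), case-insensitively on the sense strand of the mature
transcript; a cluster with no motif yields one site at its midpoint
(`cluster_center`).

Co-target enrichment bins genes into equal-occupancy expression bins
(default 10 — the bin count is a package choice) and compares the observed
number of shared targets per bin to n·(a/n)·(b/n); the pooled ratio is the
mean of per-bin ratios (empty-expectation bins skipped) and significance is
Fisher's exact test on the pooled 2×2 table. Target sets require at least 2
clusters per factor by default.

Distances are measured in nucleotides between site point coordinates along
the UTR. Two poolings are provided: one nearest-opposite-protein distance
per site (default — note each mutually-nearest pair then contributes twice)
and one minimum per UTR. Two nulls: uniform re-placement preserving
per-protein site counts, and protein-label shuffling over fixed positions.
The "modified KS" of the source analyses — a KS test plus visual
confirmation of the median shift — is operationalized as requiring
KS p < α *and* median(observed) < median(null) for a proximity call.
Because the two-sample KS p-value is discrete, its null distribution is
only near-uniform for large samples with few ties; calibration checks use
the per-UTR-minimum pooling (independent units) at several hundred UTRs.

For gene-expression monotonicity (expression standing in for Ψ), the
pairwise significance indicator is a fold change ≥ 1.2 together with a
binomial test of the two read counts against an equal split — a declared,
configurable convention, since no Bayes factor is defined for expression.

## RBNS

R(kmer) = pulldown frequency / input frequency with pseudocount 1 on counts.
Z-score bands for classes are half-open ([1,2) weak, [2,3) medium, [3,∞)
strong), resolving the ambiguity of prose band edges; k = 6 by default.
Specificity invariance across competitor concentrations reports pairwise
Spearman correlations of R vectors over all 4^k kmers plus per-kmer relative
changes for a supplied reference set (flagged above 10% by default).
Kmer counting takes a vectorized path (integer-coded windows + bincount)
for equal-length N-free reads and a dictionary fallback otherwise.

## Synthetic-data generator

The generator emulates the study conditions the analyses assume; its
defaults are the conditions, not tuning knobs.

- **Design.** Three replicates at each of a control point and four
  post-induction time points (0h, 12h, 24h, 72h, 7d); arbitrary ordinal
  designs are supported.
- **Genes.** Each gene has a cassette exon and either a tandem-UTR pair or
  an ALE pair (50/50 by default); transcript sequences are random with
  planted motifs — the analyses need motif/interval structure only, which
  removes any dependence on a reference genome. Strands are assigned at
  random (half minus by default); all coordinates are 0-based half-open.
- **Binding.** CELF sites are planted as TGTT (carrying the UGU crosslink
  context), MBNL sites as GCTT. Target status is drawn jointly so that
  CELF/MBNL co-targeting occurs at 3× the independence expectation
  (target probability 0.25 per factor — a 3× overlap is only feasible when
  the rates are below 1/3). Half of co-bound UTRs get one proximal pair
  (MBNL site within 30 nt of a CELF site).
- **Splicing.** A configurable fraction of events (default 0.5) is
  monotone; trajectories interpolate linearly between a uniform control Ψ
  and a shifted endpoint, clipped to [0.02, 0.98]; exonically CELF-bound
  cassette exons are repressed in 82.5% of regulated cases (the middle of
  the 80–85% band the RNA-map analysis expects); extension-dominant tandem
  binding shifts usage proximal in 75% of regulated cases. Non-monotone
  events have constant Ψ, which makes them an exact null for MZ
  calibration.
- **Expression.** log(change) follows the potency model with per-site
  percent effects 6.9 (core), 2.7 (extension) and 5.9 (ALE), plus gene-level
  Gaussian noise (SD 0.2 by default; a lognormal count model was chosen as
  the observation layer since none is prescribed). Per-sample counts are
  lognormal around a baseline of e^log(1000) with measurement SD 0.05, and
  the change interpolates linearly over the time course.
- **CLIP.** Reads (30 nt) are drawn around planted sites with a uniform
  background fraction (default 0.2); the central G of each planted UGU
  carries a substitution with probability 0.3, any position with
  probability 0.01; identical duplicates are emitted at rate 0.1 to
  exercise collapsing.
- **RBNS.** Input reads are i.i.d. uniform 40mers; pulldown reads are
  resampled with weight 1 + Σ affinity·occurrences. The CELF affinity
  spectrum is graded — 1.5 per UGU occurrence plus 0.25 per GU, with a
  +2 bonus for UGUUGU — because single-protein selection enriches a
  continuum of GU-rich kmers, not a handful of spikes; a graded spectrum is
  also what makes rank invariance across conditions measurable. The
  competitor-concentration label is metadata only and does not alter
  weights, encoding the independence of CELF binding from MBNL the assay
  reports. A chunked count-only path (`simulate_rbns_counts`) serves the
  large library sizes where per-kmer sampling error must be small.

What the generator does **not** emulate: sequencing error, alignment
artifacts, junction-read ambiguity, real genome composition, isoform
structures beyond two isoforms per event, or biological covariance between
expression level and binding. Passing tests therefore demonstrate
correctness of the statistics under the stated model, not robustness to
real-data pathologies upstream of these inputs.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make each
statistical claim decidable: 2 000 events for MZ calibration; 500 genes ×
200 replicates for potency CI coverage; 2 000–4 000 genes for the planted
co-binding ratio (SD of the pooled ratio ≈ 0.1–0.15); 200 runs × 500 UTRs
of 10 kb for distance-null calibration (integer positions on short UTRs
produce enough KS ties to distort the p-value lattice). For the RBNS null
check, the per-kmer sampling SD of R is ≈ √(2/c) at c counts per kmer, so
the maximum over 4 096 kmers only falls inside a ±5% band once libraries
reach a few million reads; 3.5 M reads (~1.2·10⁸ kmer tokens) are used.
Invariance correlations use 2 M reads per condition for the same reason.

Seeds: every generator and permutation consumes an explicit seed or a
`SeedSequence`-derived child, so pipeline reruns are byte-identical.

## Known limitations

- The cluster caller has no statistical peak model (no local background
  p-values); `min_height` is a hard threshold.
- The Beta-binomial BF ignores isoform-assignment uncertainty and will be
  overconfident if counts are mis-assigned upstream.
- The pooled distance distribution double-counts mutually-nearest pairs in
  the default mode; the per-UTR-minimum mode avoids this at the cost of
  discarding within-UTR structure.
- Median-ratio scaling assumes most genes unchanged; under global shifts
  (many strong targets) potencies are estimated relative to the typical
  gene.
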