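# Methods

This note documents the statistical models implemented in `lncstrat`, the
design of the synthetic cohort generator, the defaults that matter, and
the numerical choices made where more than one reasonable option existed.
It states nothing that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential expression

### Model

For gene *g* with log2-CPM vector `y_g` over n samples and design matrix
`X` (n × p, full column rank), the model is generalized least squares

    y_g = X beta_g + e_g,
    Var(e_g) = sigma_g^2 . W_g^{-1/2} R(rho) W_g^{-1/2}

* `W_g` — per-observation precision weights. Per gene, the residual
  standard deviation from an ordinary fit is quarter-root-transformed
  (`s_g^{1/2}`) and regressed on mean log2-CPM by lowess (span 0.5); the
  weight of each observation is the trend prediction at its fitted value,
  raised to −4, with predictions clamped to the trend's x-range at the
  extremes and floored away from zero. This is the classical
  mean–variance-trend weighting for log-counts; it assumes the trend is a
  smooth function of abundance only.
* `R(rho)` — block equicorrelation: observations from the same patient
  share one consensus correlation rho, zero across patients. This encodes
  that a patient contributes an initial-diagnosis (ID) and a relapse (REL)
  sample with a shared expression profile.

Counts are transformed as `log2((count + 0.5) / (eff_lib + 1) * 1e6)`.
Effective library sizes are column sums multiplied by TMM normalization
factors (doubly trimmed, precision-weighted mean of per-gene log-ratios
against a reference sample; trims 30% on M, 5% on A). TMM matters here:
when differential expression is asymmetric — up-shifts of 2 log2 units add
four-fold counts while down-shifts remove at most one-fold — plain CPM
transfers the compositional shift onto *every* null gene as a spurious
fold change; with 10% of genes perturbed this measurably inflates the
p < 0.01 tail (observed up to 2× nominal) and TMM removes it.

### Duplicate correlation

The consensus rho is estimated once, on all genes. Per gene, weighted
least-squares residuals `e = M y_w` (with `M = I − H` the residual
projector) have covariance `sigma^2 M R M`, so the naive estimator
"mean within-patient residual product / residual variance" is biased
downward by roughly p/n (with p = 3 coefficients and n = 20 samples the
bias swamps a true rho of ~0.15). The implementation therefore solves the
two moment equations

    mean_pairs e_i e_j = sigma^2 (a0 + rho a1)
    mean_i    e_i^2    = sigma^2 (d0 + rho d1)

for rho, where a0/a1/d0/d1 are means of `M` and `M B M` over within-patient
pairs and the diagonal (`B` = within-block indicator). Per-gene estimates
are clipped to (−0.99, 0.99), Fisher-z transformed, combined by a 15%
trimmed mean, and transformed back. Known limitation: a *single* consensus
rho under-corrects genes whose intra-patient correlation is far above the
consensus (high-abundance genes) and over-corrects the opposite tail; with
very few patients this leaves a residual tail inflation that no consensus
model can remove.

### Moderation and calling

Each gene is whitened by the Cholesky factor of `R(rho)` after weighting
and fitted by least squares. Residual variances are shrunk by empirical
Bayes with an inverse-gamma prior whose hyperparameters `(d0, s0^2)` are
moment-matched on `log s_g^2` (trigamma inversion by Newton iteration);
`s_post^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)`, and the contrast t-statistic
uses `d0 + d_g` degrees of freedom (normal reference when `d0` is
infinite). Passing `prior_df=0` recovers the ordinary GLS t exactly, which
the tests use as a closed-form oracle.

Genes are called differentially expressed at raw p < 0.01 **and**
|log2FC| >= log2(1.5). The fold-change bound is interpreted on the linear
scale; BH-adjusted q-values are reported alongside but not thresholded.
Before fitting, genes must have FPKM > 0 in at least one sample (when FPKM
is supplied) and total count >= 10.

Subtype contrasts are one-vs-rest with an intercept, a subtype indicator
and a REL indicator (the timepoint covariate keeps relapse shifts out of
the subtype coefficient); relapse contrasts are REL-vs-ID within one
subtype. Both block on patient; blocking is dropped automatically when
every patient contributes a single sample. Note that one-vs-rest contrasts
are not mutually exclusive: a gene strongly shifted in subtype A also
shifts the "rest" group of subtype B's contrast, so a gene can genuinely
be called in more than one subtype.

## Differential methylation

Beta values are clamped to [0.001, 0.999] and logit-2 transformed to
M-values. Only the most variant quartile of probes (exactly ceil(n/4)
rows, ties broken by row order) enters detection — variance filtering at
this ratio roughly halves the multiplicity burden while keeping any probe
with a group shift comparable to the noise SD.

Per probe, the M-value is regressed on the subtype-vs-rest indicator; the
coefficients are smoothed within probe clusters (same chromosome,
inter-probe gaps <= 500 bp) by a centered 3-probe running mean that never
crosses a cluster boundary (clusters shorter than the window stay
unsmoothed). A running mean replaces the loess smoother of the classical
method because synthetic clusters are short and dense; the window is
configurable.

The candidate cutoff is the 0.95 quantile of |smoothed coefficient| pooled
over B label permutations (group sizes preserved). Candidate regions are
maximal same-sign runs above the cutoff; the region statistic is the area
(sum of |smoothed coefficients|). Two permutation p-values are reported:

* `p_perm` (primary) — family-level: `(1 + #{permutation max areas >=
  area}) / (1 + B)`. Because the observed area is referred to the
  distribution of the *per-permutation maximum*, the chance that any
  fully-null dataset yields a region with `p_perm <= alpha` is ~alpha;
  the measured family-wise false-positive fraction over 50 null runs is
  0.02–0.06 at alpha = 0.05.
* `p_area` — pooled tail over all null candidate areas. This per-region
  quantity does not control the family-wise rate (with k candidate regions
  the any-region rate is ~1 − 0.95^k) and is reported for compatibility
  with pooled-inference conventions.

Significant regions (`p_perm <= 0.05`) are classified on the beta scale:
hyper-methylated when the group difference is >= 0.2, hypo-methylated when
<= 0. The thresholds are deliberately asymmetric; differences in (0, 0.2)
are reported as `unclassified`. Regions are annotated at their midpoint:
promoter-TSS (± 2 kb of the TSS, taking precedence), exon, intron, TTS
(± 2 kb of the termination site), or intergenic, with ties across genes
broken by TSS distance then gene id.

## Guilt-by-association

cis partners of a lncRNA are protein-coding genes whose TSS lies within
100 kb of the lncRNA TSS (TSS-to-TSS distance, boundary inclusive); trans
partners are farther but on the same chromosome (other chromosomes are
excluded — an unbounded trans definition would make every gene a
candidate). Pearson correlation is computed on log2(FPKM + 1) across all
cohort samples; the log stabilizes the heavy right tail of FPKM (raw-scale
correlation is available). Partner selection is one-sided positive
(r >= 0.55, p <= 0.05) by default, reflecting that co-expressed partners
skew positive; `absolute=True` admits |r| >= 0.55.

Enrichment of the selected partners in a gene set is the hypergeometric
upper tail P(X >= hits) with the all-protein-coding background; it is
computed by exact integer arithmetic (big-integer binomial sums) for
populations up to 2000, so it matches exhaustive enumeration to
floating-point rounding, with a log-gamma fallback above that. Enrichment
p-values are not multiplicity-corrected (BH q reported alongside);
pathway tables additionally require > 2 hit genes.

## Integration

An epigenetically altered lncRNA must be, in the same subtype, (i)
promoter-DM, (ii) DE, and (iii) significantly correlated between its
per-sample promoter methylation — mean beta over the region's probes,
log2-transformed after clamping at 0.001 — and log2(FPKM + 1). Any
correlation sign is retained at p <= 0.05; a `concordant` flag marks
hypo & up or hyper & down, rather than hard-filtering on sign, so
discordant couplings remain visible.

Chromatin-state enrichment: an intronic/intergenic DM lncRNA is "marked"
if its DM region overlaps >= 1 bp of an Enhancer or Insulator segment;
background lncRNAs (tested, not DM) are marked through their gene span,
since they have no DM region. The 2×2 table is tested with a two-sided
Fisher exact p by fixed-margin enumeration with exact integer weights —
tie handling is therefore deterministic, with no floating-point tolerance.

## Stratification

PCA is the SVD of the sample-by-gene matrix of log2(FPKM + 1), centered
per gene, unscaled (raw-FPKM PCA is dominated by a few high expressors).
Signature clustering z-scores each gene (sample SD; zero-variance rows
become zero and are flagged), computes sample–sample distances
1 − Spearman rho, and applies average linkage — the standard pairing with
correlation distances; the linkage method is configurable. Validation on
an external cohort subsets to the signature genes present (error below
50%), re-clusters at k, maps clusters to subtype labels by majority vote
(ties resolved deterministically toward the earlier label), and reports
per-subtype sensitivity and specificity.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with machine-readable planted truth:

* **Cohort structure** — default 45 patients, 37/45 paired ID/REL, in
  subtype groups (DUX4 12, Ph-like 11, NH-HeH 9, LH 3, Other 10).
  Unpaired patients alternate timepoints deterministically.
* **Layout** — one synthetic chromosome `chrS`; each lncRNA locus carries
  a protein-coding gene 30–60 kb from the lncRNA TSS (a guaranteed cis
  partner) and loci are 250 kb apart (everything else is trans). Probes
  tile each lncRNA promoter (6 probes, 350 bp spacing), gene body (4
  probes at the midpoint) and flanking intergenic space; a 5-state
  chromatin segmentation covers the chromosome in 10 kb bins.
* **Expression** — negative-binomial counts (gamma–Poisson, dispersion
  0.2) around gene baselines drawn at log2 mean 3.0 for lncRNAs vs 5.5
  for protein-coding genes (SD 1.2) — lncRNAs are systematically lower
  expressed. Planted subtype/relapse effects act multiplicatively. The
  patient random effect is a gene-specific per-patient profile
  (SD 0.3, shared by the patient's ID and REL samples); a gene-independent
  per-sample factor would cancel exactly under CPM normalization and leave
  nothing for duplicate correlation to recover. FPKM = counts /
  (exonic length in kb × library size in millions), library size = column
  sum.
* **Methylation** — logit-normal betas per probe (baseline beta uniform
  0.3–0.7, logit2-scale noise SD 0.5); planted DMRs shift the target mean
  beta of the first n probes of a region in the subtype's samples.
* **Epigenetic coupling** — a coupled lncRNA's log2 expression mean gains
  `sign × strength × (M − mean M)` where M is its *realized* per-sample
  promoter M-value (methylation is simulated first); sign −1 is
  methylation-repressed, the canonical promoter pattern.
* **Planted baselines** — planted DE lncRNAs (+1.5) and coupled lncRNAs
  (+2.0) receive log2 baseline offsets in the demo truth. Without them a
  planted lncRNA can randomly land below ~2 mean counts, where the count
  floor makes a planted down-regulation or coupling unobservable *by any
  method*; the truth being emulated is a detected, signature-grade lncRNA.
* **Determinism** — all randomness flows from the single spec seed through
  named `numpy` generators; identical seeds give byte-identical output
  files.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: GC/length biases and mappability, isoform
mixtures, batch effects, cell-composition effects on methylation,
correlated probe noise beyond the planted regions, realistic linkage
between chromatin states and methylation, and outlier samples. Effect
sizes and planted fractions are chosen for testability: 10% of genes carry
planted subtype effects in the recovery benchmarks, matching the ~9%
subtype-specific fraction such analyses report, and demo effects
(|log2FC| 2–2.5, beta shifts 0.3) sit well above the noise floor.

## Validation benchmarks

`lncstrat.benchmarks` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) fixes the problem sizes: 2000 genes with
20 + 20 independent samples for null calibration; 2000 genes, 10
independent samples per group, 10% planted at |log2FC| = 2 for recovery;
20 paired patients for duplicate-correlation recovery; 205 probes
(41 five-probe clusters), one planted cluster at logit shift 1.5, B = 200
and 50 null repetitions for DMR detection; 100 repetitions for the
epigenetic null gate; demo-scale cohorts (3 × 10 patients, 240 genes,
960 probes) for integration, stratification and the end-to-end demo. The
DE calibration/recovery cohorts use independent samples (one per patient)
because those benchmarks isolate the moderated test itself; the paired
design and its consensus-correlation estimator are benchmarked separately.
These sizes keep every benchmark in seconds on one CPU while leaving the
pass/fail margins dominated by statistics, not scale.

## Known limitations

* The consensus-rho model assumes one intra-patient correlation for all
  genes; heterogeneous per-gene correlation leaves residual tail
  mis-calibration in heavily blocked, small-n designs.
* Family-level DMR inference (`p_perm`) is conservative for secondary
  regions in a dataset that contains one dominant region.
* One-vs-rest DE contrasts are not subtype-exclusive by construction;
  consumers wanting exclusive markers must intersect across contrasts.
* The hypergeometric/Fisher exact paths switch to log-gamma approximations
  above population 2000; agreement with enumeration is then ~1e-13
  relative rather than exact.
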