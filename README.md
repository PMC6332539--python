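# lncstrat

Stratification of leukemia cohorts by long non-coding RNA (lncRNA)
expression and DNA methylation.

`lncstrat` implements the integrative analysis used to define
**subtype-specific**, **relapse-specific**, and **epigenetically altered**
lncRNAs in B-cell precursor acute lymphoblastic leukemia (BCP-ALL)-like
cohorts: paired initial-diagnosis (ID) and relapse (REL) bulk RNA-seq and
Illumina 450k-style methylation samples from patients grouped into
molecular subtypes (e.g. DUX4, Ph-like, NH-HeH). It is aimed at
computational biologists who want each stage of that analysis as a tested,
reusable component — and who need to *verify* the stages without access to
patient data, which is why the package ships a synthetic-cohort generator
with machine-readable planted ground truth.

## What it computes

**Differential expression** (`lncstrat.diffexp`). Per gene *g*, a
precision-weighted linear model on log2-CPM with blocked errors:

    y_g = X beta_g + e_g,   Var(e_g) = sigma_g^2 W_g^{-1/2} R W_g^{-1/2}

where `W_g` are voom-style weights from the empirical mean–variance trend
of log-counts, and `R` is block-equicorrelated — samples of the same
patient share a consensus correlation rho ("duplicate correlation"),
estimated once across genes by a bias-corrected moment estimator on
residual cross-products. Residual variances are shrunk by inverse-gamma
empirical Bayes, `s_post^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)`, and
contrasts tested with moderated t on `d0 + d_g` df. Library sizes carry
TMM normalization factors. Subtype contrasts are one-vs-rest with a
timepoint covariate; relapse contrasts are ID-vs-REL within a subtype.
Calls use p < 0.01 and |fold change| >= 1.5.

**Differential methylation** (`lncstrat.diffmeth`). Bump hunting on
M-values (`log2(beta/(1-beta))`, beta clamped to [0.001, 0.999]) over the
most variant quartile of probes: per-probe group coefficients, a 3-probe
running-mean smoother within probe clusters (gaps <= 500 bp), a cutoff at
the 0.95 quantile of the pooled permutation distribution, and
family-level inference of the region area statistic against per-permutation
maximum null areas (B = 1000 by default). Regions are classified
hyper-methylated (beta difference >= 0.2) or hypo-methylated (<= 0) at
p <= 0.05, and annotated as promoter-TSS (+/- 2 kb of the TSS), gene body,
or intergenic.

**Guilt-by-association** (`lncstrat.gba`). Differentially expressed
lncRNAs are correlated (Pearson, log2(FPKM+1)) with cis (TSS distance
<= 100 kb) and trans (> 100 kb, same chromosome) protein-coding genes;
partners with r >= 0.55 and two-tailed p <= 0.05 feed a hypergeometric
gene-set enrichment against the all-protein-coding background.

**Integration** (`lncstrat.integration`). Epigenetically altered lncRNAs =
promoter-DM ∩ DE ∩ significant methylation–expression correlation, with a
concordance flag (hypo & up, or hyper & down). Intronic/intergenic DM
lncRNAs are tested for Enhancer/Insulator chromatin-state overlap with a
two-sided Fisher exact test (exact fixed-margin enumeration).

**Stratification** (`lncstrat.stratify`). PCA, per-gene z-scoring,
hierarchical clustering on 1 − Spearman rho with average linkage, and
validation of a DE signature on an independent cohort (majority-vote
cluster-to-label mapping, per-subtype sensitivity/specificity).

## Worked example

```python
from lncstrat.pipeline import demo_spec
from lncstrat.synthetic import make_annotation, simulate_cohort
from lncstrat.diffexp import DEModel

spec = demo_spec(seed=0)              # 3 subtypes x 10 patients, planted truth
ann = make_annotation(spec)
cohort = simulate_cohort(spec, ann)
res = DEModel.from_cohort(cohort.counts, cohort.samples,
                          "subtype", "DUX4", fpkm=cohort.fpkm).fit()
print(res.summary())
```

prints

```
Moderated differential expression: DUX4 vs rest
  genes tested:        240
  residual df:         51
  prior df (d0):       16.6
  prior variance s0^2: 1.063
  consensus rho:       0.177
  called (p<0.01, |FC|>=1.5): 54 (24 up, 30 down)
```

`consensus rho` is the recovered intra-patient correlation (the generator
plants a patient random effect of SD 0.3 on top of counting noise); the
54 called genes contain the 16 lncRNA + protein-coding pairs planted with
|log2FC| = 2.5 in the DUX4 group. The bump-hunting stage on the same
cohort reports:

```
Bump-hunting DMRs: DUX4
  probes analyzed:   240
  permutations (B):  200
  cutoff (q=0.95): 0.4738
  candidate regions: 15
  significant (p<=0.05): 8 (2 hyper, 4 hypo)
```

which recovers the promoter/body/intergenic regions planted for DUX4 with
beta shifts of +/- 0.3.

The same thing end-to-end from a shell, including a truth-recovery report
(`truth_recovery.json`) that asserts DE sensitivity/FDR, DMR recovery,
epigenetic-coupling recovery, and perfect stratification of an independent
validation cohort:

```sh
lncstrat demo --out demo_run --seed 0
```

Per-stage subcommands (`lncstrat simulate / de / dm / gba / stratify /
run`) operate on plain TSV/GTF/BED/GMT files; `lncstrat run --config
cfg.yaml --out DIR` executes the whole pipeline on existing inputs and
writes a provenance manifest (input hashes, seed, thresholds) next to the
outputs.

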