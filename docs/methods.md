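# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults that matter, and the numerical choices where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed throughout

A paired stimulation design: the same donors are profiled once
unstimulated (CTRL) and once per stimulus. Genotypes are alt-allele
dosages (0/1/2) from a single array-typed cohort; expression is bulk
RNA-seq counts per condition. All condition comparisons are
control-versus-one-stimulus.

## Variant QC

Filters are strict inequalities: MAF > 0.05, call rate > 0.97, HWE
p > 1e-4 at the array stage; MAF > 0.05 and HWE p > 1e-6 at the eQTL
stage. The HWE test is the exact conditional test: given the observed
allele counts, the heterozygote count follows

P(h) ∝ n! / (n_hom_rare! · h! · n_hom_common!) · 2^h,

and the two-sided p-value is the total probability of all heterozygote
counts whose probability does not exceed the observed one (probability
ordering, with a 1e-10 relative tolerance for floating-point ties). A
chi-square test would misbehave at low minor-allele counts; the exact
test is standard for array QC and is verified against a full-enumeration
oracle in rational arithmetic. Removals are attributed to the first
failing filter in the order MAF → call rate → HWE, so the report's
counts sum to the input count.

Missing dosages are mean-imputed per variant before PCA and the eQTL
scan; this preserves sample count and is adequate at the high call rates
the QC enforces.

## Expression outlier QC

For each control/stimulus pair, pooled samples are reduced to the top two
PCs of centred log-CPM and modelled with a two-component full-covariance
Gaussian mixture (k-means initialisation, fixed seed; samples are
canonically sorted first so the result is order-invariant). Two rules
flag a sample:

* **low-density tail**: squared Mahalanobis distance to every mixture
  component beyond the chi-square(2) quantile at 1 − q, default
  q = 0.001. A model-based contour is used rather than an empirical
  quantile of sample densities because the empirical variant always
  flags the minimum-density sample even in clean data.
* **cluster/condition mismatch**: each condition's dominant cluster is
  the one holding most of its samples; a sample assigned elsewhere does
  not fit the design.

Degenerate inputs (zero variance across samples) return no outliers.
Whether flags are applied per condition pair or globally is the caller's
choice; the pipeline applies them per pair.

## Differential expression

TMM scaling factors follow the trimmed-mean-of-M-values recipe: reference
sample = the one whose upper quartile of depth-scaled counts is closest
to the mean upper quartile; 30% two-sided trim on M, 5% on A; inverse
asymptotic-variance weights; factors normalised to unit geometric mean.
log₂-CPM uses a 0.5 prior count scaled per sample by effective library
size, which makes log-CPM exactly depth-invariant for proportional
samples. Genes need CPM ≥ 1 in ≥ 20% of samples by default.

Per-gene linear models are fitted on log-CPM with an intercept, the
condition indicator and any covariates. Residual variances are moderated
by empirical Bayes: the prior degrees of freedom d0 and prior variance
s0² are estimated by matching the moments of log sample variances
(inverting the trigamma function by Newton iteration), the posterior
variance is (d·s² + d0·s0²)/(d + d0), and the moderated t has d + d0
degrees of freedom (normal when d0 = ∞). This is the moderated-t on
log-CPM; precision weighting of individual observations (the "voom"
weights) is deliberately not applied — a documented divergence that
matters mainly at very low counts. A spot-check against the R reference
implementation on a shared fixture gave identical log-fold changes and
moderated t within 0.01.

DEG significance is strict: adjusted p < 0.05 AND |log₂FC| > 1.5. Genes
are "specific" when significant in exactly one stimulus and "common" when
significant in two or more (a flag switches to the all-stimuli rule).
ORA is the hypergeometric upper tail P(X ≥ overlap) with BH across sets;
the default universe is the set of genes surviving the expression filter.
GSEA uses the weighted Kolmogorov–Smirnov running sum (hits weighted by
|score|^w normalised over hits, misses by 1/(N−Nh)), a gene-label
permutation null, NES normalised by the mean same-sign permutation
magnitude, and BH across sets.

## cis-eQTL mapping

Expression preparation: filtering as above, then a rank-based
inverse-normal transform per gene, Φ⁻¹((r − 0.5)/n) with average ranks
for ties, then residualisation on an intercept, sex, the top genotype
PCs (default 3) and the top PCs of the transformed expression matrix.
Expression PCs stand in for latent-factor methods (PEER-style hidden
confounder capture); the count is a configuration knob, default 15 for
data of a few hundred samples and set lower in the pipeline's desk-scale
runs. Collinear covariates raise an error.

The scan is two-stage: covariates are projected out once, then each gene
is regressed on each cis variant (|pos − TSS| ≤ 1 Mb, inclusive, signed
distance pos − TSS) by simple regression. This is O(genes × variants)
and matches the common single-pass scan strategy; by default the t-test
degrees of freedom are reduced by the number of projected covariates
(configurable).

Gene-level calibration: the expression vector is permuted; each
permutation records the minimum nominal p over the gene's cis variants.
1,000 permutations are run first; if fewer than 10 minima reach the
observed minimum, the pass continues to 10,000 (an adaptive 1,000–10,000
scheme). A Beta(a, b) distribution is fitted to the permuted minima by
maximum likelihood (Nelder–Mead on log-shape parameters,
method-of-moments initialisation, moment estimates as fallback), and the
adjusted p is the beta CDF at the observed minimum. The direct
plus-one-rule permutation p, (1 + #{perm ≤ obs}) / (1 + n_perm), is
reported alongside. With a single cis variant the minima are uniform and
the fitted beta approaches Beta(1, 1); the beta-vs-direct agreement is
checked at 10,000 permutations, where the fit's CDF error is within
0.01 (at 1,000 permutations the sampling error of the fit itself is
~0.02–0.03).

Gene-level q-values default to BH across genes, which is robust at the
small gene counts of desk-scale runs; Storey's π₀ correction (estimated
at λ = 0.5) is available behind a flag — a documented divergence from
the q-value convention of the reference permutation tool.

Per-gene permutation streams are keyed by (seed, CRC32(gene id)), so
results are independent of gene processing order and reproducible
gene-by-gene.

## e²QTL

For each condition pair, the top variant per gene is the one with the
smallest nominal p across the two conditions (ties: smaller |distance to
TSS|, then lexicographic variant id; control-only and stimulus-only
selection modes exist because the source convention is ambiguous). The
test is z = (β_stim − β_ctrl)/√(se²_stim + se²_ctrl), two-sided normal,
Bonferroni-corrected with n_tests = genes tested in that pair. The
pipeline restricts testing to the pair's eGenes (gene-level q < 0.05 in
either condition), making the e²QTL set a subset of the eGene set, which
is how the response fraction per stimulus is reported.

The control and stimulus samples come from the same donors, but the
z-test treats the two slope estimates as independent — a caveat
inherited from the method it reimplements; no covariance correction is
applied. With positively correlated errors the test is conservative.

## LD and colocalization

LD is the squared Pearson correlation of dosages (composite LD):
phase-free, allele-flip invariant, computed pairwise-complete, and
requiring non-constant vectors. This diverges from haplotype (EM) r²
computed on reference panels; for the common, well-imputed variants that
survive QC the difference is small.

Colocalization enumerates single-causal-variant configurations.
Per-variant Wakefield log-ABFs (prior effect SD 0.15 for quantitative
traits, 0.2 for case-control log-odds) are combined in log space:
S1 = Σ BF1ᵢ, S2 = Σ BF2ⱼ, S12 = Σ BF1ᵢBF2ᵢ, with unnormalised hypothesis
weights 1, p1·S1, p2·S2, p1·p2·(S1·S2 − S12), p12·S12 and priors
p1 = p2 = 1e-4, p12 = 1e-5. The H3 term is computed as a log-space
difference and clamped at zero; with a single shared variant it is
exactly zero. Effect alleles are harmonized before combining (beta sign
flips for swapped alleles; irreconcilable variants dropped with a
warning). Standard errors are required — MAF-based variance
reconstruction is not implemented. The default locus is the gene's cis
window.

## GWAS integration

A GWAS hit (p < 5e-8 on read, configurable) is linked to an eGene when
the hit lies in the gene's cis window and is in LD r² > 0.7 with the
gene's top variant. e²QTL-class records additionally require the
Bonferroni-significant slope response and gene-level q < 0.05 in the
matched condition; eQTL-class records require gene-level q < 0.05 plus
strong differential expression (adjusted p < 0.05 and |log₂FC| > 2). The
DE filter applies to the eQTL class only. One record per (gene, trait,
condition); a hit may tag several eGenes. Remote LD/association services
are replaced by local genotypes and file inputs so runs are hermetic.

## Synthetic-data model

Genotypes: variants in LD blocks generated by haplotype copying — each
haplotype carries a latent uniform redrawn with probability 1 − ld_decay
per step within a block, so adjacent-variant correlation ≈ ld_decay and
r² decays geometrically with distance. Allele frequencies are uniform on
maf_range (default 0.05–0.5). This is deliberately not a coalescent
simulation: it is desk-scale, and the r² structure is directly tunable,
which is what the LD filter and colocalization tests need. Defaults:
block size 10, ld_decay 0.9, one chromosome, 2 kb variant spacing, genes'
TSS spread across the variant span so every gene has cis variants.

Expression: counts are gamma-Poisson (negative binomial, variance
μ + φμ²) with a single dispersion knob φ (default 0.1, a typical bulk
RNA-seq value; per-gene dispersions are not modelled because no
estimates were available to emulate). The log₂ mean combines a
N(4, 1.5²) gene baseline, a lognormal library-size factor (σ = 0.2), the
condition log₂FC for true DEGs, optional sex effects, and
slope × dosage for planted eQTL. Effects act multiplicatively on the NB
mean (additively on log₂); downstream mapping is rank-based and hence
scale-free. The overall scale is a constant per condition (not
per-sample renormalisation), so planted effects stay exactly additive on
the log-mean and the realised library size varies mildly around
mean_depth (default 5e5 counts; column sums equal the recorded library
sizes by construction).

The default conditions are the six-arm stimulation design (CTRL, BPDE,
HC, MMS, TBOOH, UVC) with 461 donors. True DEGs are a configurable
fraction of genes (default 20%; the repression-emulation check uses 12%,
matching the ~9% prevalence typical of genome-wide exposure studies —
at much higher prevalence, CPM/TMM compositional bias visibly distorts
apparent fold-change directions). A shared core (60% of DEGs) is common
to all stimuli. The fraction of DEGs that are repressed is set per
condition: HC 0.85 and UVC 0.99 anchor the range, BPDE/MMS/TBOOH lie
between (0.95/0.92/0.90). |log₂FC| is N(2.5, 0.5) truncated at 0.5.
Planted outlier samples receive heavy multiplicative per-gene noise in
stimulated conditions, pushing them far from both condition clusters in
PC space.

GWAS: a fresh cohort (default 10,000) is drawn from the same
frequency/LD model, a quantitative phenotype is built from the causal
variant's effect plus N(0, 1) noise, and each variant is regressed
marginally, yielding per-variant beta/SE/p with effect-allele bookkeeping
on the alt allele.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: read-level artifacts and mapping bias,
imputation uncertainty, per-gene dispersion heterogeneity, population
structure and relatedness (genotype PCs are computed but no structure is
planted by default), trans effects, sex chromosomes, and case-control
GWAS traits (the simulator's traits are quantitative; the coloc prior
for binary traits is still exposed).

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen so the full suite completes in well under a minute of compute per
heavy check: null-calibration scans use 500 genes × 200 donors × 30 cis
variants; beta-approximation fidelity 50 genes at 10,000 permutations;
z-test calibration 2,000 genes and power 50 replicates at n = 400;
coloc discrimination 50 replicates (eQTL n = 400, GWAS n = 10,000); the
end-to-end demo 200 donors × 150 genes × 300 variants × 6 conditions at
500–2,000 permutations. These sizes are the package's own defaults for
its synthetic studies, not properties of the method.

## Known limitations

* The permutation/beta machinery assumes exchangeable samples; kinship
  or shared batches would violate it (the real-data workflow should
  regress out batch in the covariates).
* The moderated-t skips voom precision weights; very low counts are
  slightly mis-weighted.
* The e²QTL z-test ignores the control/stimulus covariance of the paired
  design (see above).
* Single-causal-variant colocalization: multi-signal loci dilute PP.H4;
  no fine-mapping or conditional analysis.
* The Storey q-value option uses the fixed-λ (0.5) estimator, not the
  spline smoother.
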