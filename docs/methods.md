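# Methods

`twinage` analyses how chronological age reshapes the transcriptome of a
twin cohort along four axes: the mean of expression, its population
variance, the discordance between genetically identical (MZ) co-twins, and
the genetic/epigenetic regulation of expression (genotype-by-age and
methylation-by-age interactions). This note records the models, the
numerical choices, and what the synthetic cohorts do and do not establish.

## Data model and normalisation

Expression arrives as a feature-by-sample count matrix (features are exons
or splicing links; every feature maps to one gene). Genes whose fraction
of zero counts exceeds 10% are removed as a whole (all their features).
Counts are scaled per sample to a common library size (default 10 million
reads) and each feature is rank-inverse-normal transformed,
`Phi^-1((r - 0.5)/n)` with average ranks for ties. The symmetric 0.5
offset avoids infinite quantiles; the offset is configurable because the
literature uses several variants (Blom, van der Waerden) that differ only
in this constant. After the transform the marginal count distribution is
irrelevant to the linear models downstream.

Feature coordinates are 0-based half-open internally; VCF positions are
converted from 1-based at the boundary. The TSS defaults to the start for
`+`-strand and the end for `-`-strand features when not given explicitly.

## The mixed-model engine

All association testing builds on one linear mixed model,

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I),

with technical covariates (insert size, mean GC, batch where applicable)
as fixed effects and grouping factors (family, and optionally primer
index, sequencing date) as random intercepts. The engine is written from
the likelihood: the covariance is profiled as
`sigma2_e (I + sum_k gamma_k Z_k Z_k')`, `beta` and `sigma2_e` have closed
forms given the ratios `gamma_k`, and the ratios are optimised by
L-BFGS-B on the log scale (bounds `log gamma` in [-20, 12], deterministic
start at `gamma = 1`, relative tolerance 1e-8). Flat likelihood
directions — e.g. every group of size one — are snapped to the
zero-variance boundary so the degenerate case reduces exactly to ordinary
least squares. The engine reproduces lme4's REML/ML variance components,
fixed effects and log-likelihoods to about six decimals on paired designs
(checked once against `lmer` during development).

Twin cohorts allow a much faster exact path for the common case of a
single family random effect: `Z Z'` over pairs and singletons has known
eigenvectors (within-pair sum and difference), so one orthonormal rotation
turns every likelihood evaluation into a weighted least squares with at
most three distinct weights. The profile likelihood in the single ratio is
maximised by a 37-point log-spaced grid followed by vectorised
golden-section refinement, simultaneously for thousands of features. This
is what makes 100-permutation scans affordable: the rotation and the
reduced-model fits are computed once, and each permutation only refits the
full model.

Age effects on the mean are tested by a likelihood-ratio test of nested
maximum-likelihood fits (with vs without age), with the statistic clipped
at zero and referred to chi-square with 1 df. Under a fully null cohort
the LRT statistics are indistinguishable from chi-square(1) by a
Kolmogorov-Smirnov test at 1000 features.

## Pair-preserving permutations and exon-count-stratified adjustment

Permutation re-assigns person-level labels (age) across sampling units,
where a complete twin pair is one indivisible unit; singletons permute
among singleton slots. Sample-attached technical covariates stay with
their expression values. Co-twins therefore still share a family and an
identical age in every permutation.

A gene's observed statistic is the maximum over its features, which makes
genes with more exons more significant by chance. To neutralise this,
genes are binned into up to 16 quantile strata of exons-per-gene and each
gene's maximum is compared only against the pooled permutation maxima of
its own stratum, with a +1 pseudocount:
`adj_p = (1 + #{null >= obs}) / (1 + pool)`. Pooling across the stratum's
genes gives resolution far below `1/n_permutations` at the default 100
permutations. Feature-level adjusted p-values (each feature against the
stratum's pooled per-feature nulls) are emitted alongside the gene-level
ones, plus a Benjamini-Hochberg column as a diagnostic. Under a null
cohort of 1-exon and 30-exon genes the two groups' gene-level false
positive rates differ by under 0.03 — the point of the stratification.

## Variance with age

Per feature, conditional (BLUP-adjusted) residuals from a mixed model with
technical covariates and the family random intercept are taken — age is
deliberately left in. A LOESS curve of residual on age (local quadratic,
tricube weights on the nearest `floor(0.75 n)` neighbours, no robustness
iterations; span and degree configurable) absorbs the age trend in the
mean; `d = sqrt|residual - loess(age)|` is a variance-stabilised distance
from the age-specific mean, and a two-sided Spearman test of `d` against
age detects age-dependent dispersion, signed by the direction of the
change. The hand-written LOESS matches R's `loess(surface="direct")` to
5e-11 on a frozen fixture (statsmodels' lowess is degree-1 only, and the
local-quadratic smoother is part of the statistic). Because LOESS removes
the mean trend, a pure mean effect of age does not fire the test
(rejection stays at the nominal level); a doubling of the residual sd
across the age range is detected essentially always at n = 600.

## MZ discordance

MZ co-twins share genome and age, so within-pair differences are
environmental. On residuals that remove *only* technical covariates (the
family structure is the signal), each feature's pair maximum is regressed
on the pair minimum plus age; the age coefficient tests whether the
max/min relationship is conditional on age, via its t-test, with the same
pair-level permutation and stratified adjustment as above. The key
discriminant property, reproduced in the acceptance suite: divergence
injected as *non-shared* noise growing with age fires the discordance
test, while the same variance injected as *pair-shared* shifts fires the
variance test but not the discordance test.

## ACE(+age) variance decomposition

Heritability and the age share of expression variance come from a REML
twin model on complete pairs: 2x2 family blocks with diagonal
`sA + sC + sE` and off-diagonal `sA + sC` (MZ) or `sA/2 + sC` (DZ),
components box-constrained at zero, age as a fixed effect, optimised
directly in the three variances (start: total/3 each). The age
contribution is put on the same scale as the components via
`sigma2_age = beta_age^2 * Var(age)`, so `h2 = sA/total` and
`PVE_age = sigma2_age/total` with `total = sA + sC + sE + sigma2_age`.
A and C are not identifiable from one zygosity; the fit requires both and
at least 20 complete pairs. The blockwise likelihood equals a dense
multivariate-normal evaluation to 1e-8, and the estimates track the
Falconer closed forms (`A = 2(r_MZ - r_DZ)`, `C = 2 r_DZ - r_MZ`) on the
same samples to within 0.02 in Monte-Carlo mean.

## Interaction scans

GxAge: for each eligible feature (those with an age effect on mean,
variance or discordance) and each variant within TSS +/- 1 Mb (inclusive
boundary) at MAF >= 0.05, an OLS fit of
`y ~ 1 + dosage + age + dosage*age` on family-whitened expression
residuals; the interaction coefficient is the target. The null is built by
refitting the interaction model on permuted residuals of the
main-effects-only model, 10 permutations, each permutation being one
dataset-wide relabeling shared by all features and variants so the null
maxima carry the same dependence as the observed maxima; pooling and
stratification are as in the expression analysis, with a final BH FDR call
at 5% across features.

Whitened (`V^-1/2`) rather than BLUP conditional residuals are used here:
BLUP residuals of pairs are negatively correlated within pairs while age
and genotype are pair-shared, which makes the observed t-statistics
stochastically smaller than any exchangeable permutation null — the scan
would be conservative by construction (near-zero rejection under the
null). Whitening removes the family structure *and* restores
exchangeability; with it the gene-level null rejection sits at the nominal
5% within binomial error. The variance analysis keeps BLUP residuals: its
permutation scheme is pair-preserving, so exchangeability at the pair
level is maintained there.

Methylation-by-age mirrors the genotype scan with the probe beta value in
place of dosage, on the gene set prescreened by the variance analysis
(nominal p < 0.1 by default), and calls significance at a fixed threshold
(default 1e-4, strict inequality). The threshold is taken as a
configurable constant rather than re-derived from a test count.

## Cross-tissue sharing (Storey pi1)

For an ordered (discovery, replication) tissue pair, the replication
p-values of the discovery-significant features are collected and
`pi0(lambda) = #{p > lambda}/(n (1 - lambda))` is evaluated on
lambda = 0.05..0.95 (step 0.05), smoothed by a cubic smoothing spline
weighted by `1 - lambda`, evaluated at the largest lambda and clipped to
[0, 1]; `pi1 = 1 - pi0`. A bootstrap variant (lambda minimising the
bootstrap MSE around the minimum raw estimate) is available; the smoother
is the default. The directed pi1 matrix is not symmetric and is emitted in
full. On a 30% Beta(0.1,1) / 70% uniform mixture the estimator's
expectation is ~0.28 rather than 0.30 — Beta(0.1,1) keeps ~0.5% of its
mass above lambda = 0.95, an intrinsic limit of any lambda-threshold
estimator, within the stated +/-0.05 band.

## The synthetic cohort generator

The generator emulates the study conditions of an adult female twin
cohort: MZ and DZ pairs plus singletons, ages uniform on 39-85 years
(the reported range; only range and mean are published, so uniform is the
one-parameter-free choice), co-twins sampled at the same visit and hence
at identical ages, and cohort sizes defaulting to 100 MZ + 100 DZ pairs
with 200 genes — a scaled-down version of the 856-individual cohort that
keeps every test exercised at desk scale. Each gene carries a
ground-truth profile: an age slope in residual-sd units per year; ACE
fractions summing to one (DZ allele sharing is implemented by explicit
parental-haplotype transmission, giving the exact IBD distribution rather
than a 0.5-correlation shortcut); multiplicative per-year scalings of the
unique- and the pair-shared-environment sd (anchored at the age midpoint);
a non-shared divergence term whose sd grows linearly from zero at the
youngest age (visible as MZ discordance); cis-variant main and
variant-by-age effects; and methylation probe and probe-by-age effects.
Technical covariates (insert size, GC, batch; primer index and sequencing
date as grouping factors) are independent draws with a small configurable
effect (default 0.1 sd per covariate).

Latent signals map to counts through `exp()`, per-sample library scaling
with +/-20% depth variation, and Poisson rounding; with the default
10-million-read library the Poisson layer is essentially noiseless and
rank-normalisation recovers the latent scale. Exons of a gene share the
gene-level signal; half of the unique-environment variance is exon-specific
by default (`exon_corr`).

What the generator does *not* emulate: realistic count dispersion
(negative-binomial overdispersion at low depth), linkage disequilibrium
between cis variants, non-uniform age distributions, population structure
or relatedness beyond nuclear twin families, batch-by-age confounding, and
cell-type composition shifts with age. Passing tests therefore establish
the statistical machinery — calibration, power at stated effect sizes,
identifiability logic — not robustness to those real-data complications.
One interaction worth knowing about: library-size scaling couples
features, so if a large share of genes moves with age in the same
direction, null genes inherit a small opposite trend (compositional
leakage). The calibration cohorts are fully null and unaffected; in
effect-rich simulations the leakage is visible, as it would be in real
data normalised the same way.

## Problem sizes and defaults

Acceptance-grade checks run at the sizes a laptop CPU handles in minutes:
calibration on 200-gene, 400-sample null cohorts with 100 permutations;
LRT distribution at 1000 features; ACE at 1000+1000 pairs averaged over 20
replicate features (the per-draw sampling sd of the A component is ~0.05
at this size, so single-draw comparisons would be dominated by Monte-Carlo
noise); power curves at n = 600 with 100-200 replicates; exon-count
fairness on 1000 genes (500 one-exon, 500 thirty-exon). Defaults
throughout: alpha 0.05, zero-count fraction 0.10, library scale 1e7, MAF
0.05, cis window 1 Mb, LOESS span 0.75 / degree 2, 100 permutations for
expression/variance/discordance and 10 for GxAge, methylation threshold
1e-4, variance prescreen p < 0.1.

## Known limitations

* Random technical factors route single features through the dense engine;
  cohorts much beyond ~2000 samples would need a sparse path.
* The ACE model has no dominance (ADE) or bivariate extension, and no
  age-stratified heritability.
* The GxAge scan assumes family structure is fully handled by the
  residualisation; no mixed model is refitted per variant.
* `pi1` compares tissues through feature identifiers only; probe- or
  exon-level identifier mismatches across quantification runs must be
  resolved upstream.
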