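# Methods

`rvburden` implements a multi-study gene-based rare-variant burden
association framework for binary (case-control) traits, together with the
integrative analyses that typically follow a large sequencing study:
GWAS-convergence tests and burden-score heritability regression.  This
note records the models, the numerical choices, and what the synthetic
cohorts do and do not emulate.

## Masking model

Rare coding variants of a gene are pooled into *masks* defined by an
annotation criterion and a frequency criterion on MAF_max, the maximum of
the folded (minor-allele) frequency over reference super-populations and
the in-sample frequency.  The annotation grid has 20 schemes: two PTV
groups (all high-confidence protein-truncating variants; the subset
without LOFTEE flags), six missense groups (predicted damaging by REVEL,
AlphaMissense, PrimateAI-3D or popEVE individually, by at least one tool,
or by at least three of the four), and the twelve pairwise PTV x missense
unions.  Frequency tiers are nested: ultra-rare (MAF_max < 1e-5), rare
(< 1e-3), and rare+low-frequency (< 1e-2).  A gene can therefore carry up
to 60 masks (120 on chrX, where male and female strata are tested
separately).  A union mask is emitted only when both of its components
contribute at least one variant within the tier; otherwise it would
duplicate the corresponding single-class mask, and the enumeration count
for a PTV-only gene (six masks) would be wrong.  Because damaging
tool calls arrive as boolean columns, tool score thresholds live upstream
of this package; any thresholding convention can be expressed in the
input table.

Burden coding is the carrier indicator (1 if a sample carries >= 1 minor
allele across the mask's members), which makes the odds ratio
interpretable as carrier risk; allele-sum coding is available via a
switch.  cMAC, the cumulative minor allele count of a mask, drives all
count-based filters.

## Per-study association model

Each mask is tested by penalized logistic regression of case status on
the burden genotype with covariate adjustment (age, sex, ancestry PCs by
default).  Maximum likelihood diverges under separation — routine at rare
carrier counts — so estimation maximises the Jeffreys-penalized
likelihood l(b) + 0.5 log |I(b)| (Firth's correction).  Two modes:

* **exact** — all coefficients penalized jointly; used for oracles and
  small problems.
* **approximate** (default for scans) — the covariate-only null model is
  fit once by ordinary ML (statsmodels), its linear predictor becomes an
  offset, and the Firth fit involves only intercept + burden.  For a
  binary carrier burden the two-parameter information matrix, hat
  diagonals and modified score reduce to sums over carriers and
  non-carriers, giving an O(n) per-iteration fit; an exome-wide scan of a
  20,000-sample study takes milliseconds per mask.

Newton iterations use the Firth-modified score with step-halving on the
penalized likelihood (max 50 iterations, score tolerance 1e-8).  The
p-value is the penalized likelihood-ratio test of the burden coefficient,
with the constrained fit using the full-model information in its penalty
(profile penalized likelihood).  The standard error is back-corrected
from the p-value, SE = |beta|/z with z the matching normal quantile, so
that (beta, SE) reproduce the test when fed to meta-analysis; when the
LRT is exactly zero the Wald SE from the inverse penalized information is
reported instead.  Results with cMAC below the per-study threshold
(default 10; a carrier-count >= 20 mode is available) are dropped.

On a 2x2 table the exact-mode estimate coincides with the add-1/2 log
odds ratio, which the tests exploit as a closed-form oracle alongside a
brute-force grid maximisation of the penalized likelihood.

## Meta-analysis and saddlepoint correction

Per-mask study results are combined by inverse-variance-weighted fixed
effects: w_s = 1/SE_s^2, beta_meta = sum(w_s b_s)/sum(w_s), SE_meta =
(sum w_s)^(-1/2), Cochran's Q on n-1 df for heterogeneity.  Masks must
reach total cMAC >= 20 with >= 2 contributing studies to survive.

The pooled Z is normal-referenced, which mis-calibrates for rare burdens
in unbalanced studies.  The correction models the null exactly at the
count level: each of cmac_s carrier alleles falls in a case independently
with probability phi_s (the study case fraction), X_s ~ Binomial(cmac_s,
phi_s), U_s = X_s - cmac_s phi_s, and T = sum_s lambda_s U_s with
lambda_s = zeta_s / sqrt(cmac_s phi_s (1 - phi_s)), zeta_s the normalised
IVW weights.  This scaling makes T / sqrt(Var T) match the IVW Z under
normality, so the saddlepoint tail of T is a pure tail correction.  Tails
come from the Lugannani-Rice formula on the exact binomial CGF; the
saddlepoint equation K'(t) = t_obs is solved by bracketed Brent iteration
(K' is strictly increasing).  Two-sided p = 2 min(upper, lower), the
lower tail evaluated as the upper tail of -T.  The adjustment is applied
to masks with IVW p < 0.05 by default.

**Lattice handling.**  When all studies share one score span (a single
study, or equal lambda_s), T is a lattice variable, and the plain
continuous formula underestimates the tail at an observed atom by roughly
half the atom mass.  If the observed t_obs lies on the lattice, the
lattice form of the formula is used (saddlepoint at t_obs - span/2 and
the sinh-corrected v of Daniels' second continuity correction), which
agrees with exact binomial enumeration to within a few percent down to
tails of 1e-8.  Off-lattice observations and incommensurate spans use the
plain formula, whose error is negligible there.  Degenerate cases — t_obs
outside the support, saddlepoint at the origin — fall back to the exact
boundary atom and the normal approximation respectively, and any
root-finding failure returns the unadjusted p flagged as such.

A note on two-sided calibration under strong imbalance: when the total
cMAC is small, the null lower tail of T is bounded away from zero (the
all-referents atom has probability prod_s (1-phi_s)^cmac_s), so at
significance levels below that atom a two-sided rule can only reject via
the upper tail and its attainable type-I rate is alpha/2.  The
calibration experiments therefore use total cMAC large enough (~300) for
both tails to be live at the 1e-3 level.

## Gene-level combination

Surviving masks are combined with the Cauchy (ACAT) test, valid under
arbitrary dependence: T = mean of tan((0.5 - p) pi), combined p = 0.5 -
arctan(T)/pi, with the 1/(p pi) substitution below p = 1e-15 and p = 1
clipped to 1 - 1e-15 (the Firth LRT can return exactly 1).  Combination
is layered: missense-only masks, PTV-only masks and PTV+missense masks
are first combined within layer, then the 1-3 layer p-values are combined
into the gene p-value; absent layers are dropped, not imputed.  Weights
are equal throughout.  The best mask reported per gene is the minimum
(SPA-adjusted, else IVW) p, ties broken by larger total cMAC then mask
name.  Exome-wide significance uses alpha = 0.05 divided by the number of
gene-stratum tests actually performed.  Sensitivity re-combinations
(rare-only and ultra-rare-only tiers, PTV-only, missense-only) rerun the
same layering on the restricted mask set.

Calibration of a scan is summarised by lambda90: the ratio of the 90th
percentile of the chi-square(1)-transformed p-values to the theoretical
90th percentile (~2.70554).  The genomic-control median would be noisier
for the heavy-tailed Cauchy statistics; the 90th percentile matches how
such scans are usually reported.

## GWAS integration

*Enrichment grids.*  For each (burden significance cutoff) x
(prioritisation score cutoff) cell, the 2x2 of burden-significant vs
GWAS-nominated genes is tested with Fisher's exact test.  The odds ratio
reported is the conditional MLE of Fisher's noncentral hypergeometric
model (solving E_psi[X] = a), with the exact tail-inversion CI; the
sample cross-product OR is also emitted because the two conventions
differ noticeably in sparse cells.  Boundary cells return 0/infinity
estimates with one finite CI bound, and empty margins are flagged
degenerate rather than tested.

*Subset discovery.*  Restricting the search space to GWAS-nominated genes
relaxes the Bonferroni threshold to 0.05/|subset|; the function reports
the threshold with the hits.

*Effect-size power law.*  log |beta| is regressed on log MAF by OLS
across common variants, low-frequency variants and burden masks (using
cumulative MAF for masks); refitting with the CI bounds of |beta| yields
an upper and lower band.  Curation of the input effect table (study
counts, case-count fractions, coding-only restrictions) is the caller's
responsibility — these are data-curation rules, not computation.

## Burden heritability

For gene g with mask variants at frequencies p_i, the burden score is
gamma_g = sum_i 2 p_i (1 - p_i) — the variance of the allele-count burden
under independence.  With alpha_g the effect of the standardised burden
genotype on the standardised observed phenotype, E[alpha_hat_g^2 -
se_g^2] = b_g^2 gamma_g, and under exchangeable squared per-allele
effects the regression of (alpha_hat^2 - se^2) on gamma with a free
intercept (absorbing stratification and residual relatedness) gives
h2_obs = slope x sum(gamma).  Variants above MAF 1e-4 are excluded;
bins are ultra-rare (<1e-5) / rare (1e-5 to 1e-4) crossed with PTV /
damaging missense / non-damaging missense (no tool call) / synonymous;
gene-bin masks with cMAC < 20 are excluded; fits require >= 50 gene-bins.

Numerical choices: weights 1/(2 (gamma slope0 + se^2)^2) from a one-step
iteration (slope0 from the unweighted fit), matching the variance of a
squared-normal response.  `fixed_genes` removes outlying large-effect
genes from the regression and adds their own alpha_hat^2 - se^2 back,
which doubles as the per-gene partition; non-fixed genes partition the
remainder proportionally to slope x gamma_g, so contributions sum exactly
to the estimate.  `genomewide_correction` (off by default) projects the
component aligned with the genome-wide aggregate burden out of the effect
estimates before regressing; the reference procedure's exact internal
covariate is not published, so fidelity here is established by parameter
recovery on simulations with known truth, not numeric identity with any
external implementation.  Standard errors combine a 100-block contiguous
gene jackknife of the slope (weights held fixed across deletions) with
the delta-method variance 4 alpha^2 se^2 + 2 se^4 of each fixed-gene
contribution.

Liability conversion uses the standard transform h2_liab = h2_obs x
K^2(1-K)^2 / (z^2 P(1-P)) with K the population prevalence, P the sample
case fraction and z the standard normal density at the liability
threshold; for population cohorts P = K and the formula reduces to
h2_obs K(1-K)/z^2.

## Synthetic cohorts

The generator draws a shared variant catalogue — variant count per gene
1 + Poisson, allele frequencies log-uniform on [1e-6, 1e-2] (spanning all
three mask tiers and both heritability bins), annotation classes at the
observed exome composition (~25% synonymous, ~50% benign missense,
10-15% damaging missense, <5% PTV, normalised to sum to one), per-tool
damaging calls at rate 0.75 for damaging missense (at least one forced),
LOFTEE flags on 10% of PTVs — and, per study, independent genotypes
Binomial(2, p_i), covariates, and liability-threshold phenotypes.
Liability is the sum of per-allele class effects in causal genes
(constant within class, matching the homogeneity assumption of the
heritability model), covariate effects (standardised age 0.3, sex 0.25,
PCs 0 by default) and standard normal noise; the case threshold is set
from the configured prevalence on the total liability scale.  Default
prevalence is 5%, the approximate population prevalence of the target
arrhythmia in middle-aged cohorts.  Case-ascertained studies rejection
sample cases to their target count, drawing only causal-gene genotypes
for candidates (liability does not depend on the rest).  chrX genes are
optional; males carry haploid 0/1 dosages and are analysed in a
male-only stratum.

Not emulated: linkage disequilibrium (mask variants are pooled as
independent, and the heritability model assumes negligible LD at these
frequencies), haplotype structure, imputation or sequencing error,
relatedness, admixture, and per-study effect heterogeneity by default (an
optional between-study effect SD exists but defaults to zero, since no
heterogeneity level is established for the target trait).  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to those real-data features.

## Problem sizes used in the shipped checks

The null-calibration run uses 2 studies x 20,000 samples x 2,000 genes
(~8 variants/gene), chosen to give several hundred surviving gene tests
under the count filters while completing in a few minutes on one core;
gene-level lambda90 lands near 1.02.  SPA calibration uses 100,000 null
replicates over 5 studies at case fraction 0.05 with per-study cMACs
30-90 (total 300, so both tails are live at the 1e-3 level; see the
lattice note above).  Heritability recovery uses 5,000-gene
summary-statistic simulations at planted h2 = 2% with 5% causal genes and
n = 400,000.  Enumeration-based oracles (Firth grid search, binomial SPA
tails, hypergeometric Fisher) run at the small sizes where enumeration is
exact.
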