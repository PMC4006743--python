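# Methods

This note documents the statistical procedures implemented in `qtnvar`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Design and coding

The unit of analysis is a complete 2^L factorial allele-replacement panel
(L = 4 loci by default: RME1nc, RSF1c, IME1c, IME1nc), each strain carrying
the oak (O) or vineyard (V) allele at each locus.  All models use treatment
(dummy) coding with oak as the reference: the indicator for a locus is 1
for the vineyard allele, and an interaction column is the product of its
constituent indicators.  The intercept is therefore the expected response
of the all-oak strain and each coefficient the effect of swapping in the
vineyard allele(s) in that background.  Sum-to-zero coding is deliberately
not used: the fitted coefficients are then directly interpretable as
allele-replacement effects, which is how per-gene models are reported.

Canonical term order is: intercept, main effects in locus order, then
interactions grouped by order, each group in lexicographic combination
order.  This is the conventional ANOVA row order and is load-bearing: the
sequential decomposition below attributes SS in exactly this order.

## Normalization and filtering

Size factors are median-of-ratios: for each gene with strictly positive
counts in every sample, the ratio of its count to its geometric mean across
samples; a sample's factor is the median ratio.  Genes with a zero count in
any sample are excluded from factor *estimation* (their geometric mean is
zero) but are still normalized and filterable.  Counts are divided by the
sample's factor.

Filtering removes the `ceil(q * G)` genes with the smallest total
normalized count across samples (q = 0.20 by default); ties are broken by
gene label so the survivor set is deterministic.  With this convention a
5792-gene matrix with distinct totals keeps exactly 4633 genes.

## Two-stage modelling

Per gene, stage one regresses normalized counts on day-of-growth indicator
variables (OLS with intercept), equivalent to subtracting the per-day gene
mean; stage two fits the full factorial genotype model to the residuals.
The model F statistic tests all genotype terms jointly against the residual
mean square; its p-value is the per-gene "model p".

The two-stage structure is kept deliberately, although a joint day+genotype
model is statistically cleaner: the residual degrees of freedom of stage
two do not account for the day parameters removed in stage one.  With the
default design this is benign for the observed fit — each replicate of the
panel is grown on one day, so the genotype design is balanced within days
and nearly orthogonal to the day space — but it does matter for the
permutation null (below).  The alternative log-scale variant fits
`log(N + 1)` on day indicators and genotype jointly; a pseudocount of 1 is
used because zero counts occur and the natural count scale makes +1
negligible for expressed genes.  In the joint model, the model F is the
partial F of the genotype terms given the day covariates, so that "model p"
measures genotype significance in both variants.

Degenerate conventions: a zero-variance response reports R² = 0 and model
p = 1 (avoiding 0/0); rank-deficient designs (e.g. a subset panel in which
a locus never varies) are fitted by dropping aliased columns in sequence
order, which are reported with NaN coefficients and excluded from the
model df.

## Sequential variance decomposition

Type-I (sequential) sums of squares are computed from one thin QR
factorization of the design in canonical column order: the squared
projections of the response on successive orthonormalized columns equal
the drop in residual SS as each term joins the model.  The test suite and
the acceptance script verify this against a brute-force oracle that refits
every prefix model and differences the residual SS (relative tolerance
1e-8).

A term's *fraction of variance explained* is 100·SS_term/SS_total with the
residual SS included in the denominator — the convention under which the
published sporulation table's fractions reproduce from its SS column
(7702/22443.4 = 34.32%).  Per-allele shares sum the allele's significant
main term and all significant interaction terms containing it, a term being
significant when its F-test p-value is below 0.1 (a deliberately permissive
threshold); a k-locus interaction is credited to each of its k loci, so
per-allele shares overlap by design.  On the balanced full panel the
centered main-effect columns are mutually orthogonal, so main-effect SS are
order-invariant; with one dropped replicate (the 63-sample design) the
decomposition is mildly order-dependent, and the canonical order is the
documented one.

## Significance control

Benjamini–Hochberg step-up control of the FDR at 10% is applied to the
per-gene model p-values (via statsmodels); the largest unadjusted p among
rejections is reported as the effective genome-wide threshold.

The permutation null shuffles the sample-to-strain assignment as intact
multi-locus genotype vectors (never per-locus — the null must preserve the
within-strain allele correlation), refits every gene, and records the 5th
percentile of the genome-wide model p-values; 1000 replicates by default,
each on an independent stream spawned from one master seed.  Day
residualization is done once, before permuting, because the day is a
property of the sample, not of the genotype.  An option to permute within
day strata exists but is off by default.

**Known asymmetry.**  Permuting genotypes *after* residualizing out day
effects is not exchangeable when there are several days: the observed
genotype design is day-balanced and hence orthogonal to the removed day
space, while permuted designs are not, so permuted fits lose part of their
model SS to the projection and their p-values are slightly conservative
relative to the observed ones.  Under a global null with four replicate
days this places the observed 5th-percentile p about two null standard
deviations below the permutation mean (measured by the test suite).  Any
analysis using this permutation scheme on a day-residualized matrix — not
just this implementation — carries the same mild anti-conservativeness of
the observed-vs-null comparison.  Calibration checks of the permutation
machinery itself therefore use a single-day null, where observed and
permuted fits are exactly exchangeable; real signal in a fraction of genes
drives the observed percentile far below the null (z ≈ −7 in the default
synthetic study), dwarfing the asymmetry.

## Replicate noise and allele comparisons

The coefficient of variation uses the sample (n−1) standard deviation over
the mean across biological replicates — the n−1 convention is the standard
for small biological replicate counts.  Because replicates are confounded
with days, counts are first day-corrected *multiplicatively* on the
original count scale: each gene's counts on a day are divided by the ratio
of that day's gene mean to the reference day's gene mean (the reference day
is a required configuration choice; the pipeline defaults to the first day
level when unset).  Genes with a nonpositive mean on some day cannot be
corrected and are flagged and left unchanged.  CV is undefined (flagged)
for zero-mean genes.

Per-allele share profiles are compared with the two-sample Wilcoxon
rank-sum (Mann–Whitney) test, by default the normal approximation with tie
correction and continuity correction (shares contain many exact zeros, so
ties are the norm); an exact-distribution method is available and is
validated against exhaustive U enumeration for group sizes ≤ 8.

## Synthetic data generator

The generator reproduces the study design: 16 strains (all 2^4 genotypes),
4 biological replicates, each replicate grown on its own day, one strain
(vineyard at RME1nc/RSF1c/IME1nc, oak at IME1c — configurable) losing one
expression library for 63 samples, and 64 phenotype observations.

Two count modes:

- **gaussian**: `count = max(0, round(intercept + X·beta + day_offset +
  N(0, noise_sd)))`; day effects additive, matching the subtraction-based
  correction.  Default noise_sd 20 on intercepts 50–500.
- **nb**: `count ~ NegBin(mean = day_mult · exp(intercept + X·beta), size =
  dispersion)` with variance μ + μ²/size; day effects multiplicative,
  matching the ratio-based correction.  Default size 10, a typical bulk
  RNA-seq overdispersion; `size = inf` gives the Poisson limit.

By default 5% of genes carry genotype effects (the share of the genome with
significant models in the emulated study), spread over one to four random
factorial terms and scaled for an expected genotype R² around 0.5.  Day
effect scales default to sd 15 counts (gaussian) / 15% (nb).  Phenotype
truths are main-effects-only with effect sizes solved from target Type-I
variance fractions — default (34.32, 20.13, 32.13, 6.50)%, the published
per-locus sporulation fractions — by inverting the balanced-design
closed form E[SS_main] = (n/4)β² + σ², E[SS_other] = σ² per df.  The
phenotype intercept defaults to 90% with noise sd 3, keeping the [0,100]
clip more than 3σ away so clipping does not bias recovery.

What the generator does **not** emulate: gene–gene expression correlation
(genes are independent given the design), gene-specific day effects
(batches shift all genes together), library-size variation beyond what the
nb day multipliers induce, and count–mean dispersion trends.  Passing
recovery and calibration tests therefore demonstrates correctness of the
estimators under the factorial design and these noise families, not
robustness to correlated genes or complex batch structure in real data.

## Problem sizes in tests and acceptance

Calibration checks run at 300–500 genes and 63 samples with 60–100
permutations, FDR calibration over 200 simulated null datasets, recovery
over 20 seeds at the full study design, and oracle comparisons over 50
random factorial instances; the full synthetic pipeline runs at 2000 genes.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances (±3 percentage points for recovered fractions) while keeping the
whole suite fast.
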