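# Methods

This note documents the statistical models implemented in `flowgwas`,
the defaults that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## Synthetic cohorts

The generator (`flowgwas.synthdata`) exists because the cohorts this
kind of workflow runs on are access-controlled; it produces data with
exactly the structure the pipeline is built to handle, with the ground
truth recorded for every injected effect.

**Genotypes.** LD blocks are generated by a Gaussian copula: each
haplotype's latent value is `sqrt(rho)*u_block + sqrt(1-rho)*e`,
thresholded at the normal quantile of the variant's allele frequency
(drawn uniformly from the block's MAF range). Marginal allele
frequencies are therefore exact Hardy–Weinberg binomials while the
within-block dosage correlation is governed by `rho`; blocks are
independent, and cross-chromosome LD is zero by construction. Dosages
are hard genotypes {0,1,2}; an imputation INFO field is carried as
metadata (1.0 unless attenuating noise is requested). This gives a
simple exact oracle for every LD-dependent stage (clumping, the
stepwise r² cap, fine-mapping) at the cost of realism: real human LD
maps, imputation-quality variation and population structure are
deliberately not modelled, so passing tests demonstrate algorithmic
correctness, not robustness to those features of real data.

**Covariates and technical structure.** The covariate table carries
everything the adjustment models consume: measurement timestamps over a
two-year study window (working hours only), analyser label (2 levels),
seconds-since-new-year and time-of-day derived from the timestamp,
venipuncture-to-analysis interval (2–36 h, ~5% missing, imputed by the
observed median with an indicator), age, sex, menopause status
consistent with sex (males are level "male"), weight/height/pack-years
with mean-imputation flags, drinking/alcohol/smoking levels, trial arm
and clinic. Injected technical terms are: a between-analyser offset, a
slow drift (one sinusoidal cycle over the study span), an annual
seasonal sinusoid (365.25-day year, timestamps in seconds since the
epoch), and a linear venipuncture-interval trend. All are functions of
the covariate table only, hence independent of genotype.

**Phenotypes.** Traits are assembled additively on the transformed
scale — Σβ·dosage + technical terms + covariate terms + N(0, σ²) — and
mapped back through the inverse pre-transform of the trait's support
class, so the pipeline's own transform recovers the additive structure.
The measurement-error model is a pragmatic Gaussian stand-in; it makes
no claim about real analyser noise.

**Protein tables.** Per-protein allelic effect estimates are drawn
around a mean shifted by −δ for α-granule-labelled proteins (default
study condition δ = 0.038 SD at n = 1456 proteins with ~260 granule
labels, matching the scale of the enrichment analysis), with
per-protein standard errors and Wald p-values; megakaryocyte expression
is independent of the label unless confounding is requested, in which
case granule proteins are more highly expressed and expression itself
shifts the effect — the pattern the adjusted regression must undo.

## Two-stage adjustment

Pre-transforms: natural log for positive-support traits, logit for
proportions (percentages detected by values above 1 and divided by
100; exact 0/1 nudged inward by half the smallest observed spacing,
logged), identity otherwise. All are exactly invertible.

Both adjustment stages are penalised B-spline additive models fitted by
`flowgwas.smoothing`: equally spaced knots, second-order difference
penalties (cyclic penalty for the annual term), basis dimension 10 per
univariate smooth and 5×6 = 30 for bivariate tensor products, smoothing
parameters chosen by generalised cross-validation over a log-spaced
grid (10⁻²…10⁸) with two coordinate-descent sweeps across terms. The
`⊗` interaction is implemented as factor-by-smooth: factor main-effect
dummies plus one smooth per factor level, each level's basis centred
within the level for identifiability. A bespoke solver is used because
the model class — factor-by-smooth, a cyclic smooth and a tensor smooth
in one fit — is not expressible in the installed GAM implementations;
the parts are the standard P-spline recipe. Degenerate designs degrade
gracefully: a single analyser level (or a level below the minimum
count, default 50) drops or coarsens the interaction with a logged
warning; menopause levels below the minimum are pooled into the largest
female level.

Stage-1 residuals are re-centred to the mean of the unadjusted
transformed trait before stage 2.

## Outlier filters and normalisation

The MAD rules use the 1.4826 consistency factor (configurable), centre
at the median, and are applied once each, in sequence: first remove
points whose adjustment magnitude exceeds 3.5 scaled MADs from the
median adjustment, then points whose residual exceeds 4.5 scaled MADs
from the survivors' median. Under normality the scaled MAD estimates
the SD, so expected removal fractions are the closed-form normal tails
2Φ(−3.5) and 2Φ(−4.5) — the calibration the tests check. The
multivariate filter standardises a cell-type group of traits, computes
principal-component scores, standardises the leading *d* of them and
removes samples whose squared-score sum exceeds the χ²_d quantile at
1−10⁻⁷. The per-group *d* (number of independent measurements) is a
required input, not guessed.

The inverse-normal transform uses the Blom offset (rank − 3/8)/(n + 1/4)
with average ranks for ties, within analyser × sex × menopause strata;
strata below a minimum size (default 10) are excluded and flagged. The
output is exactly invariant to any strictly monotone per-stratum
transformation of the input.

## Association scan

Per-variant OLS of the normalised trait on alternate-allele dosage with
nuisance covariates (clinic dummies plus the top-10 genotype principal
components) projected out once through an orthonormal basis — the
Frisch–Waugh–Lovell device, which makes each per-variant fit exact
while the scan stays a handful of matrix products. OLS deliberately
stands in for a linear mixed model: the synthetic cohorts are unrelated,
where the two coincide. Missing dosages are mean-imputed per variant;
monomorphic variants are flagged not-testable. QC defaults: MAF >
0.04%, INFO > 0.4. Genomic control λ is the median implied 1-df χ²
statistic divided by the null median (≈0.455).

## Conditional analysis

Genome-wide-significant variants (Wald *P* < 8.31×10⁻⁹) are partitioned
into blocks by single-linkage clustering with a 10-Mb gap, never across
chromosomes. Within a block, Efroymson stepwise selection alternates
forward and backward steps: each non-member is scored by a
likelihood-ratio test against the current model (statistic
n·ln(RSS₀/RSS₁) on χ²₁ — the LR distributional choice, since only "a
likelihood-ratio test" is specified); the best candidate enters if its
p-value beats the threshold and its r² with every member is at most 0.9;
after each admission, members are ejected while the worst removal
p-value exceeds the threshold. Ties in p break by genomic coordinate
then lexicographic id, making the procedure order-invariant.
Covariates are residualised out of trait and dosages once (exactly
equivalent to carrying them in every model). The final model is an
elimination-first pass over the union of block selections; joint
effects come from the full OLS refit.

## Clumping and novelty

Clumps are connected components of the graph whose edges join variant
pairs with r² strictly above 0.8 — equivalent to the iterative
pair-merging formulation, but canonical and order-invariant.
Cross-chromosome r² is defined as zero, and by default pairs further
apart than 10 Mb are not evaluated (an exact all-pairs mode exists and
is what the oracle tests compare against). A clump is novel for cell
type X iff it contains a variant associated with an X trait and no
member is in strong LD with any catalogue variant of cell type X; the
published cCBC trait → cell type map ships as
`clumping.CCBC_CELL_TYPES`.

## Fine-mapping

Windows are 500-kb intervals centred on each conditionally significant
variant, merged when overlapping. Within a window every causal
configuration γ with |γ| ≤ K (K = the number of conditional variants in
the window) is scored exactly: with score statistics z and LD matrix R,
z | γ ~ N(0, R + n·s²·R_γR_γᵀ) under an independent Gaussian effect
prior with SD s = 0.08 on the standardised scale. Because z is a
sufficient statistic for this Gaussian family, the summary-statistic
Bayes factor equals the individual-level marginal-likelihood ratio
exactly — which is why the test suite can demand 3-decimal agreement
with an individual-level oracle rather than asymptotic closeness. The
configuration-size prior makes each variant independently causal with
probability 1/m (config-exposed; a package default, not a claim about
the original analyses). R is ridge-regularised by 10⁻⁴ for numerical
stability (disabled in oracle comparisons). Enumeration is exhaustive;
a window whose configuration count exceeds the budget raises rather
than approximating silently. The 95% credible set adds variants in
decreasing inclusion probability until the covered share of the
non-null posterior mass (the probability that at least one causal
variant lies in the set) reaches 0.95, with coordinate tie-breaks; a
1e-9 tolerance absorbs summation round-off.

## Colocalisation

Per-variant evidence is Wakefield's approximate Bayes factor,
log BF = ½·log(se²/(se²+W)) + z²/2·W/(se²+W), with effect prior
variance W = 0.01 per trait on the standardised scale. Regional model
likelihoods sum over variant assignments with per-variant priors
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (the standard defaults of the ABF
colocalisation literature; the original tool's settings are not
published, so these are package defaults): trait-1-only and
trait-2-only sums, a shared sum over per-variant products, and a
distinct-pair sum over ordered unequal pairs (S₁S₂ − S₁₂, computed in
log space). A shared posterior above 0.8 is a colocalisation call, and
regions only enter the computation when the two lead variants are in
strong LD (r² > 0.8). Multi-signal regions are reduced to single-signal
statistics first: the trait is regressed on the other conditional
variants not in strong LD with the target and the residuals re-scanned.
Case-control partners are handled on the log-odds scale with their
reported standard errors; no liability-scale transform is attempted.

## Enrichment

α-granule classification from a grey-platelet-syndrome (GPS) vs
control abundance comparison labels a protein iff a Welch t-test on log
abundances is significant at 0.05, its log-ratio lies more than 2
spreads from the median log-ratio, and it is less abundant in GPS
platelets. The spread is the ordinary SD of the log-ratios centred at
the median (the phrase "2 standard deviations from the median" is
ambiguous; a scaled-MAD alternative is available behind the `spread`
switch). The 2×2 enrichment table cross-classifies
megakaryocyte-expressed (log₂FPKM > 1), associated (*P* < 10⁻³)
proteins by granule label × effect sign; the two-sided Fisher p sums
hypergeometric probabilities no larger than the observed table's (the
conventional two-sided rule). The localisation regression fits effect
size on the granule indicator plus log₂FPKM by OLS.

## Pipeline, formats, reproducibility

Stages run in dependency order with declared prerequisites; all
randomness derives from a single root seed split per stage via
`SeedSequence`. Genotypes are read from VCFv4.2 (DS preferred, GT
summed; cyvcf2) and written by a minimal text writer; tables are TSV;
windows are BED. Coordinates: VCF/TSV 1-based inclusive, BED 0-based
half-open. The run manifest records package version, seeds, thresholds
and input digests, and identical configurations produce byte-identical
outputs.

## Problem sizes in the validation suite

The test-suite and acceptance-script simulations use desk-scale
problem sizes chosen to give the relevant statistics adequate power:
recovery simulations at n = 2000 with three 0.3-SD causal variants in
20-variant blocks (causal MAF 0.3–0.5, where per-variant power at the
genome-wide threshold exceeds 99%); 500 null scans of 10⁴ variants;
200 coverage simulations on 50-variant windows; 100-instance oracle
comparisons for clumping; adjustment checks at n = 10⁴; filter
calibration at n = 10⁵. The acceptance script reports the same
quantities at moderately reduced replicate counts.

## Known limitations

Exchangeable-block LD is a caricature of real haplotype structure; the
OLS scan does not address relatedness; fine-mapping assumes the scan's
sample computed both z and R (no allele-frequency consistency checks);
colocalisation priors are fixed rather than estimated genome-wide; and
the trait registry ships with synthetic exemplar traits rather than
real analyser trait definitions, which are not public.
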