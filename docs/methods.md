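# Methods

This note documents the statistical models, defaults, and design choices of
`mrmediate`, and what the synthetic-data validation does and does not show.

## Two-sample MR model and estimators

All analyses operate on marginal per-variant summary statistics. Binary
traits carry effects as log odds ratios, quantitative traits in SD units.
The three instrumental-variable assumptions (relevance, independence from
confounders, exclusion restriction) are addressed operationally: relevance
by the genome-wide significance filter (p < 5×10⁻⁸, strict inequality) and
the per-variant F statistic (β/SE)²; independence by a user-supplied
exclusion list of variants with known confounder associations; exclusion
restriction by removing variants directly associated with the outcome at
genome-wide significance and by the pleiotropy diagnostics (Egger
intercept, outlier test, weighted median).

**Wald ratio.** β̂ = β̂ᵧ/β̂ₓ with the first-order delta SE σᵧ/|β̂ₓ|. No
second-order term is used: at the instrument strengths this package
targets (F ≳ 29) the second-order contribution is negligible.

**IVW.** Inverse-variance-weighted mean of Wald ratios. The default report
is the multiplicative-random-effects flavour, whose SE is the fixed-effect
SE inflated by max(1, √(Q/(n−1))) — the mainstream robust default in
two-sample MR; the fixed-effect flavour is always reported alongside. The
point estimate is identical in both and equals the slope of the
zero-intercept weighted regression of outcome on exposure betas with
weights 1/σᵧ². Calibration note: under a correctly specified homogeneous
null the *fixed-effect* z-test is the nominal 5% test; the
multiplicative-random-effects variant is conservative by construction
(its SE is floored, never shrunk), so calibration properties are stated
for the fixed-effect test.

**MR-Egger.** Weighted regression of outcome betas on exposure betas with
a free intercept, weights 1/σᵧ², after orienting each pair so the exposure
beta is non-negative. The intercept estimates directional pleiotropy; its
z-test is the pleiotropy diagnostic. Analytic SEs use the weighted fit
with a multiplicative dispersion floor max(1, σ̂) matching the IVW
convention. An optional parametric bootstrap (default 1000 seeded draws of
both betas from their sampling distributions) supplies a resampling SE for
the slope; the point estimate is always the analytic slope.

**Weighted median.** Wald ratios sorted ascending; with normalized weights
w′ⱼ and cumulative midpoints sⱼ = Σᵢ≤ⱼ w′ᵢ − w′ⱼ/2, the estimate linearly
interpolates the ratios at s = 0.5. Consistent when instruments carrying
more than half the weight are valid. SE by parametric bootstrap (default
1000 draws). Clamped to the extreme ratios when s = 0.5 falls outside the
midpoint range.

**Heterogeneity and diagnostics.** Cochran's Q with df = n−1 and an
upper-tail chi-square p; leave-one-out IVW per omitted variant.

**Outlier test.** For each instrument j, the causal slope θ₍₋ⱼ₎ is
re-estimated by IVW on the remaining instruments; the observed weighted
residual sum of squares Σ wⱼ(β̂ᵧⱼ − θ₍₋ⱼ₎β̂ₓⱼ)², wⱼ = 1/σᵧⱼ², is compared
to simulations that redraw the outcome betas from
Normal(θ₍₋ⱼ₎β̂ₓⱼ, σᵧⱼ²). Empirical tail p-values use the plus-one rule
(never exactly zero). Per-instrument outliers are Bonferroni-significant
squared residuals; the corrected estimate is IVW on the non-outliers. Two
deliberate simplifications: only outcome betas are perturbed (exposure
fixed), and the leave-one-out slopes are held fixed across simulations
rather than refit per draw. Both make the global test mildly conservative
and are immaterial at F ≳ 29.

**Steiger directionality.** Per-variant variance explained
r² = F/(F + n − 2), summed over instruments (LD between instruments is
ignored, defensible after clumping at r² < 0.001), compared between
exposure and outcome via a z-test on Fisher-transformed correlations. For
binary traits r² is taken on the log-odds scale with no liability-scale
conversion; the test is used only as a sign check on direction, for which
the scale does not matter.

**P-values and CIs.** All estimator p-values are two-sided normal and all
CIs Wald-type with z = 1.96, for consistency across methods (no
t-distributions).

## Selection details

Clumping is greedy by ascending p-value (ties broken by variant id for
determinism); each retained index variant removes remaining candidates on
the same chromosome within ±10 Mb with r² ≥ 0.001. The window is
index-variant-centred. Candidates absent from the LD matrix are treated as
uncorrelated but flagged in the audit. cis-pQTLs are significant variants
within ±1 Mb of the gene *body* (start/end, not TSS). Every removal at any
stage is recorded once in the audit trail with its stage and reason.

Harmonization drops palindromic variants unconditionally — no
frequency-based strand inference — and attempts strand-complement matching
before declaring a mismatch (complementing is safe precisely because
palindromes are already gone); complement-resolved records are flagged.
Variants absent from the outcome study are reported as dropped, not
silently skipped.

## Mediation

Two-step MR: step 1 (exposure→mediator) must pass p < 0.05 to proceed
(mediators failing the screen are reported as screened-out); mediators
with no cis-pQTL instrument are reported as not-estimable; step-2
significance is reported but does not gate the arithmetic. The indirect
effect β₁β₂ uses the first-order (Sobel) variance β₁²σ₂² + β₂²σ₁²; the
exact second-order variant (+σ₁²σ₂²) is available behind a flag and
differs by < 5% of the SE at the magnitudes this package targets. The
proportion mediated β₁β₂/β₀ is reported in percent without a CI (a
delta-method ratio CI is available behind a flag). Estimates from several
mediator datasets can be pooled by DerSimonian–Laird random-effects
meta-analysis (moment estimator of τ², truncated at zero) before the
mediation arithmetic.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors
labf = ½[ln(V/(V+W)) + z²W/(V+W)] with V = SE², W the squared prior SD
(0.15 for quantitative traits, 0.2 log-OR for case–control; no MAF-based
scaling), combined under the single-causal-variant-per-trait assumption
with per-SNP priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the cited method's
conventional defaults; configurable). All hypothesis sums are computed in
log space; the H3 mass p1·p2·(S1·S2 − S12) can cancel to ≤ 0 in floating
point and is then clamped to zero with a warning. A useful identity: adding
a constant to one trait's labfs rescales the H1, H3 and H4 weights
identically, so their posterior *ratios* are invariant (the absolute
posteriors are not, because the H0 weight is fixed at 1). The pipeline runs
colocalization only for mediators with an estimated, significant indirect
effect (configurable), over ±100 kb around the lead cis-pQTL.

## Synthetic generator

Summary statistics are simulated directly at the marginal level rather
than from individual genotypes: for standardized genotypes the expected
marginal beta vector of an LD block is R·b (R the block correlation
matrix, b the causal effects); the sampling SE of a variant is
1/√(2p(1−p)n) for quantitative traits and 1/√(2p(1−p)n·v),
v = n_case·n_control/n², for binary ones; estimation errors within a block
are correlated through the Cholesky factor of R. This reproduces the
downstream statistical structure (ratio estimators, clumping, coloc) at a
tiny fraction of the cost of genotype simulation.

Default study conditions mirror the motivating application: binary
exposure with 4,533 cases / 10,750 controls; quantitative mediator with
n = 21,758; binary outcome with 6,484 cases / 401,279 controls. Twelve
exposure loci are placed on distinct chromosomes (one lead plus two
satellites in an AR(1) block with ρ = 0.8, 5 kb apart); lead causal
effects are calibrated so expected instrument F statistics span 29–101
linearly. The mediator's cis region (21 SNPs, AR(1) ρ = 0.6, 4 kb
spacing) sits on chromosome 11 — never used for exposure loci, so the
cis/trans split is unambiguous — with one causal pQTL of β = 0.25 at the
center; the effect sizes make the lead overwhelmingly significant while
its r² < 0.001 neighbours stay sub-threshold, so step 2 resolves to a
single-instrument Wald ratio, mirroring the one-cis-pQTL design of the
motivating study. Truth values default to α = 0.066 (exposure→mediator),
δ = 0.2979 (mediator→outcome), τ = 0.0847 (direct), so the total effect
is β₀ = τ + αδ = ln 1.110 and the true mediated proportion is ≈ 18.8%.
MAFs are uniform on (0.1, 0.4); 10% of variants are palindromic; mediator
and outcome records are randomly allele-swapped (25%) or
strand-complemented (10%) so harmonization is genuinely exercised; the
exclusion list names every variant of one middle locus (whichever block
member wins clumping is then removed at the confounder stage, mirroring
the removal of one pleiotropic instrument in the motivating analysis).
Optional pathologies: n_pleiotropic loci receive an additional direct
outcome effect (assigned to every other locus starting at the second, so
that with 5 of 12 invalid the valid instruments still carry > 50% of IVW
weight — the weighted-median consistency premise); the default
pleiotropic effect 0.1 is a moderate violation, and robustness
experiments use 0.2 (≈ +1 on the Wald-ratio scale).

One integer seed drives everything through a fixed draw order; identical
scenarios produce byte-identical studies and pipeline reports.

The coloc simulator generates one AR(1) region (default 50 SNPs,
ρ = 0.5, n = 20,000 per trait, effect 0.15 SD) for two quantitative
traits with a shared central causal variant, two distinct causal variants
a half-region apart, or none.

**What passing tests show — and don't.** The generator matches real GWAS
summary data in its first two moments and LD-induced error correlation,
which is what the ratio estimators, clumping, the outlier test and ABF
colocalization consume. It does not model: case-control ascertainment
beyond the 1/√(npqv) approximation, liability-scale attenuation,
sample overlap between studies, population stratification, MAF-dependent
effect-size distributions, allele-frequency estimation error, or
imputation quality. Passing calibration/recovery tests therefore validate
the statistical machinery, not robustness to those real-data artefacts.

## Validation problem sizes

Monte-Carlo checks in the test suite use: 1000 replicates for IVW type-I
error under the null scenario (τ = α = δ = 0; fixed-effect IVW, band
0.035–0.065); 500 replicates for delta-method CI coverage (≥ 90%) with
the mediated-proportion median taken over the first 200 estimated
replicates (within ±0.03 of truth); 200 replicates for weighted-median
vs IVW robustness at 40% invalid instruments; 100 replicates each for
outlier detection (10-SE displacement; ≥ 95% flagged, ≥ 90% improved by
correction) and colocalization mode identification (≥ 90% top
hypothesis); 200 replicates for Steiger directionality (≥ 99% correct on
testable replicates). These sizes keep the full suite under ~10 s on one
CPU while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- Single-mediator, single-region analysis; no multivariable MR
  "difference method" mediation, no joint multiple mediators.
- No proxy-SNP lookup for variants missing from the outcome study.
- The ABF colocalization assumes at most one causal variant per trait in
  the region; no fine-mapping or conditioning.
- The Steiger r² for binary traits is a log-odds-scale approximation.
- LD handling is matrix-based only; the package never computes LD from
  genotypes.
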