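# Methods

## Generative model

`generate_cohort` simulates individuals with integer ages A uniform on
[40, 69], genotype hard calls G_j ~ Binomial(2, maf_j), a standard-normal
unobserved confounder U, sex ~ Bernoulli(0.5) and a genotyping-chip
indicator (10% on the minor array). The quantitative trait is

    X = β₀ + β_age·A + Σ_j (β_g_j + θ_j·(A − age_ref))·G_j + β_u·U + u,
    u ~ N(0, σ²)

with defaults age_ref = 40 (so β_g is the per-allele effect in the
youngest stratum), σ = 1 trait unit, maf = 0.4. θ_j — trait units per
allele per year — is the generative quantity the meta-regression stage
estimates. Ages are generated as integers rather than a continuous
uniform: the two-year stratification grid then partitions ages exactly and
stratum mean ages are exact sample means. Genotypes carry no dosage
uncertainty; an INFO-style field is metadata only. Alleles default to A/G
(non-palindromic) so harmonization is exercised without strand ambiguity.

Selection scores are

    S = δ₁·A + δ₂·A·X + δ₃·X + δ₄·U + v,   v ~ N(0, noise_sd²)

and exactly round(missing_fraction·N) individuals are flagged unselected
by rank of S (default: highest S removed; a `direction` flag supports the
opposite convention of keeping the highest-S half, since both appear in
practice). Ties are broken by ascending individual id for determinism, and
`noise_sd=0` gives a fully deterministic rank cut for testing. Selection
only flags rows; traits and genotypes are never modified.

Outcome GWAS summary statistics are drawn directly on the log-odds scale,
Γ̂_j ~ N(b_level·π_ref_j + b_rate·θ_j, se_j²): `b_level` couples the
outcome to the SNP's trait effect at the reference age, `b_rate` to the
rate of change of that effect with age. Covariate effects and
liability-scale details of a real binary-outcome GWAS are deliberately
absorbed into the noise model. Attendance at a repeat assessment is
Bernoulli with logit p = α + (b_trait + b_trait_age·(A − age_ref))·X.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent unless a test constructs correlated dosages explicitly),
relatedness and population structure, genotype imputation error,
non-linear age trajectories, cohort/generational effects, and real
participation mechanisms. Passing tests therefore demonstrate correctness
of the estimators under the stated model, not robustness to those
real-data features.

## Stratified association scans

`assoc_scan` fits OLS of the trait on each SNP plus covariates (default
age, sex, chip; within two-year strata the age covariate is retained but
switchable, since within-stratum adjustment is a judgment call). A linear
mixed model adds nothing here — the synthetic cohorts contain no
relatedness or structure for a random effect to absorb — so OLS is the one
intentional methodological simplification relative to large-cohort
practice. Implementation uses the Frisch–Waugh–Lovell decomposition (one
QR of the covariate block shared by all SNPs), which makes the 500-SNP ×
15-strata scans used in calibration runs take seconds; coefficients and
classical SEs are oracle-tested against statsmodels OLS at 1e-10.
Monomorphic or degenerate SNPs yield flagged null records rather than
errors. Stratum capping downsamples uniformly without replacement to the
reference stratum's size (stratum 7 by default); capping is drawn once per
cohort. Clumping is greedy: rank by ascending p (ties by variant id),
retain, drop everything with r² ≥ threshold to the retained variant,
repeat.

## Meta-regression

Per SNP, weighted least squares of the stratum betas on stratum mean age
with fixed-effect weights 1/se². An intercept is included by default: the
no-intercept display form would force the fitted line through age 0, far
outside the 40–69 range; `intercept=False` reproduces the
origin-constrained fit for comparison. SEs come from the weighted normal
equations without multiplicative rescaling (the fixed-effects convention);
residual heterogeneity is reported as QE, the weighted residual sum of
squares. Inference is z-based — with 15 strata a t reference would differ
little, and z matches standard fixed-effects meta-regression software
defaults. All classification thresholds (0.05, 5e-5, 5e-8, 0.05/n
Bonferroni) are strict inequalities. A SNP needs ≥ 3 usable strata;
missing strata produce a flagged fit on what is available.

Calibration at the study's scale (500 SNPs, stratum n ≈ 2,000): type-I
error of the interaction test is nominal within ±1.9 percentage points and
95% CI coverage of θ is nominal within 3 binomial MC SEs — both recomputed
by `scripts/acceptance.py` per run.

## Mendelian randomization

All point estimators follow the NOME convention — weights use the outcome
variance only; exposure SEs are carried for reporting. IVW is weighted
regression through the origin; a single variant degenerates to the Wald
ratio with first-order delta-method SE. Default SEs apply multiplicative
random-effects inflation max(1, √(Q/df)); `fixed_se=True` disables it
(software defaults differ on this point, so both are exposed). MR-Egger
re-orients variants so all exposure betas are non-negative before fitting,
without which the intercept is not invariant to allele recoding. The
weighted median interpolates the midpoint-weighted empirical CDF of the
Wald ratios at 0.5, with a parametric bootstrap SE (default 2,000
resamples, mandatory seed — there is no closed form). Harmonization drops
palindromic variants with allele frequency in [0.42, 0.58] (conventional
window) and logs every drop. The modified IVW is *exactly* the IVW code
path with δ̂_j substituted for the exposure beta — a substitution identity
asserted in the tests — so its estimate is in log-odds per exposure-unit
per year.

## Selection-bias simulation

Per replicate: generate a single-SNP cohort (MAF 0.4), remove 50% by rank
of S, split the observed sample into 4 equal-width age groups (equal-width
rather than equal-count: deterministic under selection), and fit OLS of X
on (1, G, A) per group — the within-group age covariate matching the
estimating equation of the stratified analysis. Reported per grid point:
mean γ̂₁ₐ, bias against the generating β_g, Monte-Carlo SE, and the
marginal R² of the missingness indicator regressed on G alone and on age
alone over the full pre-selection sample (marginal rather than joint
partitioning; G and A both act on missingness through X, so the two R²
are not additive).

Grid defaults were fixed once: δ₁ ∈ {0, 0.005}/yr, δ₂ ∈ {0, 0.01}/(yr·unit),
δ₃ ∈ {0, 0.5}/unit, δ₄ = 0.5, β_age = 0.005/yr, β_u = 0.5, β_g ∈ {0, 0.3},
n = 50,000, 200 replicates. The equality-at-δ₂=0 property is exact only
when the age gradient of the selection cutoff, (δ₁ + δ₃·β_age) per year,
is small against the selection-index noise; with ages in years this bounds
how large an age-additive selection effect the no-interaction regime
tolerates, and the defaults sit inside that regime (a cutoff drift of
≈ 0.2 SD of the index across the age range). With ranked selection the
overall scale of S is irrelevant; only ratios of the δ terms matter.

The attendance analyses mirror the repeat-clinic design: a
linear-probability model with age-group dummies and trait × group
interactions (5 groups), and logistic trait + age + trait×age fits overall
and within bins via IRLS (statsmodels GLM, deviance tolerance 1e-8, max 50
iterations; separation surfaces as a flagged non-convergent record).

## Pipeline, determinism, numerics

Stage seeds derive from the master seed as SeedSequence(master,
stage_counter), so any stage can be re-run in isolation; rerunning the
pipeline with one master seed reproduces byte-identical outputs, verified
by sha256 digests in the run manifest. Summary statistics travel as
tab-separated files with a fixed header and '.' for missing; the validator
checks types, se > 0, p ∈ (0, 1] and allele characters row by row.
P-values are floored at the smallest positive double rather than reported
as 0. Degenerate inputs (monomorphic SNPs, empty age groups, separation)
are flagged records, never exceptions, except where an estimand is
genuinely undefined (all exposure betas zero, empty variant intersection).

Problem sizes in the test and acceptance runs — 500 SNPs × 30,000
individuals for calibration, 3 grid points × 200 replicates × 50,000 for
the selection study, 5,000 × 50 for end-to-end smoke — were chosen so the
full suite completes in well under a minute on a single core while keeping
every Monte-Carlo band at its stated width.

## Known limitations

Only linear age trends are modelled (by design — the estimand is the
linear interaction slope); the OLS stand-in ignores relatedness; the
liability-scale transformation of linear-model statistics for binary
outcomes is out of scope (outcome summaries are generated directly on the
log-odds scale); clumping operates on a supplied r² matrix, not on a
reference-panel LD computation; and the weighted-median SE is a bootstrap,
so it carries seed-level variability (stable to ~5% at 2,000 resamples).
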