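# Methods

## The questionnaire and its encoding

The Morningness–Eveningness Questionnaire is a 19-item instrument; fifteen
items are multiple choice with fixed point values and four (questions 1, 2,
10, 18) are visual time scales marked by the respondent and scored by the
band of the scale the mark falls in. Per-item maxima sum to 86 and minima
to 16, and the loader enforces that range on any instrument file it is
given. The five-band typology (16–30 definitely evening, 31–41 moderately
evening, 42–58 intermediate, 59–69 moderately morning, 70–86 definitely
morning) partitions the integer scale with inclusive boundaries.

The instrument is shipped as a versioned YAML data file rather than code so
translations or variants with identical scoring can be dropped in. Time
scales are expanded to 15-minute tick options, reflecting how the printed
scales are actually administered: each tick is scored by the published band
containing it (a tick on a band boundary takes the earlier listed, i.e.
more morning-oriented, band — the printed scales are ambiguous there), and
the tick itself is the preferred time, so the earliest wake option is
exactly 05:00. Bedtimes past midnight are encoded as decimal hours greater
than 24 (01:30 → 25.5) so cohort mean bedtimes average correctly; this is a
representation choice, configurable by editing the instrument file's scale
blocks. Missing or out-of-range responses are refused with the item number
— in field practice single omissions are resolved by re-contacting the
participant, so the software never imputes.

## Kinship

The additive relationship matrix A = 2Φ is computed by the tabular
recursion in ancestors-first order: φ(i,i) = ½(1 + φ(f,m)) and
φ(i,j) = ½(φ(f,j) + φ(m,j)) for previously processed j, with φ involving a
missing parent equal to 0 — equivalently, each missing parent is a unique
unrelated founder. Diagonal entries are 1 + F with F the inbreeding
coefficient (e.g. 1.125 for the offspring of double first cousins, 1.0625
for the offspring of single first cousins; both are verified in the tests
against an independent discrete allele-dropping Monte-Carlo oracle).
Relative degrees are classified on the outbred expectation
(2φ = 0.5 / 0.25 / 0.125 → first/second/third degree, anything else
"other"). The matrix is stored dense: at the intended cohort scale (~10³
individuals) dense linear algebra is faster and simpler than sparse
handling, and disconnected families make it block-diagonal, which the
fitting code exploits.

## The polygenic model and its estimation

Phenotypic covariance is modelled as Ω = 2Φσ²ₐ + Iσ²ₑ with multivariate
normal phenotypes and fixed covariate effects Xβ. Writing σ²ₚ = σ²ₐ + σ²ₑ
and h² = σ²ₐ/σ²ₚ, Ω = σ²ₚ[h²K + (1−h²)I] with K = 2Φ. Estimation is plain
maximum likelihood (REML is available behind a flag but is not the primary
path): after rotating y and X by K's eigenvectors the likelihood separates,
β̂ is generalized least squares and σ̂²ₚ closed-form at every h², and the
resulting 1-D profile likelihood is maximized over h² ∈ [0, 1] by a
deterministic coarse grid (51 points) followed by bounded Brent refinement
to 10⁻⁸ — no randomness, so fits are bit-reproducible for a fixed input
order. Eigendecomposition is done family-block-wise when family labels are
supplied, after checking that the labels really block-diagonalize K.

Numerical conventions:

- h² estimates within 10⁻⁶ of 0 or 1 are flagged as boundary fits, not
  errors; K = I (or any flat-spectrum K) raises an "unidentifiable" error
  because σ²ₐ and σ²ₑ then exchange roles exactly.
- K must be positive semidefinite to a relative tolerance of 10⁻⁸; tiny
  negative eigenvalues are clipped to zero.
- The standard error of h² is the inverse square-root curvature of the
  profile log-likelihood (central second difference, step 10⁻³, one-sided
  at the boundary). The delta method is not needed because the profile is
  parameterized in h² directly. The choice of a curvature SE is a design
  decision; a Wald SE from the full information matrix would differ
  slightly.
- The test of h² = 0 is a likelihood-ratio test against the null fitted at
  h² = 0 (weighted OLS), referred to the boundary-corrected null — the
  50:50 mixture of a point mass at zero and χ²₁ — so p = ½P(χ²₁ ≥ Λ),
  which equals 0.5 at Λ = 0. A Wald test would give different p-values;
  the mixture LRT is the primary path.
- Age is z-scored (and age², sex×age built from the z-scored age) inside
  the optimization design for conditioning; reported β are re-estimated by
  GLS at the optimum against the natural-units design, which spans the same
  column space and therefore changes nothing else.
- Complete-case analysis per covariate model: rows missing the phenotype or
  any covariate the model uses are dropped before fitting, so n can differ
  across the four standard models. Relatedness is always taken from the
  full pedigree before subsetting, so unphenotyped connecting relatives
  still shape the matrix.

The standard suite fits four models: unadjusted; sex + age; sex + age +
age² + sex×age; sex + age + residence. The dense un-rotated likelihood
(`profile_loglik_direct`, `grid_search_direct`) is implemented separately
as a brute-force cross-check and is compared against the spectral path in
the tests.

## Descriptive layer

Group summaries pool exactly (within-group sums of squares plus
between-group dispersion), so printed subgroup rows reconstruct their total
column. Cohen's d defaults to the unweighted-variance standardizer
√((s₁² + s₂²)/2); the sample-size-weighted pooled-SD variant is available
(with groups as unbalanced as 729 vs 96 the two differ visibly, ~0.73 vs
~0.69 for the same means). The d confidence interval inverts the noncentral
t distribution of d√(n₁n₂/(n₁+n₂)) — asymmetric, as exact intervals for
standardized differences are; a symmetric normal-approximation interval is
provided for comparison, and for the unweighted standardizer the inversion
is the conventional pooled-df approximation. Two-sample t-tests from
summaries offer pooled (default) and Welch variants. The age trend is
ordinary least squares with the usual slope t-test; two points are
accepted (exact interpolation, p undefined). Q-Q coordinates use plotting
positions (i − ½)/n against standard-normal quantiles; histogram tables
report exact per-score counts within the 16–86 scale.

## The synthetic cohort generator

The generator exists so every estimator can be validated on data whose
generating process is exactly the model's assumption, plus the one known
violation of interest (the scale ceiling).

Pedigrees: independent families, each from a founder couple with
Poisson(mean sibship) + 1 children; in later generations each offspring
marries an unrelated founder with probability `mate_prob` and reproduces.
Defaults (112 families, 3 generations, mean sibship 2, mate probability
0.22) give ~820 individuals spanning first- to third-degree relatives,
matching the scale of a mid-size family cohort.

Phenotypes: additive values are gene-dropped (founders N(0, σ²ₐ); children
receive the parental midpoint plus segregation noise
N(0, σ²ₐ/2·(1 − (F_f + F_m)/2)), the inbreeding-adjusted Mendelian
variance), so their covariance is exactly 2Φσ²ₐ; environmental noise is
iid N(0, σ²ₑ). Covariates are drawn iid per individual — age truncated
normal 46.4 ± 16.3 on [18, 89], sex Bernoulli(0.602 female), residence
Bernoulli(96/825 rural) — and added with configurable coefficients
(defaults: 0.26 points/year, +1.8 male, +7.6 rural). Drawing ages iid
rather than by generation is deliberate: it makes covariate-variance
arithmetic exact (the omitted-covariate dilution
h²_marginal = σ²ₐ/(σ²ₚ + σ²cov) holds to within sampling error), whereas in
real cohorts age is confounded with pedigree position, which the model does
not represent. A `generational_ages` mode (each generation ~27 years
younger, jittered, truncated) exists for realism and is documented as
invented. The latent value is centered so the cohort mean sits at 63.5 on
the default variance scale (σ²ₐ = 49.4, σ²ₑ = 53.5, i.e. residual-scale
h² = 0.48 and total SD ≈ 11.2 including covariates); with `censor` on, it
is rounded and clipped to [16, 86], reproducing the ceiling distortion
visible in the Q-Q upper tail.

`calibrated_config(h2_adjusted, h2_unadjusted)` solves the
variance-inflation identity σ²cov = h²_adj/h²_unadj − 1 on a unit residual
scale and splits σ²cov between age (95%) and sex (5%), the split mirroring
the dominance of the age trend over the sex difference in the default
effect sizes; censoring is off there because heritability is invariant to
the affine scale mapping. An item-response allocator
(`responses_for_total`) greedily assembles a 19-answer vector for any
target total so scoring can be exercised end to end.

What passing the synthetic suite does and does not show: it validates the
estimators under the model's own assumptions (and under ceiling censoring,
whose attenuation is measured at under 0.05 at the default variance scale).
It cannot detect violations real cohorts bring — shared household
environment, assortative mating, age–pedigree confounding, spouse
correlation — none of which the two-component model represents.

## Problem sizes used in the checks

Replicate counts were chosen to keep Monte-Carlo error comfortably inside
the asserted tolerances: 100–200 cohorts of ~112 families for recovery
means (MC SE of the mean ≈ 0.007), 1.2–1.5×10⁵ allele drops for kinship
oracles (SE ≤ 0.002 per entry, compared at 3 SE), 500 replicates for the
null-calibration Kolmogorov–Smirnov check, 200 iid-noise fits for the
boundary-pileup bias bound.

## Known limitations

- Only two variance components; no household, dominance, or bivariate
  models, and no marker-based (GWAS/IBD) estimation.
- The unweighted-variance Cohen's d CI uses the pooled-df noncentral-t
  inversion as an approximation; an exact interval for that standardizer
  would require a Welch-type df.
- The residence classifier is a regex heuristic (street token followed by a
  house number → municipal) intended for Brazilian-style addresses; an
  explicit zone column always overrides it.
- ML variance components carry the usual O(p/n) downward bias relative to
  REML; at the intended n (~800) with ≤ 5 covariates this is negligible,
  and REML is available behind a flag.
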