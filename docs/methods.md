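# Methods

## Model and procedure

The package tests, per variant, the omnibus null hypothesis that a
K-vector of univariate GWAS z-scores **z**_j is multivariate normal with
mean zero and covariance **R̃**. The pipeline is:

1. **Trait preparation.** Each trait is OLS-residualized on an intercept
   plus all covariates (and, optionally, a global covariate such as total
   intracranial volume) in a single regression, then mapped to normal
   quantiles of its ranks, y′ = Φ⁻¹((r − c)/(N − 2c + 1)) with c = 0.5.
   Ties receive average ranks and therefore equal transformed values.
   Samples with any missing trait or covariate are dropped listwise before
   anything else, so all traits share the same N — a requirement of the
   shared-permutation scheme. Without the rank transform, heavy-tailed
   traits yield non-normal z-scores and an invalid omnibus null.
2. **Univariate GWAS.** Pearson correlation r between dosage and trait,
   t = r√(N−2)/√(1−r²), two-tailed p from the t distribution with N−2 df,
   and z = sign(r)·Φ⁻¹(1 − p/2). The t→z conversion goes through the
   p-value (not z := t) so tails are exact at small N. This is identical
   to the regression-slope t-test of the standard additive model. Missing
   dosages are mean-imputed per variant; complete-case analysis would give
   traits different effective sample sizes and break the shared
   permutation.
3. **Permutation null.** Each variant's dosage vector is shuffled once,
   with a per-variant RNG stream spawned from one master seed (results are
   independent of processing order), and the permuted vector is reused for
   all traits — preserving the cross-trait correlation of the null
   z-scores while destroying genotype–phenotype association.
4. **Calibration.** **R̃** is the correlation matrix of the permuted
   z-score columns (default), or of the prepared traits themselves — the
   two estimates agree under the permutation scheme, and the z-score route
   works in meta-analytic settings where traits live at different sites.
   The Mahalanobis statistics of the permuted rows are fitted with a
   gamma(a, b) by maximum likelihood (profile likelihood in the shape with
   Brent bracketing from a method-of-moments start); a moment-matching
   switch and a `tail_fraction` option to fit only the largest statistics
   exist but are off by default: the default fits all mass.
5. **Scoring.** X² = **z**ᵀ**R̃**⁻¹**z** with the (regularized) inverse;
   p is the fitted gamma's upper-tail probability. The gamma "CDF"
   description of the p-value is implemented as the survival function —
   the lower tail would increase with the statistic and is not a p-value.
   Everything is computed in log space (see numerics).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `c` (rank offset) | 0.5 | quantile offset of the inverse-normal transform |
| `r_reg` | 0 | eigenvalues floored before inverting **R̃**; a warning fires when the condition number exceeds 1e4; no automatic selection |
| `correlation_source` | permutation | `phenotypes` switches to the trait-correlation estimate |
| `tail_fraction` | 1.0 | fraction of largest permuted statistics used in the gamma fit |
| QC thresholds | 10% sample miss, 5% variant miss, HWE p ≥ 1e-9, MAF ≥ 0.005 | standard imputed-data pipeline values |
| clumping | p < 5e-8, r² ≥ 0.6 / ≥ 0.1, merge < 250 kb | FUMA SNP2GENE stages |

The min-P correction fits Beta(1, Meff) to the permuted per-variant
minimum p-values (MLE Meff = −n/Σlog(1−p), clipped to [1, K]) and corrects
the observed minimum as 1 − (1 − p)^Meff. Calibrating Meff on the same
permutation null as the omnibus test keeps the two comparators on an
identical footing.

## Synthetic data

`simulate_genotypes` draws biallelic hard calls: two haplotypes per
sample, each a latent Gaussian thresholded at Φ⁻¹(MAF). With `ld_decay`
ρ > 0 the latent process is AR(1) per chromosome, giving controllable
local LD (adjacent-pair r² is checked against a Monte-Carlo of the same
rule in the tests). `simulate_study` builds traits y = f(Gβ + ε):

- ceil(nc·T/t) causal variants drawn from the causal chromosome; trait
  subsets of size t are dealt round-robin from one random trait
  permutation, so every trait gets exactly nc effects and each causal
  variant touches t traits (non-integer nc·T/t rounds up with a warning);
- effects normal or standard Cauchy, cross-trait correlation via a
  Gaussian copula in the Cauchy case (the heavy-tail marginal has no
  moments, so "correlated Cauchy" is defined by its copula);
- residuals multivariate normal with an injectable correlation matrix;
  the default is AR(1) with coefficient 0.5, a parametric stand-in for the
  covariance of real anatomical trait panels, which is study-specific;
- per-trait residual variance Var(Gβ)(1−h2)/h2, so heritability is
  enforced before the link; the exponential link then distorts it — it is
  a non-normality stressor, not a generative model of real traits;
- `n_heritable` < T zeroes the effect columns of the remaining traits
  (pure noise, unit residual variance);
- `rank_deficient` replaces the T traits with all T(T−1)/2 pairwise
  **sums**: sums (unlike products) create exact linear dependence, which
  is the point of the stress case.

Default scenario sizes are desk-scale: N = 2,000, M = 20,000 with a
1,000-variant causal chromosome, K = 10 traits, nc = 10 causal variants
per trait, h2 = 0.05 per trait. The generator does not emulate realistic
allele-frequency spectra, long-range LD, population structure,
relatedness, or genotyping error, so passing tests demonstrate the
statistical machinery, not robustness to those artifacts.

Power-comparison operating points were chosen from the noncentrality
calculation before any runs: a causal variant explains h2/nc of a trait's
variance, so its expected z is ≈ √(N·h2/nc). The distributed scenario
(h2 = 0.05 → E z ≈ 3 per trait, omnibus noncentrality ≈ T·N·h2/nc ≈ 100
against a χ²₁₀ threshold of ≈ 66 at 5e-8) puts the omnibus test in its
favorable regime with min-P underpowered; the one-heritable-trait
scenario (h2 = 0.18 → E z ≈ 6 in the single signal trait, omnibus
noncentrality ≈ 36) reverses the ordering. Both give intermediate power,
where the comparison is informative.

## Numerical choices

- p-values are carried as log10 p alongside; the gamma survival function
  switches from `gammaincc` to its asymptotic expansion once the direct
  value underflows (below ~1e-280), keeping log p finite for arbitrarily
  extreme statistics (observed data can reach p ~ 1e-305).
- z ↔ p conversions use `ndtri_exp`/`log_ndtr`, exact in the far tail.
- Spectral regularization reconstructs **R̃**′ = U S′_r Uᵀ from the
  eigendecomposition; r = 0 is a strict no-op, r = K−1 yields λ_max·I.
- The Hardy–Weinberg exact test enumerates heterozygote counts
  conditional on allele counts in log space and sums configurations with
  probability ≤ observed (two-sided), with a 1+1e-12 slack on the
  comparison to absorb rounding; verified against an exact-rational
  enumeration oracle.
- Greedy clumping breaks p ties by (chrom, position, variant id);
  merged loci keep the lead with the smaller p.
- Degenerate inputs raise typed errors: constant traits (unrankable),
  collinear covariates (named), monomorphic variants (NaN row + warning),
  zero genetic variance with h2 > 0.

## Design choices on genuinely open points

- **Global covariate**: regressed out jointly with the other covariates
  in a single OLS (the two-pass alternative gives different residuals only
  when the global measure correlates with other covariates; the joint fit
  is the standard multiple-regression interpretation).
- **HWE test**: exact (conditional enumeration) rather than asymptotic
  chi-square — the exact test is the default in standard genotype-QC
  tooling and is well-defined at rare-allele counts.
- **Rank-deficiency demonstration**: the regularization stress test runs
  on the raw pairwise-sum features without the rank transform. The
  derived features are Gaussian by construction, and the strictly
  monotone rank mapping would break the *exact* linear dependence the
  case is designed to exhibit; with only approximate dependence the
  fitted gamma self-calibrates at desk scale and the distortion retreats
  into tails that need millions of null variants to observe.
- **K = 1 identity**: with one trait, X² = z² and the theoretical
  gamma(1/2, 2) null makes the omnibus p equal the univariate p exactly;
  the fitted-gamma default reproduces it only up to fit noise, so the
  `theoretical_null` option exists for exact collapse.

## Known limitations

- No effect directions from the omnibus statistic — it is a p-value-only
  test.
- Hard-call genotypes only; no dosage/BGEN input, no mixed models,
  relatedness correction, or case/control traits.
- Meff-based min-P correction is itself permutation-calibrated; with very
  few variants the Beta fit is noisy (a warning fires below 10·K rows).
- The gamma tail extrapolates far beyond the permutation support (one
  permutation per variant gives M null statistics; claims at p ≪ 1/M rest
  on the gamma form being correct).
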