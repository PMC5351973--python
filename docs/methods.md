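# Methods

This note records the models `gwsel` implements, the choices made where the
design was genuinely open, and what the synthetic-data experiments do and do
not demonstrate.

## Trial models and variance components

Two mixed models cover the two trial designs:

* germplasm bank (randomized complete blocks):  `Y = Xr + Za + Wp + e`
* diallel (adds full-sib family deviations):    `Y = Xr + Za + Wp + Tf + e`

with `r` fixed block effects, `a` random additive genotype effects
(covariance = identity or a genomic relationship matrix), `p` the random
block×genotype (plot) term, `f` random family effects and `e` the residual.
When every plot cell contains at most one observation, `p` is confounded
with `e` and is dropped with a warning (overridable).

**Estimator.** The default is EM-REML on Henderson's mixed-model equations:
at small n it is slow but extremely robust, keeps every component
nonnegative, and its restricted likelihood is non-decreasing at every
iteration (exposed in the `trace` attribute and asserted in the tests).
Single-random-term models use a spectral fast path (absorb the fixed
effects, eigendecompose once, O(q²) per sweep).  Because EM approaches a
zero boundary as a 1/t crawl, every fifth iteration a guarded Aitken
delta-squared extrapolation is attempted: the jump is kept only if the
restricted likelihood does not decrease, which preserves the monotonicity
guarantee while converging boundary cases in tens rather than thousands of
iterations.  Convergence is declared when the largest component change is
below `tol` relative to the total variance (components that have collapsed
to the boundary stop gating convergence).

**Unconstrained mode** (`constrain=False`) maximizes the restricted
likelihood directly (Nelder–Mead started from the EM solution) with no sign
constraint.  The likelihood is evaluated on the fixed-effect complement
(null-space projection of X), which matters: a VanRaden G always carries
the ones vector in its null space, so requiring positive definiteness of
the full covariance would wrongly forbid negative residuals that the
restricted likelihood itself allows.

**Genetic parameters.** h² = σ²ₐ/σ²ₚ with σ²ₚ the sum of the *fitted*
components; CVg = 100·√σ²ₐ/mean, CVe = 100·√σ²ₑ/mean, CVr = CVg/CVe.
Negative components (unconstrained fits) make the corresponding CV
undefined (NaN with a warning); a zero residual makes CVr infinite.

**Half-sib conversion.** When the genotype term indexes half-sib families
(open-pollinated accessions measured as plot means), the additive variance
on the individual scale is the Falconer conversion σ²ₐ = 4·σ²_family
(`additive_multiplier=4`).  σ²ₚ remains the observational component sum, so
with plot-mean records and a small residual the reported h² = 4σ²_f/σ²ₚ can
exceed 1.  This is deliberate: it reproduces the classic small-n pathology
of subtraction-style estimation (an implied residual σ²ₚ − σ²ₐ − σ²_b < 0),
which with ~40 families and near-zero residual occurs in essentially every
replicate.  The package reports it rather than clipping it, because
recognizing the pathology is part of interpreting small-trial estimates.

**Indirect selection.** The break-even genomic cycle length is
L_Y = (r_A/H_X)·L_X, with r_A the genomic prediction accuracy, H_X the
phenotypic-selection accuracy, and L_X the phenotypic cycle length.  What
to use for H_X (√h² or another proxy) is left to the caller as an explicit
argument.

## Whole-genome regressions

All eight methods model the entry mean yᵢ = μ + gᵢ + εᵢ on the centered
allele-dose matrix Z (dominant presence/absence markers enter as {0,2} dose
equivalents; centering frequencies always come from the phenotyped
individuals only).

* **RR-BLUP / G-BLUP.**  Variance components by spectral REML: after
  projecting out the fixed effects, the restricted likelihood is profiled
  over δ = σ²ₑ/σ²ᵤ through the eigenvalues of the projected kernel; the
  optimum is located by root-finding on the analytic derivative, which
  pins δ to near machine precision and makes the RR-BLUP ≡ G-BLUP
  equivalence hold to <1e-6 between two independently estimated fits.
  RR-BLUP solves the marker-space penalized normal equations; G-BLUP works
  through the VanRaden matrix G = ZZ′/(2Σpⱼqⱼ) and predicts unphenotyped
  individuals through the off-diagonal block.  Marker effects are recovered
  from a G-BLUP fit by the unique RR-consistent backsolve β = Z′α/c.
* **Bayesian alphabet (BRR, Bayes A, Bayes B, Bayes Cπ, BLASSO).**
  Single-site Gibbs samplers (numba-compiled, Fortran-ordered marker
  matrix).  π is always the probability a marker has zero effect.  Variance
  priors are scaled inverse chi-square with ν = 4; scales default to a
  prior-R² = 0.5 heuristic (prior mode of the residual = (1−R²)·var(y);
  prior mode of the marker variance = R²·var(y)/Σvar(zⱼ), inflated by
  1/(1−π) for the spike-and-slab models).  BLASSO uses β ~ N(0, σ²ₑτ²ⱼ),
  Exp(λ²/2) on τ²ⱼ via the inverse-Gaussian conditional, Gamma(1.1, rate)
  on λ², and the residual prior scale 1 with 4 degrees of freedom.  The
  default chain is 20,000 burn-in + 40,000 iterations thinned by 10.  A
  split-chain drift flag (report-only) replaces visual trace inspection.
* **RKHS.** Gaussian kernel K = exp(−h·d²/median(d²)) on Euclidean
  dose distances (median over phenotyped individuals), fitted with the
  G-BLUP machinery; default bandwidth h = 1 (single kernel).

Degenerate inputs return valid null fits (constant y → zero effects), so
cross-validation loops never die on a pathological fold.

## Cross-validated prediction ability

Folds partition plants into k groups of near-equal size (default k = 5).
For each fold the validation phenotypes are masked (NaN); matrix methods
carry the validation genotypes inside the kernel (their phenotypes never
enter), marker methods center validation genotypes by training-fold
frequencies.  Ability is the Pearson correlation of GEBV with the held-out
phenotype; undefined correlations (zero variance) are excluded from means,
not zero-imputed.  The validation phenotype is the plant-level entry mean
(block effects average out in complete designs; `adjusted_means` provides
the OLS-adjusted version for incomplete ones).

**A calibration subtlety.**  For a fixed phenotype vector the per-fold
abilities are strongly correlated: the realized alignment of y with the
leading eigenvectors of G is frozen, so a single h² = 0 dataset can show a
mean "ability" of ±0.4 with a deceptively small fold-based SE.  Null
calibration is therefore always judged across independently simulated
traits (fresh phenotype per repeat), and that is how the package's null
tests are written.

## Marker-density study

At each step the loop fits G-BLUP on the current panel, backsolves marker
effects, records 5-fold CV ability (mean and SE over `reps` repetitions
with fresh fold seeds), the genomic h², and the genetic/residual variance,
then drops the marker(s) with the smallest |effect| (ties broken by marker
id).  The exact schedule removes one marker per step; the default geometric
schedule removes ~1–5% of the current panel per step, tracing the same
curve at logarithmically spaced counts in a fraction of the time.  The
"sufficient density" is the smallest count whose ability is within one SE
of the curve maximum.

**Known limitation — selection bias.**  Ranking markers on the *full-data*
fit (the protocol this module reproduces) leaks phenotypes of future
validation folds into marker selection.  On pure-noise phenotypes the CV
ability is correctly ~0 at the full panel but climbs steeply once
elimination starts (measured ≈0.84 at intermediate counts, averaged over
independent noise datasets) — the classic selection-without-refolding
artifact.  Two practical consequences: density-curve abilities are
optimistic at intermediate and small counts (which is also why such curves
can approach 1 on real data), and the apparent ability peak shifts slightly
*below* the true causal marker count (a planted 300-causal panel yields
sufficient densities of roughly 200–300 across seeds).  An unbiased curve
would require re-running the entire elimination path inside each training
fold; that estimator answers a different question and is out of scope here.

## Synthetic data

Founders are unrelated, markers unlinked, frequencies uniform on the
configured range, genotypes Hardy–Weinberg; a configurable fraction
(default 50%) are dominant presence/absence markers scored 1 when at least
one copy of the marker allele is present.  Diallel progeny are produced by
per-marker Mendelian gamete sampling from the founders' latent doses.  QTL
are a random marker subset with normal effects rescaled so the realized
additive SD is exact; the residual SD is set from the target h² on the
realized additive variance, and diallel family deviations (variance =
`dominance_ratio`·σ²ₐ, rescaled exactly) model dominance at the family
level.  Everything is a pure function of (config, seed).

The study-like bundle is 36 genotyped founders (2 blocks) plus a complete
diallel of 3 contrasting founders (3 families × 14, 5 blocks): 78 plants ×
1,248 markers, GY with target h² 0.27 (mean 740, additive SD 97) and W100S
with target h² 0.35 (mean 62, additive SD 3.4) — scales chosen to give
realistic genetic and residual coefficients of variation for a seed crop.
The default architecture is 100 QTL (oligo-polygenic).

What the generator does *not* emulate: linkage and LD (markers are
independent, so density curves here reflect sample-size and selection
effects, not map saturation), genotype-by-environment interaction,
multi-year repeatability, genotyping error beyond the dominant-scoring
information loss, and pedigree errors.  Passing tests therefore demonstrate
correctness of the estimators under the stated architecture, not field
performance.

## Scaled profiles

Tests and the acceptance script use reduced problem sizes chosen to keep a
complete run at desk scale: sampler chains of 500/1,500 (tests) or
2,000/4,000 (acceptance script) instead of the 20,000/40,000 default;
geometric 5–10% elimination batches instead of one-at-a-time; 3–5 CV
repetitions per density record instead of 50.  The full-scale settings
remain available as the pipeline's `--study-profile` preset.  Component
recovery studies use 500 genotypes × 2 blocks (variance components), 20
fixtures of 80 × 300 (model equivalence), and a 300-plant, 1,200-marker
panel with 300 equal-effect QTL (plateau detection).
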