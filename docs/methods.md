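# Methods

## Model

Each nuclear family contributes two full siblings. For sibling i of family
f, trait k is

    y_k(i) = x(i)·α_k + p(f)·β_k + ε_k(i)

where x(i) is the individual's standardized genotype row (M SNPs), p(f) the
standardized sum of the parents' dosages (shared by both siblings), α_k and
β_k per-SNP direct and indirect effect vectors, and ε_k(i) an error term.
Per SNP, the effect 4-vector (α₁, α₂, β₁, β₂) is i.i.d. N(0, Ω/M); Ω holds
the ten genetic parameters (two direct variances, two indirect variances,
ρ_α, ρ_β and the four direct–indirect covariances). Per family, the error
4-vector (ε₁ sib1, ε₁ sib2, ε₂ sib1, ε₂ sib2) is Gaussian with within-trait
blocks [[σ²_{εk}, ρ_{εk}], [ρ_{εk}, σ²_{εk}]] and cross-trait blocks
[[η, δ], [δ, η]]. Both 4×4 matrices must be positive semi-definite
(eigenvalue tolerance −1e−10); `validate_parameters` enforces this, and the
simulator accepts exactly the parameter sets the validator accepts.

Assumptions worth keeping in mind: additivity (no dominance or epistasis),
random mating, SNP independence in the simulator (no LD), exactly two
siblings per family, no sibling-to-sibling effects, and a single combined
parental path — maternal and paternal effects are not separated, except in
the simulator's split-parent mode used to test the averaging identity
below.

## Standardization conventions and error variances

Genotype columns are standardized to in-sample mean 0 and variance 1;
missing dosages become exactly 0 after centering. The parental-sum columns
are standardized to variance 2 by default (`Convention("var2")`): the sum of
two independent unit-variance genotypes naturally has variance 2, and under
random mating the child–parental-sum covariance is then exactly 1. The
alternative `var1` convention scales parental sums to unit variance
(child–parent-sum covariance 1/√2). The convention fixes the nominal
diagonals (d_X, d_P, d_C) = (1, 2, 1) or (1, 1, 1/√2) used in the diagonal
subtractions below.

Because traits are standardized to unit variance, error variances are
derived, not estimated: σ²_{εk} = 1 − (σ²_{αk}·d_X + σ²_{βk}·d_P +
2ρ_{αkβk}·d_C). Note the tension this creates under var2: the modeled
genetic variance contains 2σ²_{βk}, while the reconstruction below reports
h²_k = σ²_{αk} + σ²_{βk} + 2ρ_{αkβk} with a unit coefficient on the
indirect term. Both quantities are computed and reported (`FitResult`
carries `model_variance_k` alongside `h2_k`); the estimator–simulator pair
is self-consistent in the 14 parameters under either convention, and we do
not take a position on which combination equals a population-scale
heritability. A negative implied error variance after fitting is reported
with a warning, never clamped.

## Estimation

The model implies cov(y) = I + Σₛ Θₛ Ṽₛ for the stacked 4N-vector
y = [Y₁; Y₂]. All 14 relatedness matrices are block-structured over the
2N×2N matrices K = XXᵀ/M, G = PPᵀ/M, C = XPᵀ/M and the sibling indicator S:
variance-type parameters place K − d_X·I, G − d_P·I, C + Cᵀ − 2d_C·I or S on
their trait's diagonal block (the diagonal subtraction implements the
error-variance substitution; it applies only to the block where the
parameter acts), and cross-trait parameters place K, G, C, Cᵀ, I or S on the
off-diagonal block.

Minimizing ‖yyᵀ − I − Σₛ Θₛ Ṽₛ‖²_F gives normal equations AΘ = B with
A_{st} = tr(ṼₛṼₜ) and B_s = yᵀṼₛy − tr(Ṽₛ). Products of a within-trait and
a cross-trait placement have zero diagonal blocks, so A decouples into a
4×4 within-trait block (shared by the two traits) and a 6×6 cross-trait
block; everything is computed from the 2N×2N blocks without materializing
4N×4N matrices (a dense path exists for oracle tests and small data). The
system is solved symmetrically; if the condition number exceeds 1e8 the
solver falls back to minimum-norm least squares and flags the fit. No
constraints are imposed on the estimates — method-of-moments estimates may
leave the PSD region, and PSD status is reported rather than enforced.
Phenotypes are standardized in-sample before fitting; fixed-effect
covariates Z are removed by multiplying with a Q whose rows orthonormally
span the null space of Zᵀ (from the SVD), applied identically to both
traits; each relatedness block A becomes QAQᵀ and the projected traits are
rescaled to unit mean square (no re-centering — with an intercept in Z the
projected space has no mean direction).

Two small systematic effects of these choices are documented rather than
removed: in-sample standardization couples the scale of y across families,
and covariate projection removes c directions, attenuating family-local
covariances by O(c/N) (about 7×10⁻⁴ for the sibling-error covariance at
N = 300, c = 2 — an order of magnitude below the estimator's sampling
noise at that size).

## Uncertainty

Analytic variances of quadratic-form estimators can be unstable at
realistic N, so standard errors come from a delete-one-block jackknife,
var(Θ̂ₛ) = (B−1)/B · Σ_b (Θ̂_{s,b} − Θ̄ₛ)², with Wald z = Θ̂/SE, two-sided
normal p-values, and Benjamini–Hochberg FDR across the parameters of a run.

The resampling axis matters, and the package implements both:

- **SNP blocks (default).** The averaging units of the moment estimator are
  SNPs — the random effects are per-SNP, and K, G, C are SNP averages.
  Deleting a SNP block rescales K, G, C; every leave-block-out system is
  recovered exactly from SNP-space Gram matrices (e.g. tr(K_J G_J) =
  Σ_{j,k∈J}(x_jᵀp_k)²/|J|², for kept set J), so the whole jackknife costs
  one extra column-space Gram product. In repeated-simulation studies this
  axis is well calibrated: SE/SD ratios near 1 for all 14 parameters and
  null rejection rates at the nominal level.
- **Family blocks.** Families are the sampling units of the data, and
  blocks never split a sibling pair (contiguous blocks after a seeded
  shuffle, so ordered input is safe). Leave-block-out systems are computed
  by exact downdating of the trace and quadratic-form sums, verified
  against explicit refits. This axis is exact for family-local information
  (e.g. the sibling error covariances) but systematically conservative for
  the genetic covariance parameters: their identification rests on
  cross-family realized-relatedness contrasts, which enter the moment
  equations as pair products y_i y_j K_ij; a delete-block jackknife counts
  every pair spanning two blocks twice (the degenerate-U-statistic
  inconsistency), inflating those SEs by up to √2 at any M. We measured
  SE/SD ratios of 1.3–1.7 and near-zero null rejection rates with this
  axis at desk scale, with full per-block refits (re-standardizing
  everything) behaving identically to the downdated path.

Calibration studies and the acceptance script therefore use SNP blocks;
`axis="family"` remains available for sensitivity analysis. The default
block count is min(100, axis size); studies in this repository use B = 50.

## Parental-sum imputation

When parents are unobserved, `impute_parental_sum(g1, g2, p)` returns
E[G_f + G_m | g1, g2] by exact enumeration of the nine parental genotype
pairs with Hardy–Weinberg priors {(1−p)², 2p(1−p), p²} and Mendelian
transmission likelihoods, siblings conditionally independent given parents.
It satisfies the total-expectation identity Σ P(g1,g2)·E[sum|g1,g2] = 4p
exactly and the forced value E[sum | 0, 2] = 2. This is a deliberate
single-SNP simplification: multi-SNP, IBD-aware imputation is out of scope,
and because two siblings carry limited information the imputed contrast is
shrunk, attenuating indirect-effect components relative to fits on observed
parental sums (which the estimation studies use). A missing sibling dosage
is treated as uninformative in the enumeration.

## The simulator and what passing tests mean

`simulate_families` draws allele frequencies uniformly on [0.05, 0.5]
(mirroring a MAF ≥ 0.05 analysis filter), parents as Binomial(2, p) under
Hardy–Weinberg, and children by explicit Mendelian transmission (each
parent passes one allele with probability dosage/2, independently per child
and SNP). `simulate_phenotypes` draws effects from Ω/M and family error
vectors from the error covariance, then standardizes traits in-sample; with
`standardize_traits=False` the conditional covariance of y given genotypes
equals I + Σ Θₛ Ṽₛ exactly, which is tested against Monte-Carlo family
blocks. In split-parent mode trait 1 uses separate paternal and maternal
effect draws on separately standardized parental dosages; fitting the
combined model then targets var((β_p + β_m)/2), the averaging projection
identity, verified by simulation (σ²_{βp} = 0.2, σ²_{βm} = 0 recovering
0.05). All randomness flows through one seeded generator; identical seeds
give bit-identical cohorts and phenotypes.

What the simulator does not emulate: linkage disequilibrium, assortative
mating, population structure, genotyping error, or imputed-parent noise
correlated across SNPs. Passing calibration tests show the estimator and
its uncertainty are correct under the stated model; they do not address
biases those real-data features can introduce.

## Study sizes and reference settings

Preset parameter settings live in `parsec.presets`: a full 14-parameter
setting with realistic magnitudes (direct variances 0.2–0.3, indirect
variances ~0.05, sibling shared environment 0.15–0.2) and a null setting
identical in spirit but with ρ_α = 0. The repository's studies use: type-I
error, 200 repeats × 500 families × 500 SNPs, B = 50; unbiasedness and SE
calibration, 100 repeats × 1000 families × 1000 SNPs, B = 50; averaging
identity, 100 repeats × 1000 families × 500 SNPs; covariate invariance, 50
paired repeats × 300 families × 300 SNPs. These sizes give Monte-Carlo SEs
small enough for 3-SE checks while keeping the full suite in the tens of
minutes on one CPU.

## Known limitations

- Genetic-correlation (as opposed to covariance) estimates are not
  produced; ratios of noisy estimates are unstable at these sample sizes.
- Binary traits, >2 siblings, separate maternal/paternal fits, LD-aware
  relatedness and IBD-based imputation are out of scope.
- The family-block jackknife's conservativeness for covariance parameters
  is inherent to that resampling axis (see above), not fixable by larger B
  or by re-standardizing refits.
- With M ≫ N the structural parts of the K, G, C columns become collinear
  (K ≈ I + S/2, G ≈ 2I + 2S, C ≈ I + S within families); identification of
  the cross-trait parameters then rests entirely on realized-relatedness
  fluctuations, and the solver's condition-number fallback may trigger.
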