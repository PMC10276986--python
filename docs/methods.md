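# Methods

This note documents the statistical model behind the package, the
parameters that matter, the numerical and design choices taken where more
than one reasonable option existed, and what the simulation-based tests do
and do not establish.

## Statistical setting

For m tested markers with p-values p₁…p_m, a multiple-testing procedure
rejects R hypotheses of which FP are true nulls; the false discovery
proportion is FDP = FP / max(R, 1) and the FDR is its expectation. The BH
step-up rule rejects the k smallest p-values with
k = max{i ≥ 0 : p₍ᵢ₎ ≤ iα/m}; under independence (and PRDS dependence) it
controls the FDR at π₀α ≤ α, where π₀ is the true-null proportion. The
weighted variant applies the same rule to pᵢ/wᵢ for non-negative weights
with Σwᵢ = m, which preserves FDR control for weights independent of the
null p-values.

### The wBHa weight family and exponent selection

Weights are a one-parameter family of the covariate,
wᵢ(a) = m·xᵢ⁻ᵃ / Σⱼ xⱼ⁻ᵃ. With x = MAF, larger exponents concentrate
weight on rarer markers; a = 0 is plain BH. The exponent is selected by
maximizing the number of weighted-BH rejections over the grid
a = 0, 0.1, …, 10, with bagging for stability: K = 100 bootstrap rounds
each draw ⌊m/K⌋ hypotheses with replacement (minimum 1), the grid search
runs on the subsample, and the final exponent is the arithmetic mean of
the K per-round winners (each winner lies on the grid; their mean need
not).

Three aspects of the round-level search were genuinely open and are
resolved as follows:

- **Weight normalization inside rounds.** Each round scores hypotheses
  with their *full-set* weights m·xᵢ⁻ᵃ/Σⱼ₌₁..ₘ xⱼ⁻ᵃ (the step-up
  threshold uses the round's sample size). Re-normalizing weights within
  the small subsample was considered and rejected: for exponents whose
  weight mass concentrates on hypotheses outside the subsample, a
  subsample-normalized search keeps crediting rejections the full-data
  procedure could never make, biasing the selected exponent upward. The
  effect is large for heavy-tailed covariates — in the reference design
  with an uninformative U(0,1) covariate, subsample normalization drives
  the mean exponent to ≈0.84 and costs ≈17% of BH's power, while full-set
  normalization yields ≈0.40 and essentially no power loss.
- **Uninformative rounds.** A round whose rejection count is zero at
  every grid value carries no information about a and contributes the
  neutral exponent 0. Without this rule, sparse-signal studies (where most
  subsamples of ~m/K hypotheses contain no signal) would tie across the
  whole grid, resolve to the grid maximum, and drive the averaged exponent
  so high that overall power collapses by an order of magnitude.
- **Tie-breaking.** When several exponents achieve the (positive) maximal
  rejection count, the tied values are split into runs of consecutive grid
  points (a gap above 1.5 grid steps starts a new run, so floating-point
  drift cannot split a run). A single run returns its maximum; otherwise
  the longest run (by number of grid points — equivalent to span on a
  constant-step grid) wins and its maximum is returned; runs tied for
  length are ranked by the distance of their nearest endpoint to 1, with
  the larger maximum breaking any remaining tie. Duplicate values are
  removed before tie-breaking.

Reproducibility: one root seed; round k draws from an independently
spawned seed-sequence child, so at a fixed per-round sample size the first
rounds are unchanged when K grows.

### π₀ estimation and the adaptive step-up

The Storey-type estimator computes π̂₀(λ) = #{pᵢ > λ}/(m(1−λ)) on the grid
λ = 0.05, …, 0.95 and smooths with a cubic smoothing spline
(`scipy.interpolate.UnivariateSpline`, k = 3, default smoothing)
evaluated at λ = 0.95, clipped to (0, 1]. With fewer than 20 p-values the
spline has no support and the estimator falls back to the conservative
π̂₀ = 1 with a warning. The adaptive procedure is BH at the effective
level α/π̂₀ (equivalently, q-value ≤ α); since π̂₀ ≤ 1 it never rejects
fewer hypotheses than BH.

## Generative model

One simulated study is parameterized by `SimulationDesign`:

| parameter | default | meaning |
|---|---|---|
| n | 2000 | individuals |
| m | 8000 | markers |
| m1 | 25 | causal markers |
| rho | 0 | within-block latent equicorrelation, in [0, 1) |
| block_size | 10 | markers per correlation block |
| trait | quantitative | quantitative or binary phenotype |
| scenario | 1 | effect-size regime (see below) |
| r_squared | 0.2 | target coefficient of determination (quantitative) |
| seed | — | root seed; the study is bit-reproducible given it |

**Genotypes.** Latent values are multivariate normal with block-diagonal
equicorrelation, simulated by the one-factor construction
√ρ·Z_block + √(1−ρ)·Z_marker (O(nm) cost, the full covariance is never
materialized). Each marker is discretized at the latent quantiles Φ⁻¹(p²)
and Φ⁻¹(1−(1−p)²), so expected genotype frequencies follow Hardy–Weinberg
equilibrium (p², 2pq, q²) for MAF p. (The quantile pair is the unique
choice consistent with HWE; a naive upper threshold at Φ⁻¹((1−p)²) would
give P(G=0) = 1−(1−p)², not (1−p)².)

**MAF structure.** Null-marker MAFs are U[0.01, 0.5]. Causal markers are
placed uniformly at random and split into four groups — rare U[0.01, 0.05],
medium-rare U[0.05, 0.15], medium U[0.15, 0.25], common U[0.30, 0.40] —
with ⌊m1/4⌋ markers each and the remainder in the common group. Random
placement means correlated designs can put several causal markers in one
block; the evaluation handles this via cluster units.

**Effects.** Per-group effect sizes (rare → common): scenario 1 gives
(4, 3, 2, 1) for quantitative traits and (log 2.2, log 1.8, log 1.5,
log 1.3) for binary; scenario 2 reverses the ordering; scenario 3 sets all
equal (2, resp. log 1.5). Null markers have effect 0.

**Phenotypes.** Quantitative: y = Gβ + ε with ε ~ N(0, σ²) and
σ² = (1−R²)·SS(Gβ)/(R²(n−2)), the variance-partition solution for the
target R² (implemented in this positive form; the residual variance is
common to all individuals). A design with no causal markers has a constant
genetic score, in which case σ² falls back to 1 (pure-noise phenotype)
with a warning. Binary: yᵢ ~ Bernoulli(expit(β₀ + Gᵢβ)) with β₀ solved by
root bracketing so the mean predicted prevalence is exactly 0.5 (balanced
cases/controls); the solver is exact to 10⁻¹², and realized case fractions
fluctuate binomially around ½.

A user-supplied 0/1/2 genotype matrix can replace the simulated genotypes
(semi-simulation seeded from real data): MAFs are then computed from the
matrix and causal markers drawn from observed-MAF bins (0.01–0.05,
0.05–0.15, 0.15–0.30, ≥0.30) in the same group proportions, with an error
if a bin cannot supply its quota.

**What the generator does not emulate:** realistic LD maps and
recombination, population structure and relatedness, genotyping error and
missingness, imputation artefacts, covariate confounding. Equicorrelated
blocks are a deliberately stylized stand-in for LD. Consequently, passing
tests demonstrate calibration and operating characteristics *under this
model*; on real data, effect direction and FDR behaviour additionally
depend on the features listed above (LD pruning is common practice before
FDR procedures on dense panels).

## Association scans

Quantitative traits: per-marker simple linear regression via the
closed-form identities (slope, SE, two-sided t-test on n−2 df), vectorized
across markers; p-values are invariant to affine rescaling of y.
Binary traits: per-marker logistic regression by a batched two-parameter
Newton–Raphson (linear predictor clipped to ±30; at most 25 iterations,
convergence at 10⁻⁸), two-sided Wald test on the slope. Monomorphic
markers, non-converged fits and (quasi-)separated markers (|β̂| > 15) are
conservatively reported with p = 1 and a warning. Both scans are
deterministic given (G, y) and are cross-checked against statsmodels
OLS/Logit in the test suite.

## Evaluation

Counting uses the FDP convention FP / max(R, 1). With correlated markers,
marker-level truth is ambiguous, so counting switches to cluster units:
connected components of the graph joining marker pairs with empirical
|Pearson correlation| ≥ 0.8 on the 0/1/2 codes, computed within declared
simulation blocks (O(m·B²) cost) or genome-wide for user data. A cluster
is causal if it contains a causal marker, rejected if any member is
rejected; a causal cluster with no rejected member counts as a false
negative, a null cluster with no rejection as a true negative. Subgroup
power stays marker-anchored under clustering: a causal marker counts as
detected when any member of its cluster is rejected. Summaries report
means and standard errors (sample SD/√replicates) over replicates;
replicate seeds derive from one root through a splittable seed sequence,
and replicates can run in parallel via joblib.

## Problem sizes used by the shipped tests

The test suite and the acceptance script use 100 replicates of the
n = 2000, m = 8000, m1 = 25 independent-marker design — enough for
Monte-Carlo standard errors of ~0.01 on power and FDR, which the
assertions account for explicitly (nominal level plus twice the MCSE).
Simulator calibration checks run at n = 20000 with a handful of markers;
the large-m code path is exercised for shape correctness at m = 20000.

## Known limitations

- The bagged exponent is a point estimate; no uncertainty is attached to
  it, and the final weights are treated as fixed in the weighted step-up.
  FDR control with data-adaptive weights is therefore approximate, though
  empirically tight in all tested configurations.
- Only one continuous covariate is supported, and the weight family is
  monotone in it; multi-covariate or non-monotone weighting is out of
  scope.
- The binary scan's Wald test can be conservative near separation (rare
  markers at small n); score or likelihood-ratio alternatives are not
  provided.
- Cluster-based counting depends on the 0.8 correlation threshold; at
  thresholds near the within-block correlation the partition is unstable
  between replicates.
- π̂₀ depends mildly on the spline smoothing; any smoother consistent at
  λ → 1 gives equivalent results at the tolerances tested.
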