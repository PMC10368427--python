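# Methods

`cortasym` implements a population-level analysis of cortical hemispheric
asymmetry as a tested pipeline over synthetic surface data with planted,
recoverable ground truth.  This note documents the models, the synthetic
data they are exercised on, the numerical choices, and the limits of what
the passing tests demonstrate.

## The asymmetry index

All stages work on the asymmetry index at homotopic locations,

    AI = (L − R) / ((L + R) / 2),

positive for leftward lateralization, bounded in (−2, 2) for positive
inputs, antisymmetric in its arguments and invariant to common positive
rescaling.  Where L + R = 0 the index is undefined and carried as NaN
through every downstream statistic rather than being zeroed, so degenerate
vertices cannot create sign artifacts.

Mean AI maps average subject-level AIs (longitudinal timepoints averaged
within subject first), not the AI of group-mean maps.  The two conventions
differ at second order in the vertex noise; the subject-level convention
matches the individual-difference analyses downstream, which operate on
per-subject AIs.

The vertex-wise hemisphere main effect is tested through the paired-
difference reduction of the two-row mixed model: within-subject L−R
differences regressed on an intercept plus centered covariates (age, sex).
Because every scan contributes both hemispheres, subject random intercepts
cancel exactly in the difference, so this is the mixed model's hemisphere
inference at a fraction of the cost.  The intercept is the hemisphere
effect at sample-mean covariates.

## Synthetic surfaces and the consensus algorithm

The shared template is an icosphere (subdivision 4, 2562 vertices,
10·4^L + 2 in general) rescaled to 9×10⁴ mm² — roughly one human
hemisphere — standing in for a symmetric registration surface.  Per-vertex
area is one third of incident triangle areas, so vertex areas partition
the total surface exactly; all cluster sizes are in mm² of this template.

Planted asymmetry fields are sums of geodesic caps with cosine falloff
(peak magnitude m at the center, 0 at radius r).  Caps give direct control
of patch location, extent and supra-threshold footprint, which spherical-
harmonic fields would not.  Subject maps are constructed as
L = μ(1 + a/2) + ε, R = μ(1 − a/2) + ε with baseline μ (per-vertex area
for the area metric, 2.5 mm for thickness) and i.i.d. Gaussian noise of SD
`noise_sd`·μ, so the expected vertex AI equals the planted field exactly.
The default configuration emulates a seven-sample consensus study: two
robust patches (|AI| peak 0.12, radius 30 mm), one patch present in only
five datasets, and one small patch whose supra-threshold footprint
(~100 mm² on this mesh) falls under the size filter.  The default
per-vertex noise (3% of baseline at n = 30 subjects per dataset) puts the
standard error of a dataset's mean AI at ≈ 0.008, well clear of the
discrete field's margin around the 0.05 threshold (nearest field values
0.044 and 0.0705), so consensus membership is stable; this is the
signal-to-noise regime the recovery tests assume.  Already-smooth fields
emulate the effect of surface smoothing of real data; no smoothing kernel
is applied.

Consensus pipeline order: binarize each dataset's mean AI map at
±threshold (closed at the threshold: ties count, for determinism; 0.05
for area, 0.01 for thickness), sum per direction, keep vertices reaching
`min_overlap` (default 6) datasets, split into edge-connected components
(shared-triangle-edge adjacency, the standard surface convention — not
corner adjacency), then drop components under `min_area` (200 mm²).  The
size filter is applied to the final consensus components; applying it to
per-dataset maps instead would be a different (and more permissive)
reading, and the choice is asserted by the recovery tests.  Leftward and
rightward maps are processed independently.

Per-subject cluster values are unweighted means of member-vertex L and R
values, with the cluster AI recomputed from the means.

## Lifespan trajectory model

For a cluster's hemispheric value y (one row per scan per hemisphere):

    y = β₀ + β_H·h + β_a·a + β_aH·a·h + sex + scanner [+ ICV]
        + s_L(age)·1[h=L] + s_R(age)·1[h=R] + b_subject + ε,

with h = ±1/2 hemisphere coding, a the standardized age,
b ~ N(0, σ_b²) shared over a subject's scans and hemispheres, and
ε ~ N(0, σ²).

**Basis.**  Each smooth uses a cubic B-spline basis with k = 6 basis
functions (interior knots at age quantiles, clamped boundary knots) under
a second-order difference penalty, in the mixed-model reparametrization:
the basis is sum-to-zero constrained over the fitting ages, the penalty
null space (the linear-in-age trend) is carried by the explicit β_a and
β_aH columns, and the remaining directions are whitened so the penalty is
exactly λ·I.  Consequently λ → ∞ drives each smooth to zero and the model
degenerates to hemisphere-specific straight lines — a property the tests
assert.  The smooth's span therefore differs from the raw B-spline span by
replacing the basis's approximate linear null vector with the exact linear
age term; the effective dimension is the same.

**Estimation.**  The two smoothing parameters and the subject-intercept
precision ratio are chosen by profiled REML.  With all penalized
coefficients collected in θ and S(λ) the block penalty,

    −2·l_r(λ) = (n − p₀)(log 2πσ̂² + 1) + log|CᵀC + S| − log|S|₊,
    σ̂² = (RSS + θ̂ᵀSθ̂)/(n − p₀),

where p₀ is the penalty null-space dimension (the fixed effects).  The
criterion is minimized by Nelder–Mead on log λ (clipped to ±25), with one
restart from the incumbent if the first pass exhausts its budget.
Convergence requires the optimizer's own tolerances or a plateau of the
best criterion value (relative change < 1e-8, with a looser 1e-6 plateau
accepted to absorb slow crawling along flat ridges when a variance
component sits at its boundary — the fit is unchanged there to far more
digits than any downstream quantity).  With smoothing parameters frozen,
the coefficients equal the penalized GLS closed form to 1e-8 (asserted
against an independent solve).

**Difference trajectory.**  d(age) is the difference of the grid-demeaned
hemispheric age-curves plus the hemisphere offset, evaluated through the
model's linear predictor matrix; pointwise 95% intervals use the Bayesian
posterior covariance σ̂²(CᵀC + S)⁻¹ of the penalized coefficients
(half-width 1.96·SE; simultaneous bands are not attempted).  Two Wald
χ² tests with rank-truncated covariance pseudo-inverse (eigenvalues below
1e-8 of the maximum dropped) summarize the curve: d ≡ 0 anywhere
("asymmetry somewhere in life") and d non-constant over the grid
("asymmetry changes with age").  Null calibration of the pointwise
intervals is checked by simulation (200 replicates at n = 150 subjects —
a deliberately reduced problem size that keeps the full calibration run
in the default suite): mean pointwise coverage ≈ 0.95.

**Gross errors.**  Scans whose residual from the population-level fitted
trajectory of either hemisphere (observed covariates, no subject effect)
exceeds 6 model residual SDs (σ̂, the residual variance component — not
the marginal SD, which also contains σ_b) are removed and the model refit
exactly once; the log records each removal in SD units.  With this scale a
planted k-SD gross error measures ≈ k, and ordinary observations (whose
marginal residuals have SD √(σ_b² + σ²)) essentially never cross 6 at the
default variance ratio.

**Derived quantities.**  Relative change divides each hemisphere's
reference-covariate trajectory (sex at sample proportion, scanner at first
level, ICV at sample mean) by its own prediction at the minimum fitted
age, so both curves start at exactly 1; SEs follow by the delta method.
The age at peak asymmetry is where the hemispheres' pointwise 95% CIs are
maximally non-overlapping: gap(age) = lower bound of the larger-valued
hemisphere − upper bound of the smaller, maximized on a dense grid
(≤ 0.5-year resolution), earliest age on ties, undefined if the intervals
overlap everywhere.  Because the gap subtracts the (age-varying) interval
widths, this estimator is mildly biased toward well-sampled ages relative
to the argmax of |d|; recovery of a planted 24.3-year peak is therefore
scored as mean absolute error over replicates (≈ 1–1.5 years at n = 500).

**Default lifespan generator.**  Thickness-like curves: both hemispheres
thin linearly from 2.5 mm at age 4; the left adds a 0.05 constant offset
plus a 0.2-magnitude unimodal component (gamma-density shape) peaking at
24.3 years — an early-adult asymmetry peak.  Subject SD 0.05, residual SD
0.10 (trait units), 1–3 visits per subject (50/30/20%), 1–4-year
intervals, small sex/scanner/ICV effects so the covariates-of-no-interest
paths are exercised.

## Interregional covariance

Cluster AIs are sign-aligned (rightward clusters multiplied by −1 so
positive always means "more asymmetric in the population direction"),
then residualized per cluster on age, sex, and scanner in a collated
model; where subjects repeat, a subject random intercept is added
(statsmodels MixedLM) so the fixed-effect correction is not distorted by
cohort age structure.  Residuals keep the subject-level deviation — only
fixed covariate effects are removed — and are averaged within subject, one
value per subject.  Removing the estimated subject intercept instead would
strip precisely the stable individual signal whose interregional
correlation is the object of study; within-subject averaging is what
suppresses occasion noise.

Cluster-cluster matrices are Pearson correlations over subjects.
Replication between cohorts uses a one-sided Mantel test: r over the
lower triangle, null by jointly permuting one matrix's row/column labels,
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) with 10,000 permutations by
default; an exhaustive mode enumerates all k! permutations for small
matrices (there p includes the identity and the attainable minimum for a
generic matrix is 1/k!).  Type-I error is verified at 0.03–0.07 over 1000
independent-matrix replicates at 500 permutations.

Geodesic distances are Dijkstra shortest paths on the mesh edge graph
weighted by Euclidean edge length — an upper bound on exact polyhedral
geodesics, with small error on fine meshes; cluster-pair distance is the
mean over all cross-cluster vertex pairs (centroid-to-centroid would be
cheaper but is not what "average distance between clusters" means).  The
distance-covariance analysis correlates pair distance with Fisher-z
transformed pair correlations (Spearman, average ranks on ties),
restricted to a direction combination (opposite-direction pairs by
default).

The global analysis reports the variance share of PC1 of the z-scored
sign-aligned residuals, the correlation between cluster-area-weighted
(and unweighted) mean asymmetry across leftward vs rightward clusters,
and the correlation of the two blocks' first principal components.  The
"partial correlation" flavor of the left-vs-right comparison is realized
as a plain correlation on covariate-residualized values — the covariates
are already partialled out at residualization.  An optional robust screen
flags multivariate outliers at squared Mahalanobis > χ²(0.999); it is off
by default because no principled criterion is specified for it.

## Heritability

**GRM.**  A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)) over
SNPs with sample MAF ≥ 0.01; missing dosages are mean-imputed per SNP
(the generator can plant missingness to exercise this path).  Relatedness
pruning is greedy: while any off-diagonal exceeds the cutoff (0.025),
remove the individual in the most offending pairs (lowest index on ties) —
one member of an isolated pair, two of a 3-clique.  At desk-scale SNP
counts the GRM's off-diagonal noise SD is 1/√M, so the 0.025 cutoff is
only meaningful relative to M; the pruning tests therefore use constructed
matrices and planted duplicate genomes.

**GREML.**  V = σ²_g A + σ²_e I with fixed effects = intercept + top 10
GRM eigenvectors (population-structure axes; synthetic data has no
array-level structure, so the GRM's own eigenvectors are the natural
choice) + optional covariates.  Estimation is AI-REML with a two-step EM
warm start, computed in the GRM eigenbasis where every iteration is
O(n·p): one eigendecomposition per GRM, then scores, average-information
matrix and likelihood are all diagonal-form.  Components are floored at
1e-6 of the phenotypic variance; steps are halved until the restricted
likelihood does not decrease, with an EM fallback and boundary-stall
detection; convergence at relative log-likelihood change < 1e-8.
Phenotypes are age/sex-residualized and z-scored before analysis.  The
σ²_g = 0 test uses the boundary mixture 0.5·χ²₀ + 0.5·χ²₁; SE(h²) by the
delta method from the inverse AI matrix.

**Bivariate GREML.**  The two-trait REML likelihood block-diagonalizes in
the same eigenbasis into 2×2 problems per eigenvalue.  It is maximized
over Cholesky-parametrized genetic and environmental covariance blocks
(log-diagonal), which keeps both blocks PSD and rG within [−1, 1] by
construction and is robust at the rG = ±1 boundary — the reason this
solver deviates from AI-REML updates.  p tests zero genetic covariance
(χ²₁, an interior hypothesis); SE(rG) by delta method from a numerical
Hessian at the optimum and is unreliable when the estimate sits on the
boundary (reported as computed; the LRT is the inferential quantity
there).

**Twin AE.**  Families carry kinship matrices K with unit diagonal and
off-diagonals 1 (MZ co-twins) or 0.5 (DZ co-twins, siblings); twin pairs
are same-sex by construction, and trio families (twin pair + sibling) give
3×3 blocks.  Family covariance a²K + e²I shares K's eigenvectors, so each
family rotates into independent scalar (or 2×2) components grouped by
eigenvalue — likelihood evaluation is O(#distinct eigenvalues) regardless
of sample size.  Maximum likelihood over (a², e²) with a² ≥ 0; a²= 0
tested with the boundary mixture.  On data whose empirical moments satisfy
cov_MZ = 2·cov_DZ with unit variances exactly, the MLE equals the moment
solution exactly (the structured model attains the empirical covariances),
which the tests verify on moment-whitened constructions.  The bivariate
model is the Cholesky AE (K ⊗ Σ_A + I ⊗ Σ_E), genetic covariance tested
at χ²₁.  A single relationship class (all a-coefficients equal, no trios)
leaves A and E unseparable and is rejected.

**Multiple testing.**  BH step-up FDR (via statsmodels, verified against
the definitional brute force) for cortex-wide banks; Bonferroni per metric
for the small robust-cluster screens.

## Cognition composite and the association screen

The 11-test battery follows a one-factor model: test_j = λ·g + √(1−λ²)·e
on standardized scales, with g correlated with age at −0.39.  The default
loading λ = 0.5755 is chosen so the population PC1 variance share of the
battery is 39.2%: for n equal-loading standardized indicators the top
correlation-matrix eigenvalue is 1 + (n−1)·λ²/(λ²+u), giving share
(nλ² + u)/(n(λ² + u)).  Missingness is completely at random (10% by
default).

Missing scores are completed by iterative low-rank PCA imputation:
center/scale, start missing cells at column means, repeatedly replace them
with the rank-r SVD reconstruction until the relative change in imputed
values falls below 1e-5 (observed cells are never altered; convergence is
geometric at a rate set by the trailing eigengap, so ranks that mostly fit
noise converge slowly — the cross-validation path caps iterations rather
than failing).  The rank is chosen by 5-fold cross-validated
reconstruction error over ranks 1–5, masking observed cells; on one-factor
data rank 1 wins and beats marginal-mean imputation in held-out RMSE.  PC1
of the completed matrix is sign-fixed to correlate non-positively with
age.  Note that imputation inflates the in-sample PC1 share (imputed cells
carry no unique noise), so the closed-form share comparison is made at
zero missingness.

The screen fits, per cluster, OLS on sign-aligned AIs with two model
families mirroring the differing availability of the predictors: cognition
PC1 (age, sex, ICV controlled) and handedness + sex + ICV jointly (age
controlled), with right-handers and females coded 0 and mixed-handers
excluded.  Significance at Bonferroni α = alpha_base/(n_clusters × 4); at
the study's scale of 34 clusters and base α = 0.01 this is 0.01/136 =
7.4e-5.

## Problem sizes and what the tests do and do not show

The default suite runs every stage at reduced but honest sizes: 7×30
subjects on 2562 vertices for consensus; 150–500 subjects for trajectory
calibration/power (200 and 20 replicates); n = 1000, M = 2000 for GREML;
500+500 twin pairs; 1000 Mantel replicates at 500 permutations; n = 2000
for the battery.  These sizes make sampling error explicit in every
tolerance (2-SE recovery bands, 4-SE null bands, binomial bands on
rejection rates).

The generators emulate the statistical structure of the real problem —
smooth planted fields with dataset-specific noise, mixed cross-sectional/
longitudinal designs with subject intercepts, polygenic additive genetics,
one-factor batteries with MCAR missingness — but not: cortical folding
geometry, registration error, spatially correlated or non-Gaussian imaging
noise, MNAR missingness, assortative mating or shared-environment (C)
variance, or linkage disequilibrium.  Passing tests therefore demonstrate
that the estimators recover what they claim under their stated
assumptions, not that those assumptions hold in any real cohort.
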