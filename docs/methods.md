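# Methods

This note records the models, defaults, and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Behavioral model and cleaning

Trial tables hold the signed angular error (degrees, wrapped to
(−180, 180]) between target and final cursor position, plus reaction time.
Cleaning follows three rules:

- trials with RT > 2 s or < 100 ms are flagged invalid and excluded;
- within each continuous run (day × epoch), a cubic least-squares B-spline
  with ⌈n/40⌉ evenly spaced interior knots is fit to the valid errors.
  The spline is unpenalized: with one knot per 40 trials the basis is
  already heavily constrained, and no penalty parameter is part of the
  rule. Runs with fewer than 4 valid trials pass through undetrended with
  a warning;
- residuals beyond 3 residual-SDs are replaced by the spline value and
  flagged `interpolated`. The residual SD carries an absolute floor
  (1e−8 × data scale) so numerically flat runs never flag spurious
  outliers.

Early error is the circular mean (atan2 of mean sine/cosine) of the error
over the first 32 learning trials of a day; the mean is taken over signed
errors. Savings = early error(day 1) − early error(day 2).
Standardization of the three features uses the n−1 SD denominator.

Clustering is complete-linkage agglomeration on the Manhattan (ℓ1)
distance between the standardized features (scipy linkage; merge ties are
resolved by scipy's deterministic pair ordering). The bootstrap validity
check draws cohorts from a single multivariate normal with the observed
feature mean and covariance and records the within/total sum-of-squares
ratio per k ∈ {2..8}. Because savings is an exact linear combination of
the two early errors, the feature covariance is singular by construction;
the null sampler ridge-stabilizes it (1e−8 × mean variance on the
diagonal) and warns. The default draw count is 5000, with smaller counts
used by the drivers and tests for speed. The package reports the
observed-vs-null curves and the percentile rule (observed below the null
5th percentile) rather than auto-selecting k.

## Network excursion

The resting manifold is the span of the leading PCA components of a
network's resting scan (column-mean-centered), retaining the smallest d
whose cumulative explained variance reaches the threshold (default 0.75;
thresholds between 0.5 and 0.9 behave similarly on synthetic data). The
projector is implemented as VVᵀ for the orthonormal basis V. Task vectors
are centered at the resting mean before projection, treating the manifold
as an affine subspace through the rest mean; this choice is configurable
(`rest-mean` | `task-mean` | `none`). Volumes with near-zero centered norm
return r = 0 and are flagged rather than dividing 0/0.

Excursion curves are z-scored against the pre-rotation baseline window
(n−1 SD); a zero baseline SD is an error, not a silent floor. Early
excursion averages the standardized curve over 4 blocks × 8 trials × 2
volumes/trial = 64 volumes after rotation onset (4 s trials at TR = 2 s).

## Smoothing and multivariate functional PCA

Each excursion curve is represented as a natural cubic smoothing spline
with a knot at every observation, fit by minimizing
Σ(y_i − f(t_i))² + λ∫f″². λ is selected on a log grid (10⁻⁶..10⁹, 76
points) by GCV(λ) = n·RSS/(n − tr S_λ)². The Reinsch form of the problem
admits a Demmler–Reinsch eigendecomposition of the penalty that is
computed once per grid and shared across curves, so smoothing a cohort
costs one symmetric eigendecomposition plus a matrix–vector product per
curve. Penalty eigenvalues below 1e−12 of the maximum are zeroed so the
penalty null space (straight lines) stays exactly penalty-free at any λ;
constant inputs return a constant curve with λ at the top of the grid.
Fixed-λ fits agree with `scipy.interpolate.make_smoothing_spline` to
machine precision, which the test suite uses as an independent oracle.

mfPCA treats each subject's four smoothed curves (2 networks × 2 days) as
one multivariate functional observation and eigen-decomposes the
covariance operator, implemented as weighted PCA on the concatenated
grid-discretized curves with trapezoid quadrature weights. Elements are
weighted equally (no per-element variance normalization) because the
curves are already baseline-standardized; this is configurable by
pre-scaling the inputs. Components have unit norm under the multivariate
inner product, scores are zero-mean, and the sign convention makes the
largest-|loading| point of each component positive. K defaults to 3.

Group differences in component scores use Kruskal–Wallis (tie-corrected,
chi-square reference, with the all-tied 0/0 case defined as H = 0) and
Conover–Iman post hocs: t-type statistics on ranks with pooled rank
variance scaled by (N−1−H)/(N−g), N−g degrees of freedom, two-sided p,
Benjamini–Hochberg step-up across pairs. The t-type statistic is a
monotone transform of the equivalent large-sample z statistic.

## SPD geometry and covariance centering

Covariance estimation uses the Ledoit–Wolf linear shrinkage estimator
(sample covariance shrunk toward a scaled identity with the data-driven
intensity), which is SPD even with fewer volumes than ROIs and whose
regularization strength is a function of the sample size — hence rest and
task covariance windows share one length (177 TRs by default) so the
centering never mixes differently-regularized estimates.

All matrix functions (square root, log, exp, powers) are computed by
eigendecomposition with symmetrization; inputs failing symmetry (1e−10
relative) or positive definiteness (min eigenvalue ≤ 1e−12) raise a loud
error naming the violation — eigenvalues are never clipped silently.

- log map: T = R^{1/2} log(R^{−1/2} S R^{−1/2}) R^{1/2}
- exp map: S = R^{1/2} exp(R^{−1/2} T R^{−1/2}) R^{1/2}
- transport: T↦ G T Gᵀ, G = R̄^{1/2} R^{−1/2} (an isometry of the metric)
- distance: ‖log(S₁^{−1/2} S₂ S₁^{−1/2})‖_F
- Fréchet mean: fixed-point iteration M ← M^{1/2} exp(mean log) M^{1/2},
  initialized at the arithmetic mean, step size 1, converged when the mean
  log has Frobenius norm < 1e−8 (error if 200 iterations are exceeded).

Centering composes log map at the subject's rest covariance, transport to
the grand mean, and exp map at the grand mean (the exp reference is the
transport destination). A subject's own rest covariance centers exactly to
the grand mean, and subjects sharing a whitened task shift share the
centered tangent vector.

## Joint rank-one embedding

Centered tangent vectors are approximated by T_i ≈ Σ_k λ_ik h_k h_kᵀ with
unit-norm loading vectors h_k and sign-unconstrained scores (connectivity
can increase or decrease relative to rest). Fitting is greedy rank-one
deflation with alternating exact updates — λ_i = hᵀT_i h given h, and h =
leading eigenvector of Σ_i λ_i T_i given the scores — so the total squared
Frobenius residual is non-increasing by construction and is asserted so at
every iteration. Initialization is the largest-|eigenvalue| eigenvector of
Σ_i T_i, with a seeded random fallback if that sum is numerically zero;
all-zero inputs return zero scores with a degeneracy flag. Components are
reported largest-score-variance first with the largest-magnitude loading
entry positive; fixtures are compared up to this sign/order convention.
K defaults to 2.

Score tests use a balanced split-plot ANOVA: day and epoch within
subjects (each tested against its interaction with subjects-within-group),
group between subjects (tested against subjects-within-group), BH
adjustment across the reported main effects. Unbalanced designs are an
error — no imputation. Effect sums of squares below 1e−12 of the total
are treated as exactly null. The single-group reduction reproduces
statsmodels' AnovaRM F values, which the tests use as an oracle.

## Synthetic-data generator

The generator supplies the study's statistical structure with known
ground truth; its defaults are the task's condition counts.

*Behavior*: 120 baseline / 320 learning / 120 washout trials per day,
45° rotation, 10 subjects per phenotype. Learning error follows
rotation·exp(−t/τ) with τ = 8 trials (fast) or 60 trials (slow); FF is
fast both days, SS slow both days, SF slow day 1 / fast day 2; washout
releases the adapted fraction as an after-effect decaying with τ = 15
trials. Trial noise is Gaussian with SD 6°, giving an FF-vs-SS early-error
separation of ≈23° against a per-subject SE of ≈1.1° — cleanly separated
phenotypes, as the clustered cohorts this emulates show. RTs are
lognormal (mean ≈0.45–0.5 s, SD 0.15 s) with a 2% rate of planted RT
violations to exercise the filters.

*Neural*: x_t = μ + W z_t + s_t·u + ε with W an orthonormal n_rois × k
loading matrix, latent variances decaying geometrically (scale 4, ratio
0.6, k = 5 by default) so the 75% threshold selects a predictable
dimension, u a fixed unit direction orthogonal to span(W), and s_t a
schedulable off-manifold magnitude (zero during rest). A subject's
structural draw (W, u, μ) is seeded separately from per-scan noise so the
two days of one subject share network structure. In the pipeline the
schedule steps up at rotation onset and relaxes with τ = 32 trials
(the early-learning window), with planted heights FF 3 / SS 1 / SF 3 on
day 1 and FF 2 / SS 1 / SF 3 on day 2 in the cognitive network (half in
the sensorimotor network) — FF/SF engage the off-manifold direction more
than SS, most strongly SF on day 2.

*Covariance sets*: S_ij = Exp_{R_i}(Σ_k λ_ijk h_k h_kᵀ) with R_i an
identity base perturbed by an exp-mapped symmetric jitter (SPD by
construction); planted components and scores are returned for recovery
tests.

The generator does not emulate hemodynamic convolution, autocorrelated or
physiological noise, spatial structure within ROIs, or drift between
scans; passing tests therefore certify the estimators' correctness and
calibration under the assumed low-rank-plus-perturbation model, not
robustness to fMRI artifacts.

## Problem sizes and runtime choices

The default synthetic cohort is 30 subjects (10 per phenotype), 62 + 51
ROIs, 880 task volumes and 180 rest volumes per day, 177-TR covariance
windows — one continuous scan per day laid out as 2 volumes per trial.
Bootstrap counts default to 5000 in the library and 500–1000 in the
drivers; calibration checks use 2000 null simulations. A full pipeline
run completes in seconds on one CPU because the spline smoother shares
its eigendecomposition across curves.

## Known limitations

- The excursion step-recovery check plants a step directly in the
  excursion domain (in baseline-SD units); a step in signal space maps
  through the nonlinear ratio r_t, so its standardized height depends on
  baseline signal norms and is only checked directionally.
- The mfPCA discretizes the covariance operator on the common volume
  grid; with knots at every observation this is equivalent to the basis-
  expansion estimator up to quadrature, but no penalized eigenfunction
  smoothing is applied.
- The Conover–Iman statistics are reported on the t scale, not the z
  scale; the two are monotone equivalent.
- The split-plot ANOVA tests main effects only, assumes sphericity, and
  offers no correction for its violation.
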