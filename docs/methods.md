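# Methods

## The spatial model

`basisbrain` models a cohort of masked volumetric brain images as weighted
sums of fixed spatial basis functions. Each subject's masked image is
vectorized into **y**_s ∈ ℝ^V (V mask voxels, subjects s = 1..S) and
modelled as

    y_s = Φ w_s + ε_s,        ε_s ~ N(0, β⁻¹ I),

where Φ is the V×M design matrix collecting M basis functions evaluated at
the mask voxels, w_s is a subject-specific weight vector and β is the
noise precision. Weights carry a zero-mean Gaussian prior
w_s ~ N(0, Λ_α⁻¹) shared across subjects. With diagonal
Λ_α = diag(α₁..α_M) this is an automatic-relevance-determination (ARD)
prior: an uninformative basis function is pruned by driving its precision
α_m large, consistently across the cohort.

### Empirical Bayes

For fixed (α, β) the weight posterior is Gaussian in closed form:
A = βΦᵀΦ + Λ_α, w̄_s = βA⁻¹Φᵀy_s. The posterior precision A does not
depend on the data values, so one Cholesky factorization serves all
subjects. Hyperparameters are set by type-II maximum likelihood,
maximizing the log marginal likelihood

    L(α, β) = Σ_s log N(y_s | 0, β⁻¹I + ΦΛ_α⁻¹Φᵀ)
            = S[(V/2)log β − (V/2)log 2π + ½log|Λ_α| − ½log|A|]
              − Σ_s [ (β/2)‖y_s − Φw̄_s‖² + ½ w̄_sᵀΛ_α w̄_s ].

Gradients are analytic. Because w̄_s minimizes the inner penalized
least-squares criterion, terms through w̄ vanish (envelope theorem),
leaving

    ∂L/∂α_m = (S/2)(1/α_m − [A⁻¹]_mm) − ½Σ_s w̄²_{m,s}
    ∂L/∂β   = SV/(2β) − (S/2)tr(A⁻¹ΦᵀΦ) − ½Σ_s‖y_s − Φw̄_s‖².

Both the evidence and its gradient are verified in the test suite against
an independent dense-covariance Gaussian computation and central finite
differences, respectively. Optimization runs over (log α, log β) —
positivity by construction — with L-BFGS-B (deterministic quasi-Newton;
the log-space objective is smooth and well conditioned). Defaults:
initialization α = 1, β = 1/var(Y); convergence at relative objective
change < 1e−6 or 1000 iterations; the best iterate is returned on
non-convergence with the trace's `converged` flag cleared.

### Full Bayes (blocked Gibbs)

The richer model allows a *full* ARD precision matrix (off-diagonal
entries capture correlations between basis functions) and places conjugate
priors on everything:

    β ~ Gamma(a, b),   Λ_α ~ Wishart(N, P),   w_s ~ N(0, Λ_α⁻¹).

Conjugacy gives exact full conditionals, cycled W → β → Λ_α per sweep:

* W: per-subject Gaussians with the closed-form mean/precision above,
  evaluated at the current (β, Λ_α);
* β: Gamma(a + SV/2, b + ½Σ_s‖y_s − Φw_s‖²);
* Λ_α: Wishart(N + S, P + Σ_s w_s w_sᵀ).

**Wishart convention.** The Wishart is parameterized by (degrees of
freedom, *rate* = inverse scale), so the conditional update is the
additive form above and the mean of Wishart(ν, R) is ν·R⁻¹. This is stated
prominently because the two conventions are easily confused; draws use
`scipy.stats.wishart` with scale = R⁻¹.

Vague defaults: a = b = 1, N = M + 2, P = I. Chains default to 200 burn-in
sweeps and 1000 retained samples — the conjugate blocked structure mixes
fast and successive draws have low autocorrelation, which the Gelman–Rubin
potential scale reduction factor (R̂) confirms on multi-chain runs.
Initialization: β = 1/var(Y), Λ_α = I, W = 0; no thinning. Each chain
draws its generator from an independent spawned seed stream, so multi-chain
runs are reproducible and order-independent.

The conditional samplers are tested by Monte-Carlo moment matching
(empirical mean/covariance of 1e5 draws vs the analytic conditionals,
within 4 MC standard errors), and calibration is tested by coverage: over
100 seeded replicates at V = 500, M = 20, S = 40, the central 95% posterior
interval for β contains the generating value in ≥ 90 (96 in the recorded
run at seed 1). The coverage runs use 100 burn-in + 400 retained sweeps per
replicate; the interval estimate is stable at that length because of the
sampler's fast mixing.

## Basis sets

**Bisquare tilings.** Generic compactly supported radial functions
φ(x) = [1 − (‖x−c‖/r)²]² for ‖x−c‖ ≤ r, tiled on regular lattices at
multiple detail levels with r = 1.5 × the centre spacing. Default radii:
6, 12, 18 mm. The lattice origin is the minimum world-coordinate corner of
the mask's bounding box expanded by one spacing per side (the origin is a
free choice; this one is deterministic and mask-adapted). A centre is
retained iff at least one mask voxel falls strictly inside its support, so
no column is all-zero after masking. Distances are computed in world mm
through the affine, not in voxel indices. Retained-centre counts are
verified against a brute-force lattice enumeration oracle. Because counts
depend on the mask and lattice origin, per-level counts on a new mask are
not expected to reproduce any particular published values; the multi-level
assembly machinery is exercised with externally specified per-level counts
in the acceptance checks.

**Probabilistic atlases.** Any set of co-registered non-negative maps; one
column per map, masked; maps that vanish inside the mask are dropped with
a warning (or rejected under strict mode).

**Instantaneous-connectivity parcellation (ICP).** A soft functional
parcellation of the region from 4D timeseries. Per-voxel timecourses are
normalized to zero mean/unit SD (population SD; rows with SD < 1e−12 are
zeroed and excluded from the reference). The regional reference is the
normalized grand-mean timecourse. Instead of summarizing each voxel by its
Pearson correlation with the reference, the correlation is temporally
*unfolded* into the element-wise product series — its time mean is exactly
the Pearson correlation, an algebraic identity the tests check to machine
precision. The V×T product matrix is decomposed by spatial ICA (FastICA,
voxels as samples) at each model order d; per-order child seeds derive
deterministically from the top-level seed, so the pipeline is bit-for-bit
reproducible. ICA signs are indeterminate, so each map is flipped to make
its largest-magnitude voxel positive. Non-convergence triggers up to five
restarts with reseeded initialization and progressively relaxed (×10)
fixed-point tolerance — model orders above the data's effective rank
otherwise stall on noise directions — before raising.

Each spatial mode is converted to a non-negative confidence map: the map is
z-scored and a zero-mean two-component Gaussian scale mixture (narrow null,
wide alternative) is fit by EM; the confidence is the alternative/null
responsibility ratio, which is monotone increasing in |z| because the
alternative component has the larger variance. This is a deliberate
simplification of mixture-model soft assignment: the null is symmetric
Gaussian rather than a skewed null/Gamma alternative pair, which is enough
to order voxels by assignment confidence but does not produce calibrated
posterior probabilities. A plain |z| fallback is available. The multiscale
basis concatenates confidence maps over orders d = 2..D (Σd columns, e.g.
464 for d = 2..30), recording each column's model order; a single
high-order decomposition of the raw (not unfolded) timeseries provides the
ICA-style reference basis.

One empirical property worth knowing: the unfolding introduces a shared
global mode — the products' row means carry the regional mean-correlation
structure, and all parcel time-signatures share a cross-term with the
reference. Recovering K planted subnetworks from synthetic data therefore
needs K+1 components, and recovered maps correspond to the *row-normalized*
parcel loadings (normalization divides each voxel's loading by its
timecourse SD). The recovery tests are constructed accordingly.

**Characterization.** Basis sets are compared by the mean ± SD absolute
pairwise spatial correlation of their columns and by the normalized
eigenspectrum (squared singular values of the column-centred matrix,
normalized to sum 1): a flatter spectrum means higher intrinsic
dimensionality. Functional basis sets can be smoothed with a Gaussian
kernel (FWHM in mm, σ = FWHM/(2√(2 ln 2)); 8 mm emulates a SPECT point
spread function) by unmasking, filtering with constant-zero padding, and
re-masking.

## Evaluation

Explained variance is 1 − SS_res/SS_tot (negative values possible out of
sample). Because the modelling target is spatial interpolation,
cross-validation subsamples *voxels*: for each training fraction (defaults
0.1/0.2/0.5, 10 repeats) a uniformly random voxel subset trains the model
— hyperparameters refit within the split, nothing leaks from held-out
voxels — and the complement scores it.

Relevance ranking orders basis functions by ARD prior variance 1/α_m
(empirical Bayes) or by the posterior mean diagonal of Λ_α⁻¹ (full Bayes):
under ARD a large precision prunes a basis function, so large variance =
relevant. Because some relevance displays normalize |α_m| itself instead,
both normalized scores are reported; the ranking used for model-order
curves follows the variance convention. Complexity/accuracy curves refit
the model with the top-M′ relevant columns and report in-sample EV mean ±
SD across subjects; a nested-OLS oracle bounds the curve in tests.

Structure coefficients — the univariate correlations between each basis
column and each subject's fitted values — aid interpretation under
collinearity, where a large weight can reflect a suppressor role rather
than direct association. Split reproducibility fits two disjoint random
halves of the cohort and correlates the per-basis mean weights; it is
informative about the cohort's *shared* weight structure (with zero-mean
independent subject weights the two halves are independent and r ≈ 0 even
noiselessly, so synthetic reproducibility checks plant a common mean
weight vector, as real single-condition cohorts have).

## Probit-ARD classification

Subject weight vectors feed a Bayesian probit classifier: labels
t_s ∈ {0,1}, likelihood Π_s H(zᵀw_s)^{t_s}(1 − H(zᵀw_s))^{1−t_s} with H
the standard-normal CDF, prior z ~ N(0, Λ_z⁻¹), Λ_z diagonal ARD. The
posterior is non-Gaussian; expectation propagation builds a Gaussian
approximation through per-subject site factors over the latent values
f_s = zᵀw_s (linear-kernel Gaussian-process form, K = XΛ_z⁻¹Xᵀ). Site
updates are sequential with damping 0.8 and rank-one posterior refreshes,
a full recompute per sweep for numerical hygiene, a site-precision floor
of 1e−10, skipped updates on negative cavity precisions, and convergence
at maximum site-parameter change < 1e−6 (cap 200 sweeps, warning on
non-convergence). The EP evidence is assembled from cavity-matched site
normalizers and the Gaussian convolution integral; it matches 1-D
quadrature on single-feature problems to ~0.01 and the EP posterior mean
matches a long-run Albert–Chib data-augmentation Gibbs sampler to < 0.05
(typically < 0.01).

ARD precisions are chosen by EM-style fixed-point updates
α_j ← 1/(m_j² + Σ_jj) between EP fits (cap 25 outer iterations, relative
log-precision tolerance 1e−3, α clipped to [1e−6, 1e6]); the
best-evidence iterate — including the isotropic initialization — is
returned, so the reported evidence never falls below the starting point.
An isotropic-prior mode skips the outer loop. Predictions use the probit
predictive with posterior-variance correction, p = H(m/√(1+v)).

Generalization is measured by stratified k-fold cross-validation (default
k = 10, reduced with a warning if the smaller class is smaller than k) with
the AUROC computed from pooled out-of-fold probabilities via the rank
(Mann–Whitney) formulation. The spatial-model weights used as features are
fit unsupervised on the full cohort (no label information is involved), and
only the classifier is refit per fold.

A note on attainable AUROC in synthetic checks: a planted mean shift of
δ SD on one weight coordinate with unit within-class SD has Bayes-optimal
AUROC H(δ/√2) — 0.92 at δ = 2, 0.98 at δ = 3. Classifier checks that
demand AUROC > 0.9 therefore use δ = 3 (a clearly separated clinical
contrast); monotonicity in δ is tested separately.

## Synthetic data

All generators are pure functions of their arguments and a seed. Cohorts
follow the model exactly: w_s ~ N(mean, Σ_α), y_s = Φw_s + N(0, β⁻¹I)
(β = ∞ for noise-free). Timeseries with planted subnetworks give each
parcel an independent band-limited latent timecourse — Gaussian white
noise smoothed over ~3 frames and renormalized, a generic stand-in for
slow hemodynamic fluctuations — mixed through non-negative parcel maps
plus white noise. Two-class cohorts shift class 1's weight means by an
effect vector. The toy mask is a two-lobed "pseudo-striatum": two
overlapping ellipsoids on a 12×12×8 grid of 2 mm voxels (V = 243),
generated programmatically.

What the generators do *not* emulate: scanner physics beyond an isotropic
Gaussian point spread (no scatter/attenuation), spatial noise correlation,
registration error, hemodynamic nonlinearity, or between-site variation.
Passing tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions and robustness to white noise — not
performance on real clinical images.

**SNR convention.** Signal-to-noise ratios in the synthetic accuracy
checks are amplitude (SD) ratios: "SNR 10" means the white-noise SD is one
tenth of the pooled signal SD (variance ratio 100). Under the variance
convention the explained-variance ceiling at SNR 10 would be 10/11 ≈ 0.91,
leaving no room between the ceiling and the 0.9 accuracy bar the checks
use.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small problems chosen to make
the statistical checks sharp while keeping the suite quick: oracle
comparisons at V ≤ 50, M ≤ 10, S ≤ 5; conditional-moment checks at 1e5
draws; coverage at V = 500, M = 20, S = 40 over 100 replicates; ICP runs
on the V = 243 toy mask with T = 120–200 frames; classification cohorts of
200 subjects. Degenerate inputs fail loudly: empty masks, constant image
columns, constant prediction targets, non-PD covariance/rate matrices and
out-of-range model orders all raise typed errors rather than propagating
NaNs. Ties in relevance ranking break by ascending column index.
Eigen-/Cholesky-based code symmetrizes matrices before factorization and
reports a conditioning error when a factorization fails.

## Known limitations

* Empirical Bayes supports diagonal Λ_α only; correlated-basis modelling
  is the Gibbs sampler's job (mirroring the two model variants).
* The EP classifier is binary; multiclass problems require one-vs-rest
  composition by the caller.
* The confidence transform is a simplified scale mixture, not a
  calibrated mixture-model posterior.
* Marginal likelihoods are not estimated from MCMC output; model
  comparison under the full-Bayes route must use predictive performance.
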