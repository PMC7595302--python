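# Methods

`kernsens` is built around one observation: almost every kernel machine —
kernel ridge / Gaussian-process regression, the SVM decision function,
Parzen and eigendecomposition-restricted density estimates, and (after
grouping terms) the Hilbert–Schmidt Independence Criterion — evaluates a
finite kernel expansion

    f(x) = Σᵢ αᵢ k(x, xᵢ) + b,

so every derivative of the learned function is the same linear combination
of kernel derivatives, ∂ⱼf(x) = (∂ⱼk(x))ᵀα.  The package supplies the
kernel derivatives in closed form and builds the four derivative-based
analyses on top of them.

## Kernel families and their derivatives

Five families are implemented (derivatives always with respect to the
first argument; second-argument derivatives follow from symmetry, and from
antisymmetry for the stationary families):

| family | k(x, y) | ∂k/∂xʲ |
|---|---|---|
| linear | xᵀy | yʲ |
| poly   | (γxᵀy + c₀)ᵖ | γp yʲ (γxᵀy + c₀)ᵖ⁻¹ |
| rbf    | exp(−γ‖x−y‖²) | −2γ(xʲ−yʲ) k |
| tanh   | tanh(γxᵀy + c₀) | γyʲ sech²(γxᵀy + c₀) |
| ard    | ν² exp(−½Σ_d((x_d−y_d)/λ_d)²) | −((xʲ−yʲ)/λⱼ²) k |

Unmixed second partials and mixed partials are implemented analogously
(see `kernels.py`); Hessians are assembled from outer products and are
exactly symmetric by construction.  **ARD signs.**  Some published formula
tables state the ARD first derivative as +((xʲ−yʲ)/λⱼ²)k and the second as
(1/λⱼ² + ((xʲ−yʲ)/λⱼ²)²)k.  Direct differentiation of the ARD kernel gives
the opposite signs — gradient −((xʲ−yʲ)/λⱼ²)k and second partial
((xʲ−yʲ)²/λⱼ⁴ − 1/λⱼ²)k — and the finite-difference oracle confirms the
calculus, so that is what this package implements.  Similarly, the tanh
second partial is written here as −2(γyʲ)² sech²(u) tanh(u), which equals
the form −2(γyʲ)² sech²(u)·k sometimes printed with the kernel value
factored out.

Higher-order unmixed RBF partials use the chain rule for exp∘g with the
quadratic argument g = −γ‖x−y‖²: because g′ = −2γ(xʲ−yʲ), g″ = −2γ and all
higher derivatives of g vanish, the combinatorial (Faà di Bruno) expansion
collapses to the two-term recursion h_m = g′h_{m−1} + (m−1)g″h_{m−2} with
h₀ = k.  Orders 1–2 coincide with the closed forms to machine precision
and orders 3–4 are validated against symbolic differentiation in the test
suite.

**Parameterisation.**  The RBF kernel is stored as γ; a bandwidth σ maps
as γ = 1/(2σ²), and YAML specs accept either spelling.  Defaults: γ by the
median heuristic (1/(2·median² pairwise distance)); poly p = 2, c₀ = 1,
γ = 1; ARD lengthscales = per-feature standard deviations.  Derivative
tensors are laid out (evaluation point, anchor, feature) throughout, so
contracting the anchor axis with α yields expansion derivatives.

**Finite-difference oracle.**  Central differences with per-coordinate
step h = 1e−6·max(1, |xⱼ|) for gradients and nested central differences
with h = 1e−4·max(1, |xⱼ|) for Hessians.  It lives in the package
(`numdiff`) but is used only by tests, diagnostics and the `oracle-check`
CLI command, never on the analytic code path.

## Sensitivity maps

The feature sensitivity sⱼ is the empirical mean over an evaluation set of
the squared partial derivative ∂ⱼf(xᵢ)², and the point sensitivity qᵢ
averages the same squared derivatives over features instead.  Squaring
(rather than an absolute value) is the default summary.  The evaluation
set defaults to the training anchors.  Because both summaries aggregate
one matrix of squared derivatives, they satisfy the exact identity
n·Σⱼsⱼ = d·Σᵢqᵢ, asserted to 1e−12 in the tests.  The estimator weights
evaluation points uniformly; sensitivity under a non-uniform input density
would require weighting the sum by p(x), which is out of scope.  The bias
term contributes nothing to any derivative.

## GP / kernel-ridge regression

`fit` solves (K + σₙ²I)α = y by Cholesky factorisation; if the matrix is
numerically indefinite a diagonal jitter starting at 1e−10·tr(K)/n is
doubled until factorisation succeeds, capped at 1e−6·tr(K)/n.  The
predictive mean is k*ᵀα and the predictive variance
σₙ² + k** − k*ᵀ(K+σₙ²I)⁻¹k*, floored at zero.  The σₙ² = 0 interpolation
contract (training residual < 1e−6‖y‖) holds for well-conditioned Grams;
on densely sampled smooth 1-d designs with median-heuristic γ the Gram is
singular to machine precision and only the jittered least-squares sense is
meaningful.  No marginal-likelihood optimisation is performed;
hyperparameters come from the defaults above or from cross-validation
grids.

**Noise experiment.**  `noise_norm_experiment` fits sin(3πx) + noise on
n = 100 inputs uniform on [0, 1] (both package choices; the protocol fixes
only the signal, the SNR grid 0–50 dB and SNR = 10·log₁₀(σ_y²/σₙ²) with
σ_y² the clean-signal variance) and records four quadratic norms of the
fit: αᵀKα, αᵀKᵀKα, αᵀ(∇K)ᵀ(∇K)α and αᵀ(∇²K)ᵀ(∇²K)α, with ∇K and ∇²K the
first/second derivative matrices stacked feature-wise so the forms remain
defined for d > 1.  The regularised arm uses the true injected noise
variance as the ridge parameter; the unregularised arm uses σₙ² = 0 plus
jitter.  Within a repeat the design and a unit noise draw are shared
across the SNR grid (common random numbers) and consecutive repeats use
antithetic draws ±z: each norm is quadratic in the noise, so averaging ±z
cancels the signal–noise cross term exactly and the repeat-mean of the
unregularised norms is monotone in the injected noise power by
construction, not merely in expectation.  Reported curves subtract the
value at the largest SNR so the four norms are comparable.

## SVM margin analysis

The dual soft-margin QP is delegated to scikit-learn's SVC, invoked with
this package's Gram builder as a callable kernel so the fitted expansion
uses exactly the kernels defined here; box (0 ≤ αᵢ ≤ C) and equality
(Σαᵢyᵢ = 0) feasibility are re-checked on the returned coefficients.
Replacing the sign mask with tanh (unit slope) makes the classifier
differentiable; the chain rule factors the gradient of g = tanh(f) into a
scalar mask factor 1 − g², maximal where f = 0 and vanishing where the
decision saturates, times the kernel part ∂k*ᵀ(y∘α).  `margin_sensitivity`
reports point sensitivities of the mask factor alone (the scalar squared),
the kernel part alone, and the composite product, which therefore
satisfies q_composite = mask²·q_kernel pointwise.  Hyperparameter tuning
uses a stratified 3-fold CV grid over (C, γ); no class reweighting is
applied.

## Density estimation and ridges

The Parzen estimate uses a normalised Gaussian bump; the default
bandwidth is Silverman's rule applied per dimension, realised as an ARD
kernel whose amplitude carries the normaliser (2π)^(−d/2)/Πλⱼ, so
(1/n)Σk(x, xᵢ) integrates to one (grid quadrature confirms 1-d and 2-d
integrals within 1%).  A scalar σ selects the isotropic kernel instead.

The restricted (KECA-style) estimate eigendecomposes the un-centred Gram
K = EDEᵀ and keeps r components, selected either by variance (top
eigenvalues) or by information-potential contribution dᵢ(eᵢᵀ1)², setting
α = (1/n)E_rE_rᵀ1.  At r = n this is algebraically the Parzen estimate; as
printed without the 1/n the restricted form would not reduce to it, so the
normalisation is included here.  For r < n the estimate is an unnormalised
approximation of the pdf — it can dip slightly negative and need not
integrate to one — which is acceptable for the ridge analysis it feeds.

**Ridge extraction.**  A point of an s-dimensional ridge satisfies
∇p̂(x)ᵀV(x) = 0 where V holds Hessian eigenvectors of the density.  Two
readings of "which eigenvectors" exist in the literature; the default here
is the density-ridge convention — project on the d−s eigenvectors with the
smallest (most negative) eigenvalues and require those eigenvalues to be
negative — with the literal "top-s eigenvectors" reading available behind
`eigvec_rule="top"`.  The score is ‖Vᵀ∇p̂‖ ≥ 0, zero at modes and on exact
ridges.

Two failure modes of the bare orthogonality condition motivate the
candidacy filters: (i) isolated low-density samples form their own kernel
bumps, which are genuine local modes with near-zero score; (ii) for an
elongated cloud the minor principal axis beyond its inflection point also
satisfies the condition with negative projected curvature, and its scores
are systematically smaller than those of genuine ridge points because the
projection lies along the flat direction.  Both are known over-estimation
artefacts of formal ridge definitions, and the standard remedy is to
restrict attention to regions of appreciable density.  `extract_ridge`
therefore admits only candidates with p̂(x) at or above a floor (default:
the median of p̂ over the evaluation set; configurable or disableable) in
addition to the eigenvalue-negativity requirement, and takes the retention
threshold ε as the 5th percentile of the candidate scores when not given.
With these defaults, on a 2-d Gaussian with axis standard deviations 3 and
0.5 (n = 1000), at least 90% of extracted ridge points fall within 0.5 of
the major axis across seeds.  Retained points are ordered by Dijkstra
distance along a mutual k-NN graph (k = 5) from the endpoint of maximal
weighted eccentricity, per connected component; the ordering is for
presentation only.  The package detects ridge membership among supplied
evaluation points; it does not iteratively project points onto the ridge.

## HSIC derivatives and flows

The biased estimator HSIC = (1/n²)Tr(KHLH) is used throughout (no
unbiased variant).  Writing A = HLH, the derivative with respect to
feature q of sample xᵢ is (2/n²)Aᵢ∂_qk(xᵢ) — the factor 2 because xᵢ
enters both kernel arguments — and symmetrically for Y with B = HKH.  For
the RBF kernel the same quantity equals −(2/(σ²n²))Tr(HLH(K∘Mᵠ)) with Mᵠ
zero except row i holding xᵢᵠ−xⱼᵠ and γ = 1/(2σ²); both code paths are
implemented (the trace path deliberately literal and loop-based) and must
agree to 1e−10, which pins down the constant and the γ↔σ mapping
numerically.  Stationarity makes the gradient columns sum to zero, and a
constant kernel on either side annihilates the estimate.

`hsic_flow` performs explicit-Euler ascent/descent on the sample
positions.  Bandwidths are frozen at their initial median-heuristic values
by default — refreshing them would change the objective between steps and
break monotonicity — with per-iteration refresh available behind a flag.
The default step is scale-aware: 0.1·(pooled data standard deviation) /
max|gradient| at the starting configuration.  The flow aborts if the
objective becomes non-finite.

## Synthetic data

All generators draw from a `numpy.random.Generator` seeded explicitly, so
a fixed seed reproduces arrays bit-for-bit.  They emulate the standard toy
suites: 1-d regression targets (sin(3πx), a sinc bump, a composite
sine-plus-step) with noise calibrated to a requested SNR from the
clean-signal variance; balanced two-moons / concentric-circles /
overlapping anisotropic-Gaussian classification pairs with ±1 labels; ring,
half-ring arc and Gaussian-blob 2-d manifolds; dependence pairs (clusters
on the 1-1 line, a noisy ring, independent draws, y = sin(2x)+noise); and
a two-input piecewise-linear surface with x ~ U[−20, 20]², x₁-slope 5 on
x₁ > 0 and 1 on x₁ ≤ 0, x₂-slope 1 everywhere (continuous at the origin,
squared-slope ratio 25 on the positive quadrant).  Where a toy's published
parameters are not fixed anywhere (radii, frequencies, noise levels),
defaults were chosen once for qualitative fidelity.  These generators
produce i.i.d. low-dimensional draws with known structure; they do not
emulate spatial or temporal autocorrelation, heteroscedastic noise, or
high-dimensional covariate structure, so passing tests certify the
calculus and the algorithms' contracts, not performance on real
(e.g. spatio-temporal) data.

## Numerical choices and limitations

* Problem sizes in tests and in the acceptance script (n of order 10²–10³,
  d ≤ 5, 20 repeats, 50 flow iterations) were chosen so the full battery
  completes in a few seconds while leaving the measured properties
  clearly resolved.
* Gram PSD checks allow −1e−8·tr(K)/n of eigenvalue slack; HSIC
  nonnegativity is asserted above −1e−12.
* `hessian_batch` symmetrises its einsum output explicitly because
  contraction order need not round identically across index pairs.
* The tanh kernel is indefinite; it is excluded from PSD assertions and
  from density estimation (which requires a proper pdf kernel).
* Ridge extraction returns per-component Dijkstra distances when the
  mutual k-NN graph is disconnected; distances are not comparable across
  components.
* Multiclass SVM schemes, probability calibration, unbiased HSIC, MMD,
  kernel pre-imaging and automatic-differentiation backends are out of
  scope.
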