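# Methods

`attractormem` models continuous-report ("delayed estimation") working-memory
data: on each trial a subject memorizes one to three hues drawn from a
circular color space, and after a delay reproduces the cued hue on a
continuous wheel. The package implements a drift–diffusion account of how
the remembered hue evolves, the machinery to fit and compare that account by
maximum likelihood, the matching model-free statistics, a ground-truth
simulator, and a warped-space control model. This note records the model,
the numerical choices, and what the synthetic benchmarks do and do not show.

## The generative model

A remembered hue θ (radians on the circle) evolves during the delay as

    dθ = β_L G(θ) dt + σ_L dW,

where G is a drift function shared across loads, β_L ≥ 0 scales its strength
per memory load L, and σ_L scales white diffusion noise. G is a weighted sum
of the first derivatives of 12 von Mises densities whose means tile the
circle one circular SD (2π/12) apart, normalized so max|G| = 1; β_L is then
the maximum instantaneous drift rate in rad/s. Stable fixed points of G
(zeros with negative slope) are discrete attractors: they pull nearby
memories in, trading a bounded systematic bias against unbounded diffusion.

Encoding is a separate, fixed 1-s drift–diffusion stage with its own gains
(β*_L, σ*_L) applied to a von Mises initialization (circular SD 0.1 rad) at
the stimulus hue. The observed report then mixes the propagated target
memory with the propagated non-target memories (swap probability α), a
uniform guess component (probability λ), and an optional von Mises decoding
blur of circular SD σ† applied by circular convolution. λ and α are linear
in the delay, evaluated per trial, clipped to [0, 1], and rescaled
proportionally if their sum exceeds 1 (the clipping rule preserves their
ratio; α ≡ 0 at load 1). The decoding blur is the human-style observation
model; the monkey-style variant omits it.

Throughout, the SD of a von Mises component maps to concentration by
κ = 1/SD², the standard high-concentration approximation.

## Numerics

**State space.** The circle is discretized into 100 evenly spaced bins
(bin k covers [kΔ, (k+1)Δ), centers at (k+½)Δ, Δ = 2π/100). Densities are
per radian; every returned density integrates to 1 within 1e−8.

**Generator.** The Fokker–Planck equation for the drift–diffusion process is
discretized into a continuous-time Markov generator M (columns sum to zero,
off-diagonals nonnegative) using the exponential-fitting
(Scharfetter–Gummel) flux between neighboring bins: the rate from bin j to
j+1 is (D/Δ²)·B(−vΔ/D) with interface velocity v, D = σ²/2 and
B(x) = x/(eˣ−1). This scheme reduces to first-order upwind differencing when
advection dominates, to central diffusion when v = 0, remains a valid
generator at any drift-to-diffusion ratio, and reproduces the stationary
density of the continuous process essentially exactly. σ = 0 falls back to
pure upwind advection. Densities are propagated in closed form with the
matrix exponential; exponentials are cached per (generator, time) because an
experiment has few distinct delays.

**Resolution limit.** The scheme's practical accuracy is set by the grid: a
near-stationary density around an attractor has circular SD
σ/√(2β|G′|), and once that falls below ≈1.6 bins the 100-bin lattice cannot
represent the peak to better than a few percent total variation (e.g. β = 2,
σ = 0.15 with |G′| ≈ 4 gives SD ≈ 1.2 bins and TV ≈ 0.03–0.04 against the
exact stationary density, while an Euler–Maruyama simulation at dt ≤ 0.002
agrees with the exact density to TV < 0.003). The Fokker–Planck-vs-SDE
benchmark therefore probes σ ∈ {0.4, 0.55, 0.75} × β ∈ {0, 1, 2}, the
regime the grid resolves; inside it the two routes agree to TV < 0.02.

**Likelihood.** The report density of a trial is evaluated per radian with
periodic linear interpolation between bin centers (reports are continuous).
The dataset log-likelihood is the sum over trials; a `LikelihoodEngine`
groups trials by (load, delay), precomputes the initial densities and report
interpolation stencils once, and rebuilds only the generators each
evaluation.

**Optimization.** All free parameters — basis weights w_j ∈ [−5, 5], gains
β, β* ∈ [0, 10], scales σ, σ* ∈ [1e−3, 3], guess/swap intercepts ∈ [1e−4, 1]
and slopes ∈ [−0.5, 0.5], σ† ∈ [1e−3, 1] — are fitted jointly with
bound-constrained L-BFGS-B using central finite-difference gradients at
relative step 1e−5. Forward differences at an absolute step near machine
precision are unusable here: the objective passes through matrix
exponentials and the difference quotient drowns in round-off, silently
freezing the rate parameters at their starting values. Each start is
optimized in two stages — rate and mixture parameters first with the drift
shape frozen, then everything jointly, restarting the quasi-Newton state
until the likelihood stops improving (the normalization of G makes the
weight vector scale-free, and the resulting ravine stalls single L-BFGS-B
runs). The default start is data-informed: drift weights from a basis fit to
the derivative of the response-density estimate (attractors sit where
reports pile up), diffusion scales from the dispersion of errors; additional
starts are Latin-hypercube draws inside a plausible sub-box of the bounds.
When a family of nested variants is compared, `fit_variant_family` fits them
in order of increasing complexity, warm-starts each richer model from the
nested optima, and then re-polishes each variant from the others' optima
(projected), so information criteria are never biased by one variant's
optimizer stalling.

**Model comparison.** AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ with
Akaike/Schwarz weights exp(−Δ/2)/Σexp(−Δ/2); cross-validation is k-fold
(default 10) stratified by load × delay; bootstrap uncertainty either
resamples trials and refits (per-session) or resamples per-subject fitted
parameters and averages (population), with percentile intervals and
one-sided contrast p-values.

**Fixed points.** Attractors are located as peaks of the numerical
antiderivative of G (equivalently negative-slope zero crossings, localized
by linear interpolation between bins of opposite sign). Peaks whose
prominence percentile-rank falls at or below 0.20 are excluded; prominences
within 5% of each other count as tied (midrank), so the members of a
near-symmetric attractor set are never dropped — the rank rule is meant to
remove negligible wiggles, and with a single drift function (rather than a
population of subject fits) a plain percentile cutoff would always delete
the weakest genuine attractor. Repellors are then re-paired so stable and
unstable points alternate, keeping the deepest antiderivative trough
between consecutive surviving attractors.

## Model-free statistics

Densities for the model-free analyses use a von Mises kernel density
estimate with circular SD 10° on a 360-point grid, per radian. The
clustering metric is C = H(responses) − H(targets) with the discrete entropy
H = −Σ f log₂ f dθ; on a uniform circular distribution this evaluates to
log₂ 2π ≈ 2.65 bits, which is what pins the per-radian convention. A uniform
component equal in area to the estimated guess rate is subtracted from both
densities (floored at zero, renormalized) before the entropies are taken,
and trials are subsampled to equal per-condition counts (seeded) to equate
estimator bias. Engagement screening fits a three-component
(target/guess/swap) mixture by EM and excludes datasets with an estimated
guess rate above 20%.

Nonuniformity is tested with the Hodges–Ajne count statistic (closed-form
p) and a two-sample Kuiper statistic against the target distribution with a
pooled-relabeling permutation null. Response-histogram peaks are KDE samples
above both circular neighbors, kept when they exceed the 95th percentile of
peak amplitudes from resamples (with replacement) of the target
distribution. Bias (circular mean of signed error) and precision (circular
SD) are binned by target hue (4° default); the slope of bias at an anchor is
an ordinary least-squares line through the bins within ±15°, and the same
window summarizes precision and defines "near" a fixed point in the
error-growth contrast. The attractor/common-color alignment statistic is
the mean distance from each unit's attractors to the nearest reference
color, against a null that re-pairs units and rotates reference sets by a
random phase. These small circular-statistics routines (KDE, Hodges–Ajne,
Kuiper, circular moments) are implemented in-package on top of
numpy/scipy.

## Synthetic data and study conditions

The generator simulates complete experiments: uniform or biased color
environments (four equally spaced 20°-wide common-color clusters at a
random per-experiment phase, each sample biased with probability 0.5),
same-trial colors at least 22° apart by rejection sampling, discrete
64-hue wheels for the monkey-style task, loads 1–3, fixed or continuously
drawn delays. Reports are generated either by sampling the analytic
per-trial report distribution ("mixture" mode) or by Euler–Maruyama
simulation of every memory item at dt = 0.01 s ("sde" mode); the two agree
to TV < 0.03 at 50,000 trials, halving dt moves the histogram by < 0.005 TV
(common-random-number comparison), and the SDE route doubles as the
independent oracle for the Fokker–Planck machinery. The graded juice-reward
schedule of the monkey task (von Mises profile, SD 22°, peak 12 drops,
rounded up, nothing beyond 60°) is included.

The canonical ground truth for recovery studies has four attractors (built,
like the representative drift function, by fitting the basis to the
derivative of a four-mode response density) and per-load gains
β = {0.2, 0.4}, σ = {0.2, 0.35}, β* = {0.3, 0.5}, σ* = {0.1, 0.15} with
modest delay-increasing guess and swap rates. Encoding drift is faster than
memory drift as a rate, and both gain families increase with load. The
magnitudes were chosen by an identifiability analysis of the 1-s/7-s
two-delay design: when β_L|G′| exceeds ≈2.5/s every delay condition sits at
the stationary density, only the width σ/√(2β|G′|) is identified, and the
maximum-likelihood estimate slides along an exact β–σ ridge; at
β_L|G′| ≈ 0.7–1.5/s the 1-s condition is mid-transient and drift and
diffusion separate cleanly. With 4,000 trials the fit then recovers the
drift function at r > 0.99 and the diffusion scales within ±10%.

The normative simulations (expected absolute error over time, by quadrature
over targets and the propagated densities, guesses and swaps off) use a
single representative condition: β = 0.25, σ = 0.15, β* = 0.5, σ* = 0.3,
sized so attraction produces bias of the few-degree magnitude seen in human
reports. In a uniform environment the attractor model is worse early (the
encoding-stage pull corrupts most targets) and better late (drift caps
diffusion), with a single crossover; the crossover time depends entirely on
these representative magnitudes and is not a calibrated quantity. In an
environment where half the targets fall within 10° of attractors, the
attractor model is at least as accurate at every delay, and the advantage
grows monotonically with the biased fraction.

Scaled-down study sizes used by the test suite, chosen as the package's own
benchmark conditions: the model-selection study runs 20 replicates per
condition of 200 load-1 trials on a 48-bin grid with a 6-function basis and
a 2-attractor field (drift truth β = 0.15, β* = 0.8 — the weak memory drift
keeps the 7-s condition mid-transient so encoding and memory drift stay
distinguishable); parameter recovery runs once at the full 100-bin,
12-basis, 4,000-trial configuration; the fixed-point error-growth study
uses β = 0.3, σ = 0.25, where the escape from repellors happens between the
two delays (at much stronger drift the escape completes before the short
delay and the delay contrast vanishes — strong-drift parameters are kept
for the static bias/precision signatures, where they are optimal).

## Warped-space control

The control model explains clustering without attractors: stimulus angles
are projected radially onto a concentric unit square (the hypothetical
"true" perceptual space), memory diffuses as a ±4-site random walk on the
1,024-site discretized perimeter for 1,000 steps, and the diffused position
is projected back. Compression near the square's corners clusters reports
(C < 0), but bias slopes at the cluster peaks are non-negative — repulsive,
not attractive — which is the qualitative dissociation from genuine
attractor dynamics. The projection maps are exact inverses; with diffusion
off the pipeline is the identity up to one perimeter site.

## What the synthetic benchmarks do not show

All tests run on data generated by the model family itself (or the warp
control). They demonstrate internal consistency — correct discretization,
calibrated null distributions, recoverable parameters, selectable model
structure — not that real subjects obey these dynamics. Real data add
features the generator omits: parameter drift across a session (the
learning effects in biased environments), heavy-tailed lapse behavior,
stimulus-specific perceptual anisotropies beyond a single global warp,
serial dependence between trials, and motor noise correlated with response
time. Fitted-parameter magnitudes reported here characterize the synthetic
conditions only.

## Known limitations

- The 100-bin grid cannot resolve stationary widths below ≈1.6 bins; fits
  that push β/σ into that corner are limited by discretization, not data.
- Finite-difference gradients make a full fit O(10²–10³) likelihood
  evaluations per start; analytic differentiation of the matrix exponential
  is out of scope.
- The nested-variant warm-start scheme controls, but cannot eliminate,
  local-optimum risk in the 26-parameter full model; multi-start counts are
  the lever.
- Guess-rate correction in the clustering metric uses one pooled rate, not
  per-condition rates.
- The trial-resampling bootstrap refits the model per iteration and is
  proportionally expensive; population-level uncertainty via
  `subject_params` mode is cheap.
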