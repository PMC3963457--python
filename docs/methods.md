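# Methods

## The model

Let f_X : ℝⁿ → ℝ⁺ be a density estimated from normal data (here: a
multivariate Gaussian or a finite Gaussian mixture, including Parzen-style
kernel mixtures). The probability image space is the univariate space of
density values Y = f_X(X) ∈ [0, y_max], y_max = sup f_X. Its df

G_Y(y) = P(f_X(X) ≤ y) = ∫_{f_X ≤ y} f_X dx

is a distribution over level sets: G_Y(0) = 0, G_Y(y_max) = 1. A point is
"extreme" when its image value falls beneath a low threshold u — a
density-based notion that covers both large-magnitude points and
jointly-improbable points of moderate magnitude (e.g. a modest rise in
respiration rate combined with a modest fall in SpO₂).

### Tail model

Peaks-over-threshold for shortfalls: the depths s = u − y of the tail
values y < u are modelled with a generalised Pareto distribution in the
internal convention

G(s) = 1 − (1 + ξ s/β)^(−1/ξ),  s ≥ 0,  β > 0   (exponential branch at |ξ| < 1e−9),

support [0, −β/ξ] when ξ < 0. This depth orientation is the one under
which the GPD family is threshold-stable: refitting at a deeper threshold
u′ < u leaves ξ invariant and moves β linearly (β′ = β − ξ(u − u′)), and a
memoryless (exponentially decaying) image tail gives ξ = 0 at every
threshold. Some published treatments write the scaled estimator with the
opposite sign of ξ (so that "β = ξu" describes the constrained tie); the
package uses one convention throughout and serialises it explicitly as
`"convention": "internal-v1"`.

Two fit modes:

* **constrained** — the support endpoint is pinned at the threshold,
  β = −ξu, so the image-space boundary y = 0 is exactly the endpoint. One
  free parameter; ξ searched on (−5, −1e−4) by bounded scalar minimisation.
* **free** — (ξ, log β) fitted jointly by bounded quasi-Newton (L-BFGS-B)
  with three deterministic restarts: a moment-matching start, a
  near-exponential start, and an endpoint-tied start from the constrained
  profile (this rescues short-tailed samples, ξ < −0.5, whose optimum hugs
  the sample maximum). Ties are broken by likelihood, then smallest |ξ|.

The scaled tail estimator anchors at the empirical tail fraction (strict
counting, Ĝ_Y(u) = N_u/N with N_u = #{y_i < u}):

Ĝ_Y(y) = (N_u/N) · (1 + ξ(u − y)/β)^(−1/ξ),   y ∈ [0, u],

so Ĝ_Y(u) = N_u/N exactly and, in constrained mode, Ĝ_Y(0) = 0 exactly.

### Standard errors

The default estimator is the inverse observed information (numeric Hessian
of the negative log-likelihood at the optimum). For short tails the MLE is
non-regular — the Fisher information is infinite for ξ ≤ −1/2 and no
asymptotic-normal SE exists — and the Hessian is frequently non-PD at the
optimum; the fallback is then the half-width of the *profile* likelihood
(nuisance parameter re-maximised) at a rise of 0.5, flagged
`se_method="profile"` in the output. In constrained mode the scale SE
follows from the tie: se(β) = u · se(ξ).

### Extended GPD over data space

With a fitted tail, the survival F^e(x) = (1 + ξ f_X(x)/β)^(−1/ξ), clamped
to 0 in the normal region f_X(x) ≥ u, extends the tail model back over the
data space; for a Gaussian f_X it is evaluated in closed form through the
Mahalanobis radius M(x) via log f = −log C_n − M²/2, C_n = (2π)^{n/2}|Σ|^{1/2}.
The normalised extended density f^e(x) = Z⁻¹ G(f_X(x)) (df clamped to 1 in
the normal region) is computed by trapezoid quadrature for n ≤ 3; the grid
must capture ≥ 99% of the model's own mass or the computation refuses with
a diagnostic. The visualisation transform φ(x) = 1 − log f^e(x) grows with
extremeness.

### Closed-form Gaussian image df

For Gaussian f_X the squared Mahalanobis radius is χ²_n, so with
t = −2 log(y C_n),

G_Y(y) = P(χ²_n ≥ t),

which expands to a finite series: for even n = 2p a polynomial
y · Σ_k A_n^k t^{p−k−1}, for odd n = 2p+1 the analogous half-integer-power
series plus an erfc(√(t/2)) term. The coefficient tables use the
unit-sphere surface area Ω_n = 2π^{n/2}/Γ(n/2); with that constant the
series is *exact* (machine-precision agreement with the χ² survival
function for n = 1…8, and G(1/C_n) = 1 identically — both certified in the
test suite, along with a Monte-Carlo check at N = 1e5 for n ∈ {1,…,7}).
Series terms are evaluated in the log domain so that y near underflow maps
continuously to G = 0.

## Two-stage novelty scoring

Stage 1 is the conventional gate on the novelty score z(x) = −log f_X(x):
a point is "extreme" iff z > κ_z, equivalently y < κ_y = exp(−κ_z) (the
boundary point itself is normal; the two gates are verified to agree on
every point). Stage 2 scores the extreme points with Ĝ_Y(y) ∈ [0, N_u/N]:
monotone in depth-of-tail, anchored at the threshold. No per-point verdict
is attached — the score orders extreme points so a downstream consumer can
separate extreme-but-normal from extreme-and-abnormal populations; the
`compare_tail_populations` report (QQ tables against the fitted GPD plus a
two-sample Kolmogorov–Smirnov distance) supports the population-level
version of the same question.

## Diagnostics

* **QQ table** — empirical type-1 quantiles of the tail depths at
  percentiles i/100 against the fitted GPD quantiles (grid coarsened and
  flagged below 100 points; an unbounded model's top percentile is
  evaluated just inside the support and flagged; an all-constant sample
  yields a degenerate-flat flag, not an exception).
* **Mean excess** — the shortfall magnitude mean(u − y | y < u), reported
  positive. If the tail is GPD the mean excess is linear: in the classical
  exceedance orientation (`side="above"`, for direct GPD samples) the slope
  in the threshold is ξ/(1−ξ) with intercept β/(1−ξ); in the image-space
  shortfall orientation (`side="below"`) the same line appears with the
  axis mirrored, slope −ξ/(1−ξ). The closed form (β + ξu)/(1 − ξ) requires
  ξ < 1.
* **Threshold stability** — `fit_tail` repeated over a threshold grid
  (default: 25 log-spaced thresholds between the 0.5% and 20% image
  quantiles); grid points with fewer than the minimum tail count (default
  30) are skipped and flagged rather than reported as garbage.
* **Records** — a record occurs at index i when y_i < min(y_1…y_{i−1})
  (strict: a repeated minimum is not a record; y_1 is the first record).
  Under i.i.d. sampling E[N_i] = Σ 1/k (harmonic number, computed exactly
  via the digamma identity) and var[N_i] = Σ(1/k − 1/k²), with
  E[N_i] − log i → γ ≈ 0.5772. The calibration report lists, for each
  observed record, the expected count at its index with a ±2 sd band, and
  flags the sequence consistent with i.i.d. iff ≥ 95% of records fall
  inside the band. Note the band events are strongly correlated along one
  sequence, so the family-wise coverage of this rule under true i.i.d.
  sampling is ≈ 82% at length 1e4 — materially below the per-record 95%;
  treat a single "inconsistent" flag as a prompt to look at the table, not
  as a hypothesis test at α = 0.05.

## Synthetic fixtures: what they emulate

All constants live in `src/densitytail/data/fixtures_config.json`; every
fixture is bit-reproducible from (name, parameters, seed).

* `standard_gaussian_fixture(dim, …)` — standard Gaussians of dimension
  1–7 for the image-space experiments (y_max = (2π)^{−n/2}: 0.0635 at
  n = 3, 0.0016 at n = 7).
* `bivariate_mixture_fixture` — an 8-component bimodal 2-D mixture with
  unequal mode heights (global modal density ≈ 0.31, a visible secondary
  peak in the image-space pdf) and N = 1e5 samples. The component
  constants are artifact choices with the documented qualitative
  structure; they do not reproduce any published figure numerically.
* `vitalsign_fixture(n_normal, n_abnormal, seed)` — a 4-D stream (heart
  rate, respiration rate, SpO₂, systolic blood pressure; plausible adult
  ranges documented in the config). The model of normality is a 400-kernel
  Parzen mixture (seeded k-means centres on 4000 draws from a documented
  two-component physiological base, shared Silverman bandwidth); normal
  rows are drawn from that model itself, abnormal rows from a documented
  two-regime mixture in which respiration and heart rate rise while SpO₂
  falls, including a jointly-improbable-but-individually-moderate
  sub-regime with inverted heart-rate/respiration correlation. Labels are
  attached. The fixture does *not* model temporal autocorrelation — a
  green pipeline test establishes score separation between regimes, not
  performance on real, serially-dependent patient data.
* `gpd_fixture(params, u, count, seed)` — inverse-cdf GPD samples for
  parameter-recovery tests. Image samples "whose tail is exactly GPD" are
  built as y = u − s from these draws, so the shortfall depths are exact
  GPD variates.

## Numerical choices

* Mixture densities by log-sum-exp; underflow maps to log-density −inf and
  image value 0 (a legal image value; depths equal to u are nudged inside
  the support by a relative 1e−15 to keep the constrained likelihood
  finite).
* Mixture modal density by L-BFGS-B ascent on −log f with analytic
  gradients, started from every component mean (for kernel mixtures with
  more than 16 components: from the 16 highest-density means; the result
  is always ≥ the density at every component mean and is a certified lower
  bound on sup f, refined numerically).
* ξ = 0 branch switch at |ξ| < 1e−9; the exponential branch is exact to
  ~1e−9 relative at the switch.
* Empirical quantiles use the type-1 rule (order statistic at ⌈p·n⌉) with
  a 1e−9 backoff against floating-point p·n landing just above an integer.
* `image_quantile` returns the smallest stored value whose strict-counting
  empirical df reaches the level (ties share a df value; the maximum is
  returned when no value reaches the level).
* Parzen bandwidth: Silverman's multivariate factor
  (4/(d+2))^{1/(d+4)} m^{−1/(d+4)} on the mean marginal standard
  deviation, or a user-fixed value; zero-variance training columns are
  rejected.
* All randomness flows through `numpy.random.default_rng` seeded per
  fixture stream; CLI runs record inputs (SHA-256), seeds and versions in
  a manifest.

## Known limitations

* The constrained fit assumes a compact tail touching y = 0; for models
  whose image tail is genuinely light-but-unbounded the free mode should
  be used and the QQ/mean-excess diagnostics consulted.
* Standard errors in the non-regular regime (ξ ≤ −1/2) are profile-based
  summaries of likelihood curvature, not asymptotic-normal SEs; coverage
  statements there are approximate.
* The numeric extended GPD is quadrature-based and limited to n ≤ 3; in
  higher dimension work directly in the image space.
* Threshold *selection* is deliberately out of scope: the stability sweep,
  mean-excess curve and QQ table are exported as data for a human analyst.
* The record diagnostic detects non-i.i.d. behaviour but the fixtures do
  not simulate serial dependence, so its power against realistic
  autocorrelation is not established by this test suite.
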