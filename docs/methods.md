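# Methods

## Model and estimators

### Correlation entropy K2 at finite scale

Given a univariate series x_1..x_N, delay vectors V_i = [x_i, x_{i+L},
..., x_{i+(m-1)L}] are formed and the correlation integral C^(m)(eps) is
the fraction of unordered distinct vector pairs whose maximum-coordinate
(Chebyshev) distance is at most eps.  The correlation entropy at scale
eps is estimated as

    K2(eps) = [ln C^(m)(eps) - ln C^(m+1)(eps)] / (L * dt),

which at fixed eps is the sample entropy (SampEn) without self-matches.
Conventions, all configurable:

* **Distance** is Chebyshev.  With unit delay this gives the prefix
  property — an (m+1)-dimensional match implies an m-dimensional match —
  which in turn guarantees C^(m+1) <= C^(m) and K2 >= 0.
* **Shared template set.**  Both correlation sums run over the same
  N - m*L templates (the SampEn convention of Richman and Moorman).
  Using the full N - (m-1)L vector set for the m-dimensional sum would
  break the prefix property at the margin and allow spurious negative
  entropies.  The standalone `correlation_integral` function, by
  contrast, uses the full vector set of its own dimension, which is the
  textbook definition of C^(m).
* **Ties count.**  A pair at distance exactly eps is a match (Heaviside
  step with H(0) = 1).
* **Normalization** divides by L*dt with dt = 1 by default, i.e. entropy
  per sample.  Dividing additionally by m — a variant sometimes seen in
  print — would scale the K2-vs-ln(eps) slope by 1/m and is incompatible
  with the unit-slope scaling law below; it is not used.
* **Delay** L = 1 and embedding dimension m = 2 by default (m = 5 for the
  HRV pipeline); no Theiler window by default, though one is available
  via `EmbeddingConfig(theiler=...)`.
* **Definedness.**  A K2 value is reported only when both correlation
  sums contain at least `min_pairs` (default 10) matching pairs;
  otherwise it is NaN, never silently 0.  This threshold also defines
  eps* (below).

The pair counting is O(N^2) and is performed by a compiled (numba)
kernel when numba is importable, with a chunked numpy fallback that
produces bit-identical counts; both are cross-checked in the tests
against a brute-force double loop.

### Multiscale entropy and the bi-scaling law

Coarse-graining replaces the series by means over non-overlapping blocks
of size bs (trailing remainder dropped; full blocks only).  For fGn with
Hurst parameter H the aggregated variance obeys var(X^(bs)) =
sigma^2 * bs^(2H-2), so a scale eps for the raw data corresponds to
bs^(H-1) * eps for the smoothed data.  Combined with the small-scale law
K2(eps) ~ -ln(eps) this yields the bi-scaling law

    K2^(bs)(eps) ~ (H - 1) ln bs - ln eps.

Crucially, the MSE surface holds eps fixed in **original-data units**
across block sizes (by default as a fraction of the original series'
standard deviation, converted to absolute units once).  Re-normalizing
eps by each smoothed series' own SD would cancel the variance decay and
erase the (H-1) ln bs term.

The Hurst estimator is h_hat = 1 + slope from the OLS regression of
K2^(bs)(eps) on ln bs, by default over bs = 1..10 at eps = 0.2 x SD.
For white noise h_hat -> 1/2 (entropy decays as -(1/2) ln bs); for 1/f
noise the MSE curve is flat and h_hat -> 1.

### Shannon–Kolmogorov (rate-distortion) entropy

For a stationary Gaussian process with PSD Phi(omega) on (-pi, pi], the
entropy at mean-square distortion eps^2 follows the Kolmogorov
water-filling construction: theta solves
(1/2pi) Int min[theta, Phi] = eps^2 and
h_SK = (1/4pi) Int max{0, ln(Phi/theta)}.
fGn has Phi(omega) = B(H) |omega|^(1-2H) with B(H) =
sigma^2 (2-2H) pi^(2H-1), fixed by requiring the same variance sigma^2
for every H.  For small eps this gives the closed form
h_SK = A(H) - ln eps with A(H) = (1/2) ln sigma^2 +
(1/2)[ln(2-2H) - (1-2H)], maximal at H = 1/2.

Numerical choices: for power-law PSDs both integrals are evaluated in
closed form (the omega -> 0 singularity for H > 1/2 is integrable and
integrated analytically, with the integration domain split at the
water-line crossing Phi(omega*) = theta); theta is found by bracketed
Brent root-finding to relative tolerance 1e-12, and the distortion
residual at the solution is below 1e-8.  Arbitrary PSDs fall back to
adaptive quadrature.  eps^2 greater than the process variance is
rejected explicitly (the h_SK = 0 regime).

The closed form is a small-eps asymptote: the exact water-filling value
deviates from A(H) - ln eps by O(omega*) where omega* is the water-line
crossing.  At eps = 0.05 sigma the two agree to better than 1e-4 for all
H in [0.1, 0.9]; at eps = 0.2 sigma the gap grows toward strongly
anti-persistent processes, reaching ~1.5e-3 at H = 0.1.  The package
always computes the exact value and exposes the closed form separately.

## Scaling fits and diagnostic features

* `fit_eps_scaling` — OLS of K2 on ln eps over the defined points of a
  curve, optionally restricted to an eps range.  The fitted scaling
  region for the headline slope checks is eps in [0.01, 0.5] x SD on a
  25-point log grid; the small-eps end is bounded by the min-pairs
  threshold, the large-eps end by saturation as C^(m) -> 1.
* `fit_bs_scaling` — OLS of K2^(bs) on ln bs at fixed eps; reports
  h_hat = 1 + slope, its standard error, and which block sizes failed
  the pair-count threshold.
* `epsilon_star` — the smallest grid eps at which K2 is defined.  The
  underlying idea, "the smallest scale resolvable by the data", is a
  statement about statistical sufficiency, operationalized here by the
  min-pairs criterion.
* `fit_error_feature` — the relative RMS residual (x100) of an OLS line
  through `n_points` (default 6) consecutive defined scales starting at
  eps*.  The error normalization is RMS residual divided by the mean
  |K2| over the window; "percentage of fit error" admits several
  formulas and this one is recorded and configurable.

## Synthetic generators

* **fGn** by circulant (Davies–Harte) embedding of the exact
  autocovariance r(k) = (sigma^2/2)(|k+1|^2H - 2|k|^2H + |k-1|^2H):
  exact in distribution, so the correlation structure is right at every
  lag — a prerequisite for testing the bi-scaling law, which probes all
  scales at once.  The circulant eigenvalues are provably non-negative
  for fGn; tiny negative values from roundoff are clipped at a 1e-9
  relative tolerance and anything larger raises.
* **1/f^alpha noise** by random-phase spectral synthesis: deterministic
  Fourier amplitudes f^(-alpha/2), uniform random phases, zero DC bin,
  Hermitian symmetry via the real inverse FFT, output rescaled to unit
  variance.  This covers the alpha = 1 (H = 1) boundary that fGn cannot
  reach.  Because the amplitudes are non-random, the periodogram follows
  the target power law exactly, which the tests exploit as an oracle.
* **Random walk / difference** are exact inverses up to the first
  sample: the walk prepends no zero, so differencing it returns the
  original series minus its first point.
* All generators draw from `numpy.random.default_rng(seed)` with one
  seed per call and no global state; fixed seed implies bit-identical
  output.

## Physiological feature pipelines

**HRV.**  RR-interval series are nonstationary with anti-persistent
1/f-type increments, so features are computed on the first-differenced
series: the K2(eps) curve at m = 5, eps*, and the 6-point fit error.
Records longer than 30,000 points are truncated to that length
(configurable).  The eps grid here is **absolute** (seconds, log-spaced
over 1e-4..1) and shared across records, because the clinically
discriminating information in eps* is the amplitude of the RR
variability itself — heart-failure records have strongly reduced
variability and hence a smaller resolvable scale — and per-record SD
normalization would erase exactly that.

**EEG.**  EEG segments behave like random walks, so MSE is computed on
the differenced data by default (a `raw` flag is available).  Features
are K2^(bs)(eps) at the requested (bs, eps) cells — bs = 2 and 15 at
eps = 0.2 and 0.05 by default — with eps as a fraction of the SD of the
analyzed (post-preprocessing) record, plus an h_hat fitted across the
requested block sizes.  With 4097-point segments, block sizes near 20
leave only ~200 samples and are allowed but warned about.

**Group summaries** report per-group mean/SD of each feature and a
complete-separation flag: whether the per-group [min, max] ranges are
pairwise disjoint.  No significance testing or trained classifier is
included; separation-by-ranges is the criterion of interest.

## What the synthetic benchmarks do and do not show

The generators emulate the correlation structure (Hurst scaling) and the
amplitude relationships of the target signals, under Gaussianity and
stationarity (of increments).  They do not emulate multifractality,
nonlinear phase coupling, ectopic-beat artifacts, or measurement
drift — so passing the synthetic group-separation tests demonstrates
that the feature definitions behave as designed, not that any clinical
discrimination level is attained on real recordings.  Two fixture
choices deserve note:

* A smooth random walk analyzed raw yields *abundant* template matches
  (its K2 is near zero at most scales), so "failure on nonstationary
  data" manifests as a grossly non-fractal K2 curve (slope far from -1),
  not as missing values; the tests check the scaling-quality property.
* Additive stationary contamination (Gaussian or spiky) largely
  preserves the -ln eps law and does not reliably inflate the 6-point
  fit error; coarse measurement quantization does, by placing a
  staircase inside the fit window, and is used as the poor-scaling
  fixture.

## Problem sizes and tolerances

Headline simulation checks use 2^14-point signals, m = 2, five fixed
seeds, eps grids of 25 log-spaced points (slope checks) or the single
value 0.2 x SD with bs = 1..10 (Hurst recovery); unit tests use
2^12..2^13 points with proportionally looser tolerances.  Monte-Carlo
distributional checks average 20–50 seeds.  OLS fits use
`scipy.stats.linregress`; exact-line fixtures are recovered to 1e-12.
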