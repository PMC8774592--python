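# Methods

This note records the model assumptions, the numerical conventions, and the
design choices behind `ordentropy`, at the level of detail a maintainer or a
careful user needs.  Notation follows the README: ordinal range
`s_0 < … < s_m`, marginal CDF `f_i = P(X ≤ s_i)` with `f = (f_0, …, f_{m−1})`,
lagged bivariate CDF `f_ij(h) = P(X_t ≤ s_i, X_{t−h} ≤ s_j)`.

## Entropy generating functions

An EGF is concave on [0, 1] with φ(0) = φ(1) = 0.  Shipped families:

| family | φ(z) | parameter, default domain | notes |
|---|---|---|---|
| a-entropy | (z − z^a)/(a − 1) | a > 0, a ≠ 1 | a = 2, 3 both give the IOV |
| Shannon | −z ln z | — | the a → 1 limit; 0 ln 0 = 0 |
| q-entropy | 1 − \|2z − 1\|^q | q ≥ 2 (q ∈ [1, 2) behind an opt-in flag) | q = 1 is Leik's measure |

EGFs are first-class values carrying closed-form first and second
derivatives; no production code differentiates numerically (finite
differences appear only in tests).  Conventions 0 ln 0 = 0 and 0⁰ = 1 are
applied explicitly, so φ_q derivatives are continuous at z = ½ for q ≥ 2.

**Smoothness bookkeeping.**  The asymptotic theory needs φ′ (variance) and
φ″ (bias, κ_φ).  A `smoothness_order` field encodes differentiability *on
the open interval*: 2 for every a-entropy with a > 1 and for Shannon, 2 for
q ≥ 2, 1 for q ∈ (1, 2), 0 for q = 1 and for a < 1.  Boundary divergence
(e.g. Shannon's φ″ = −1/z at z = 0) is a separate phenomenon handled at the
point of evaluation: weight entries at boundary CDF components come out as
flagged infinities with a warning, and the asymptotic routines drop the
affected summands — the same workaround recommended for the per-category
standardized κ\*.  a < 1 is constructible (its dispersion values are fine)
but barred from all asymptotic paths: its boundary blow-up makes the normal
approximation practically useless.  q ∈ [1, 2) requires an explicit
`allow_nonsmooth=True` and is likewise barred; for those cases only plain
dispersion values (e.g. Leik via `lov`) are meaningful, and resampling would
be the route to uncertainty statements.

## Dispersion asymptotics

With gradient weights `d_k = (φ′(f_k) − φ′(1 − f_k)) / (2 m φ(½))` and
Hessian-diagonal weights `h_kk = (φ″(f_k) + φ″(1 − f_k)) / (2 m φ(½))`:

- `σ²_iid = Σ_{i,j} d_i d_j (f_min(i,j) − f_i f_j)`;
- variance under dependence: `σ² = σ²_iid (1 + 2 Σ_h ϑ_φ(h))` with
  `ϑ_φ(h) = Σ d_i d_j (f_ij(h) − f_i f_j) / σ²_iid`;
- first-order bias: `(1/2n) Σ h_ii f_i(1 − f_i) · (1 + 2 Σ_h κ_φ(h))`,
  always ≤ 0 by concavity.

The reported `se_factor` is `√(1 + 2 Σ ϑ_φ(h))` — the multiplier on the
*standard error* scale, which is the number practitioners quote; the
variance-scale factor is exposed alongside it.  Confidence intervals are
`bias-corrected estimate ± z_{1−α/2} · σ̂/√n`, two-sided, default level
0.95 (z = 1.96).

**Dependence modes.**  `iid` uses factors 1.  `plugin:H` sums empirical
ϑ̂, κ̂ over lags 1..H; H is a deliberate user choice — automatic lag
selection for these sums is an open research question and silently picking
one would hide a consequential decision.  A Markov model computes the
factors exactly from its own stationary law (they are ratios of model
quantities), while the i.i.d. ingredients σ²_iid and the bias prefactor are
still evaluated at the sample CDF when data are analyzed — the factors
describe the dependence structure, the plug-ins describe the observed
marginal.

**Infinite sums.**  Model-implied lag sums truncate when both per-lag
increments fall below `tol` (default 1e−10), hard cap 10⁴ lags.  The
shipped chains mix geometrically, so the discarded tail is far below the
reporting precision (the fitted air-quality chain needs 27 lags).

**Degenerate cases.**  At the extreme two-point CDF all d_k vanish, the
linear Taylor term dies, and the estimator's limit is χ²-type rather than
normal.  This is detected (‖d‖ < 1e−12), flagged, and the normal CI is
withheld (NaN bounds); no χ² interval is constructed.  One-point marginals
give dispersion 0 with SE 0.

## Serial dependence: κ_φ and its test

`κ_φ(h)` uses curvature weights `w_i = φ″(f_i) + φ″(1 − f_i)` (≤ 0); it is
0 under independence, 1 under perfect positive lag-h agreement, and reduces
to the ordinal Cohen's κ for constant weights (a = 2, 3) and to the
averaged per-category standardized κ\* for Shannon.  κ\*'s division-by-zero
at boundary f_i is resolved by zeroing the affected summands while still
averaging over all m (a `legacy_eps` option instead floors the zero
variance at ε for comparability with older simulation conventions).

Under the i.i.d. null, `√n (κ̂_φ(h) + 1/n) → N(0, σ²_κ)` with
`σ²_κ = Σ_{j,k} u_j u_k (f_min(j,k) − f_j f_k)²` and normalized weights
`u_j = w_j / Σ_i w_i f_i (1 − f_i) ≥ 0`.  The bias −1/n is the same for
every EGF.  The test therefore uses the *asymmetric* critical pair
`−1/n ± z_{1−α/2} σ̂_κ/√n`, centered at the null mean, with σ̂_κ from the
sample CDF; p-values are two-sided normal; no multiplicity adjustment
across lags (per-lag bands, as is conventional for correlograms).

**Vanishing curvature weights.**  For φ_q with q > 2 the curvature is zero
at f_i = ½, so at the polarized CDF all weights vanish and κ_φ is a 0/0
form.  The implementation falls back to the constant-weight (ordinal-κ)
limit with a warning; on a binary scale this is the exact limit (and makes
σ²_κ = 1 there for every EGF, by cancellation).

**Covariance blocks.**  The i.i.d. covariance matrix of
(f̂, diag f̂(h)) has blocks `c_ij`, `2 f_j c_ij`, and
`(f_min + 3 f_i f_j) c_ij` with `c_ij = f_min(i,j) − f_i f_j`.  Contracting
it with the gradient of κ_φ at the null (entries −2 f_j u_j and u_j)
reproduces σ²_κ exactly; the test suite verifies this identity to 1e−10 on
random CDFs and pins the blocks down independently with an exact
small-sample enumeration oracle (all sequences of length 6 on a binary
scale).

## Empirical CDFs

`f̂_i` uses denominator n; the lagged bivariate `f̂_ij(h)` averages the
pair indicators over the n − h available pairs.  The pair-count denominator
makes each entry an unbiased mean; relative to full-sample marginals the
coupling identities then hold only up to O(h/n) edge effects, which is
immaterial for the asymptotics and accounted for with a 1/(n−h) tolerance
when invariants are checked on data.  Category labels are ranked strictly
by their position in the user's scale configuration — never
lexicographically — and unknown labels are a hard error.  Categories never
observed remain legitimate levels (flat CDF segments), which is why every
downstream routine must, and does, cope with boundary f̂_i ∈ {0, 1}.

## Markov-chain calculators

A chain on {0, …, m} with transition matrix P and stationary law π yields
`f_ij(h)` exactly via `Σ_{k≤j} Σ_{l≤i} π_k (P^h)[k,l]`.  The stationary law
solves the overdetermined system (πP = π, Σπ = 1) by least squares after an
ergodicity check (some power of P up to 2(m+1) strictly positive).  Matrix
powers are plain repeated multiplication — state spaces here are tiny and
exactness beats elegance.

Shipped processes:

- **BAR(1)** `bar1_model(m, p, ρ)`: binomial autoregression
  `I_t = α ∘ I_{t−1} + β ∘ (m − I_{t−1})` with thinning probabilities
  α = p(1−ρ) + ρ, β = p(1−ρ); stationary Bin(m, p), rank-count ACF ρ^h.
  Negative ρ is attainable only down to max(−(1−p)/p, −p/(1−p)) (the range
  where both thinning probabilities stay in [0, 1]); out-of-range ρ is
  rejected with the bound in the message.  ρ = 0 gives the i.i.d. generator
  used as the null throughout.
- **One-inflated truncated Poisson** `oitp_model(λ0, λ1, ω, m)`: row k
  mixes a point mass at state 1 (weight ω) with Poisson(λ0 + λ1·k)
  truncated to {0, …, m}.  The defaults (0.3489, 0.7594, 0.3463, m = 5) are
  the published fit to the daily Shanghai air-quality level series; only
  this reduced univariate form is implemented — covariates and any
  zero-inflation component of the original model class are out of scope.
  One-inflation is read as a mixture on the *conditional* law, which
  reproduces the published dependence factors to printed precision.

## Simulators and study harness

Paths are drawn by inverse transform from the rows of P, starting from the
stationary law; R replications advance in lockstep (one vector operation
per time step), so 10⁴ replications of length 500 cost seconds.  Every
entry point requires an explicit seed; studies derive one child stream per
scenario from (seed, scenario index) so any cell is reproducible in
isolation.  Identical configuration and seed give byte-identical tables.

`run_dispersion_study` reports simulated mean/SD of CPE_φ(f̂) against the
asymptotic mean (bias-corrected) and SE, with Monte-Carlo standard errors;
`run_size_power_study` reports rejection rates of the lag-1 test with
binomial MC-SEs.  Default replication count is 10⁴.

**What the generators do and do not emulate.**  The synthetic processes
cover stationary, geometrically mixing ordinal dynamics with fully known
theory — exactly the regime the asymptotics address.  They do not emulate
non-stationarity (trends, seasonality, regime shifts), covariate effects,
missing data, or long memory; green calibration results here say nothing
about such data.  Real series should be checked for stationarity before
the CIs are trusted.

## Known numerical limitations

- **Finite-sample SE under dependence.**  The asymptotic variance uses the
  full infinite lag sum, whereas the variance of a length-n average weights
  lag-h autocovariances by (1 − h/n).  Under medium dependence (ρ = 0.4)
  at n = 50 this makes the true sampling SD sit ~2–3% below the asymptotic
  SE — visible in tight Monte-Carlo comparisons, negligible by n ≥ 250.
  The reported intervals are therefore slightly conservative for short
  dependent series.
- **OV_q near polarization.**  The identity
  OV_q = 1 − (1 − CPE_{φ_q})^{1/q} is exact in real arithmetic but
  catastrophically cancels in floating point when the CDF is near the
  polarized point; validations compare on the complementary scale
  (1 − OV_q)^q = 1 − CPE, which is well conditioned.
- **Small n with sparse categories.**  For a < 2 the curvature weights
  diverge at empty categories; the summand-dropping workaround keeps the
  statistics finite but adds finite-sample noise, one reason the a ≥ 2
  members are the recommended default (a = 5/2 in the examples).
- Test sizes run slightly above nominal for n ≤ 100; by n = 500 the 5%
  level is met within Monte-Carlo accuracy (the study harness reproduces
  both regimes).
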