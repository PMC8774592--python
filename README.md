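# ordentropy

Entropy-based dispersion and serial-dependence analysis for **ordinal time
series** — categorical sequences whose levels carry a natural order but no
numeric scale (air-quality levels, credit ratings, sleep stages, pain
severities, Likert responses).

For such data the variance and the autocorrelation function are meaningless,
yet applied questions remain the same: *how dispersed are the observations*,
and *are consecutive observations dependent*?  `ordentropy` answers both
with one coherent family of measures built from the cumulative distribution
function, together with asymptotic standard errors, bias corrections,
confidence intervals, and a significance test for serial dependence.

## The measures

Let the range be `s_0 < s_1 < … < s_m` and `f_i = P(X ≤ s_i)` the marginal
CDF (the vector `f = (f_0, …, f_{m−1})`).  Every concave *entropy generating
function* (EGF) φ on [0, 1] with φ(0) = φ(1) = 0 induces the normalized
**cumulative paired φ-entropy**

    CPE_φ(f) = 1 / (2 m φ(½)) · Σ_{i<m} [ φ(f_i) + φ(1 − f_i) ],

which equals 0 exactly for one-point distributions (maximal consensus) and 1
exactly for the extreme two-point distribution (maximal polarization).
Classical ordinal dispersion indices are members: Leik's ordinal variation
(φ_q, q = 1), the OV_q family (φ_q(z) = 1 − |2z − 1|^q), the index of
ordinal variation IOV (a = 2), and the cumulative paired Shannon entropy
(φ(z) = −z ln z, the a → 1 limit of the a-entropies φ_a(z) = (z − z^a)/(a − 1)).

For stationary short-memory series, the plug-in estimator CPE_φ(f̂) is
asymptotically normal with variance `σ²_iid · (1 + 2 Σ_h ϑ_φ(h))` and a
negative O(1/n) bias proportional to `1 + 2 Σ_h κ_φ(h)`, where

    κ_φ(h) = Σ_i w_i (f_ii(h) − f_i²)  /  Σ_i w_i f_i (1 − f_i),
    w_i = φ″(f_i) + φ″(1 − f_i),

is a **weighted ordinal Cohen's κ** at lag h built from the lagged bivariate
CDF `f_ij(h) = P(X_t ≤ s_i, X_{t−h} ≤ s_j)`.  Constant weights recover the
classical ordinal κ.  Under the i.i.d. null, `√n κ̂_φ(h)` is asymptotically
normal with mean bias −1/n and a computable variance σ²_κ — the basis of the
per-lag serial-dependence test this package provides.

Exact Markov-chain calculators (stationary laws, lagged bivariate CDFs,
dependence factors via matrix powers) and seeded simulators — a binomial
AR(1) chain with Bin(m, p) marginal and geometric ACF, and a one-inflated
truncated-Poisson autoregressive chain — make every asymptotic statement
checkable without external data.

## Worked example

Analyze a six-level ordinal series (here: a daily air-quality level series
of length 2068 drawn from the package's fitted one-inflated
truncated-Poisson chain, `oitp:defaults`), with the recommended a-entropy
EGF a = 5/2:

```sh
ordentropy measure --input series.csv --scale scale.yaml --column level \
    --egf a-entropy:a=2.5 --dependence oitp:defaults
```

```json
{
  "egf": "a-entropy:a=2.5",
  "n": 2068,
  "estimate": 0.37651211561370196,
  "bias": -0.0003362374820342973,
  "bias_corrected": 0.3768483530957363,
  "se": 0.01340528161487653,
  "ci": [0.35057448392796137, 0.4031222222635112],
  "level": 0.95,
  "dependence_mode": "model",
  "degenerate": false
}
```

The point estimate 0.377 says the series is markedly closer to consensus
than to polarization; the serial dependence in the data inflates the i.i.d.
standard error by the model-implied factor 1.343 and the (negative) bias by
1.907, which the bias-corrected estimate and the 95% CI above already
incorporate.  Those factors come from the exact chain arithmetic:

```sh
ordentropy theory --model oitp:defaults --egf a-entropy:a=2.5 --head 3
# "kappa_head": [0.2749, 0.1046, 0.0428], "bias_factor": 1.9069992,
# "theta_head": [0.2645, 0.0848, 0.0312], "se_factor":   1.3430218
```

Testing for serial dependence, lag by lag:

```sh
ordentropy test --input series.csv --scale scale.yaml --column level \
    --egf a-entropy:a=2.5 --lags 1:3
```

```
lag 1: kappa_hat 0.281  reject true   (p ≈ 2e-88)
lag 2: kappa_hat 0.105  reject true   (p ≈ 9e-14)
lag 3: kappa_hat 0.058  reject true   (p ≈ 3e-05)
critical pair: [-0.0281, 0.0272]   (centered at the null mean -1/n)
```

All three lags reject independence at the 5% level: κ̂_φ(1) ≈ 0.28 indicates
a medium positive dependence that decays quickly, AR(1)-like.  Note the
critical pair is asymmetric around zero because the null mean of κ̂_φ is
−1/n, not 0.

The same steps are available as library calls (`estimate_dispersion`,
`test_serial_dependence`, `theoretical_kappa_sequence`), and
`ordentropy simulate` runs seeded Monte-Carlo studies of estimator
calibration and test size/power over a DGP × EGF grid.

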