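# hvgchaos

Horizontal-visibility-graph (HVG) quantifiers for deciding whether an
irregular scalar time series is governed by low-dimensional deterministic
chaos or by a (correlated or uncorrelated) stochastic process — a question
that autocorrelation and power spectra cannot settle, since chaotic and
stochastic signals share wide-band spectra and delta-like correlations.

The package is aimed at practitioners of nonlinear time-series analysis
(physics, ecology, physiology, econophysics) who want graph-based
complexity quantifiers with a fully seeded synthetic benchmark: 27 standard
chaotic maps, the intermittent Schuster map, the Lorenz and Rössler flows
reduced to minimum maps, f^−k spectrally filtered noises, fractional
Brownian motion / fractional Gaussian noise, and noise-contaminated chaos.

## Method

A series x₁, …, x_N maps to a graph with one node per observation; nodes
i < j are linked iff every intermediate observation lies strictly below
both ends, xₙ < min(xᵢ, xⱼ) for i < n < j. The graph is invariant under
x → a·x + b (a > 0) and its node-degree distribution P(κ) is the object
all quantifiers operate on:

- **λ tail rate** — fit P(κ) ∝ e^(−λκ) by least squares on ln P(κ) over an
  explicit scaling region. For iid noise, P(κ) = (1/3)(2/3)^(κ−2), so
  λ = ln(3/2) ≈ 0.4055; λ below / at / above ln(3/2) has been proposed as a
  signature of chaotic / uncorrelated / correlated dynamics. The package
  reports the 95 % confidence interval and R², classifies accordingly, and
  deliberately exposes the scaling region as a parameter — the rule's
  sensitivity to that choice, and its outright failures (e.g. the Holmes
  cubic map fits well with λ > ln(3/2); heavy-tailed intermittent maps
  admit no single scaling zone), are reproducible with two calls.
- **Quantile shape** — Bowley skewness
  SK = [Q(3/4) + Q(1/4) − 2Q(1/2)] / [Q(3/4) − Q(1/4)] and Moors kurtosis
  on octiles KR = [(E₇−E₅) + (E₃−E₁)] / (E₆−E₂), robust summaries suited to
  the asymmetric, sometimes heavy-tailed P(κ).
- **Shannon–Fisher plane** — the pair (H, F) with
  H = S[P]/S_max (S = −Σ p ln p; normalized either by ln of the number of
  support states or by a pinned white-noise reference entropy) and
  F = F₀ Σ (√p_{κ+1} − √p_κ)², the discrete Fisher information on
  probability amplitudes, scaled so the maximal-gradient distribution has
  F = 1. H is a global functional, F a local (gradient) one; chaotic and
  stochastic systems occupy distinct regions of the plane and the noise
  families trace an ordered frontier in H.

## Worked example

```python
import numpy as np
from hvgchaos import HVGAnalysis

rng = np.random.default_rng(42)
results = HVGAnalysis(rng.uniform(size=100_000), region=(2, 15),
                      norm="whitenoise_reference").fit()
print(results.summary())
```

```
HVG analysis results
====================================================
series                      series
observations                100000
graph edges                 199981
mean degree                 3.9996
----------------------------------------------------
lambda (tail rate)          0.4034
95% CI                      [0.3981, 0.4086]
R squared                   0.9995
scaling region              kappa in [2, 15]
ln(3/2) threshold           0.4055
classification              uncorrelated
----------------------------------------------------
Shannon entropy H           1.0000  (whitenoise_reference)
Fisher information F        0.1833
statistical complexity      0.3193
quantile skewness           0.3333
quantile kurtosis           1.3333
====================================================
```

Uniform white noise lands exactly where theory says: mean degree ≈ 4,
λ̂ = 0.4034 with ln(3/2) inside its confidence interval (classification
"uncorrelated"), entropy 1.0 under the white-noise normalization, and the
degree-law quantile skewness/kurtosis equal to the geometric closed forms
1/3 and 4/3. Running the same analysis on the Holmes cubic map
(`HVGAnalysis.from_system("holmes", region=(2, 12))`) gives λ̂ = 0.4166
with R² = 0.977 — a well-fitting exponential tail on the *wrong* side of
the ln(3/2) threshold, the documented failure mode of the λ rule that the
plane quantifiers are designed to survive.

The same pipeline is scriptable from the shell:

```sh
hvg generate --system logistic --length 100000 --seed 7 --out series.txt
hvg lambda --in series.txt --kmin 2 --kmax 12
hvg plane --in series.txt --norm whitenoise_reference
hvg suite --out plane.csv --plot plane.png --seed 1   # full corpus
```

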