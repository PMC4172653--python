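# Methods

## The horizontal visibility graph and its degree law

For a series x₁, …, x_N the HVG links nodes i < j iff xₙ < min(xᵢ, xⱼ) for
every i < n < j. Consecutive observations are always linked, so every node
has degree κ ≥ 1, interior nodes κ ≥ 2, and for a ties-free series the
graph is outerplanar with at most 2N − 3 edges. The criterion depends only
on order relations, hence invariance under positive affine maps of the
values; time reversal maps the graph onto itself under index reversal.

**Tie rule.** The strict inequality is applied literally: an intermediate
at exactly the height of the lower endpoint blocks visibility, while
adjacent equal values stay connected (no intermediate exists). A constant
series therefore yields the path graph. Real data contain ties, so the
rule is part of the contract, not an implementation detail.

**Algorithm.** A single monotone-stack sweep builds the graph in O(N)
amortized time: the stack holds indices with strictly decreasing values; a
new point links to every popped smaller value, then to the first value at
least as tall, and an equally tall entry is popped because it can never
see past the new point. An independent O(N²) brute-force builder is kept
permanently in the test surface and compared edge-for-edge against the
sweep, both on random series and exhaustively on all ordinal patterns up
to length 8.

**Degree distribution.** P(κ) = counts/N on a contiguous integer support.
The support is anchored at κ = 1 regardless of whether the bin is occupied.
Rationale: only the two boundary nodes can attain degree 1, so under an
"observed minimum" convention the presence of the κ = 1 bin is a coin flip
on the endpoints of each realization; the Fisher information, which sums
squared amplitude gradients along the support, would then jump by an order
of magnitude between otherwise identical series. Anchoring makes the local
quantifier stable and convergent in N while changing nothing of
substance — entropy is unaffected (0·ln 0 = 0) and the anchored bin holds
at most 2/N mass. Zero-count bins interior to the support are likewise
retained: their gradient terms are real, and discarding them would also
hide the known failure of the Jensen–Shannon–based complexity on HVG
degree laws.

## The λ rule

λ is estimated by ordinary least squares of ln P(κ) on κ over an explicit
scaling region, restricted to bins with at least `min_count` nodes
(default 10); λ̂ = −slope, with a symmetric 95 % interval from the
normal-theory slope standard error (±1.96 SE) and R² reported. The fit is
deliberately unweighted — fidelity to the plain least-squares recipe over
statistical optimality; a Poisson-weighted variant would change the
numbers and is out of scope. Defaults: region κ ∈ [2, 12] for map-like
series, κ ∈ [2, 20] for stochastic ones, both overridable everywhere and
recorded inside the returned fit, because region choice is the rule's main
fragility: for f^−2 noise, moving from κ ∈ [2, 8] to κ ∈ [2, 15] changes
λ̂ by roughly 90 % (the acceptance script recomputes this).

Classification against the iid value ln(3/2): `chaotic` when the whole
interval lies below, `correlated_stochastic` when above, `uncorrelated`
when it straddles, and `inconclusive` when R² < 0.95 — a poor log-linear
fit voids the rule regardless of the point estimate. The Holmes cubic map
is the packaged counterexample: an excellent fit (R² ≈ 0.98) with
λ̂ ≈ 0.417 > ln(3/2).

## Quantile shape statistics

Sample quantiles are type 1 (left-continuous inverse ECDF), the natural
choice for discrete degree data and the convention matching the empirical
CDF definition. Bowley skewness uses p = 1/4; Moors kurtosis uses the
octile grid (1/8, 2/8, 3/8, 5/8, 6/8, 7/8) with the interquartile range as
denominator. Closed forms for the two reference laws are evaluated from
their quantile functions at run time: the standard exponential
(SK ≈ 0.2619, KR ≈ 1.3063, scale-free) and the geometric iid HVG law
(SK = 1/3, KR = 4/3).

Limitation: on strongly intermittent maps (Schuster with z ≥ 1.5, Cusp)
the degree law is so peaked that the interquartile range collapses onto a
single integer and the kurtosis functional is undefined; this is raised as
an explicit error rather than patched, since it is the same
heavy-tail/peakedness pathology that defeats the λ scaling zone.

## Information quantifiers

S = −Σ p ln p (natural log throughout; normalizations cancel the base).
Two entropy normalizations are provided: `uniform` divides by ln(number of
support states) — the number of possible HVG degrees is otherwise
unbounded, so the observed contiguous support defines the state count —
and `whitenoise_reference` divides by a pinned reference entropy
S_ref = 1.9093163138255758, the mean HVG entropy of 100 seeded Gaussian
white-noise series (fGn, Hurst 1/2) of length 10⁵ (seeds 20140923+i,
regenerable via `compute_whitenoise_reference`). The reference mode keeps
white noise at H ≈ 1 at every length, whereas ln(n_states) grows slowly
with the observed degree range; the infinite-sample analytic value for the
geometric law is ln 3 + 2 ln(3/2) ≈ 1.9095.

Discrete Fisher information: F = F₀ Σᵢ (√p_{i+1} − √p_i)² over the ordered
support, with F₀ = 1 when the distribution is a delta at either support
boundary and F₀ = 1/2 otherwise, so the maximal-gradient (delta)
distribution maps to F = 1 and the uniform law to F = 0.

Statistical complexity C = H·Q_J (Q_J the Jensen–Shannon divergence to the
uniform law on the same support, normalized to 1 for a delta) is shipped
as a diagnostic only: HVG degree laws carry many near-zero components, the
divergence saturates, and C discriminates poorly — which is demonstrable
with the packaged systems.

## Synthetic systems

All generators are pure functions of a `SystemSpec` (name, parameters,
kept length, transient discard, seed): identical specs give bit-identical
series. Defaults: kept length 10⁵, transient discard 10³.

- **Maps.** The 27-map registry (noninvertible, dissipative, conservative
  families) ships book-standard parameters and initial conditions in
  `data/sprott_maps.json`. Two numerical amendments: the tent map slope is
  1.99999 rather than 2 because exact binary doubling collapses to 0 in
  IEEE doubles after ~53 iterations; the Gauss continued-fraction map
  1/x mod 1 re-injects from frac(e) whenever the orbit lands within 1e−14
  of 0 (every float is rational, so exact-reciprocal collapse is otherwise
  inevitable). Divergent orbits raise an error naming the iteration.
- **Schuster map** x → x + x^z mod 1, z ≥ 1, seeded random start in (0,1):
  laminar creep near 0 punctuated by chaotic bursts; larger z widens the
  laminar phases.
- **Flows.** Lorenz (σ = 10, r = 28, b = 8/3) and Rössler
  (a = b = 0.2, c = 5.7) are integrated with fixed-step RK4 (dt = 0.01 and
  0.05), order-4 convergence being verified by a Richardson-style test;
  adaptive stepping buys nothing here because only the sequence of strict
  local minima of the X coordinate (the "minimum map") feeds the analysis.
  Plateaus and endpoints never count as minima.
- **f^−k noises.** Seeded uniform white noise is Fourier filtered by
  f^(−k/2) (DC removed), inverted, and standardized to zero mean and unit
  variance — free operations for an affine-invariant graph. The
  log-periodogram slope recovers −k to within a few hundredths.
- **fBm/fGn.** Davies–Harte circulant embedding gives exact-covariance
  fractional Gaussian noise; fBm is its cumulative sum started at 0. The
  increment covariance ((|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})/2) and the
  t^{2H} variance scaling are both verified against the closed forms.
- **Contamination.** y = x + A·η with η seeded zero-mean uniform noise,
  the observational-noise model used for the contaminated logistic map.

What the generators do *not* emulate: measurement quantization, missing
samples, non-stationary parameter drift, and dynamical (feedback) noise.
Passing tests therefore certify the quantifiers on clean model classes,
not on arbitrary field data.

## Problem sizes and stability

The working length for all quantifier studies is N = 10⁵ with the defaults
above; the (H, F) point of a deterministic map then varies by well under
1 % between N = 5·10⁴ and 10⁵. For stochastic systems different lengths
are independent realizations, so length-stability comparisons use ensemble
means (10 realizations per length) — a single draw would confound
convergence with realization noise. The test suite uses shorter series
(2·10³–5·10⁴) wherever the property under test permits.

A genuine limitation surfaced by the benchmark: for strongly correlated
noises (f^−k with k ≳ 2.5, fBm with Hurst ≳ 0.9) the head of the degree
law does not self-average at N = 10⁵ — the series is dominated by a few
low-frequency components — so single-realization Fisher values scatter by
a factor ~2 across seeds. Consequently the noise frontier is cleanly
ordered in H (entropy strictly decreasing with correlation strength,
Spearman ρ = −1 across the k grid), but the F ordering at the strongly
correlated end, and any claim that one particular noise attains the
minimum F, is realization-dependent; similarly the most correlated noises
reach entropies below those of wide-band chaotic maps, so entropy alone
does not separate the two classes — the plane location (H together with
F), not either axis, is the discriminator. The corresponding acceptance
test asserts the strict orderings and is expected to flag exactly these
two clauses.
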