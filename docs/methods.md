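# Methods

## Model and inference procedure

We assume the observed variables obey coupled ODEs whose right-hand sides
decompose into intrinsic dynamics plus interaction functions of increasing
order on an unknown hypergraph.  The inference never tries to identify the
coupling functions or edge weights — only the *binary* structure: for each
target variable i, which source sets S jointly influence ẋᵢ.

The key identity is that a nonzero mixed Taylor derivative
∂ⱼ∂ₖFᵢ(x₀) (j,k ≠ i) can only come from an interaction of order ≥ 3
involving j and k jointly: a pairwise function h(xᵢ,xⱼ) has no mixed
derivative in (j,k).  Conversely, if a "triadic" function decomposes into a
sum of pairwise functions, its mixed derivatives vanish and no method can
distinguish it from a closed triangle of links — this indistinguishability
is a property of the problem, not of the algorithm, and the test suite
asserts it as a negative control (a decomposable coupling must yield no
triadic inference).

Estimation is per-target sparse regression ẋᵢ = D(X)vᵢ over a monomial
library of deviations from a base point, solved by sequential thresholded
least squares (STLSQ).  Hyperedges are read off the support: a monomial's
**distinct-variable set** minus the target defines the candidate's source
set, and the interaction order is |S|+1.  We deliberately use the
distinct-variable set rather than the monomial degree: odd couplings such as
`sin(θⱼ+θₖ−2θᵢ)` have a vanishing second-order cross derivative at the
symmetric base point θ = 0, but their cubic expansion terms (θⱼθₖ²,
θᵢθⱼθₖ, …) still witness the triad {j,k} → i.  For this reason the Kuramoto
presets pair `max_order = 3` with `library_degree = 3`.

A candidate scored by several monomials takes the **maximum** coefficient
magnitude (a `sum` reduction is available); multi-degree-of-freedom nodes
(Lorenz: x, y, z per node) are handled by running the regression at the
variable level and taking the largest coefficient between any degrees of
freedom of the nodes involved, dropping within-node candidates.

The existence threshold ε is applied *a posteriori* to the saved scores, so
a single regression yields the whole ROC curve.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `max_order` | 3 | highest interaction order sought (sources ≤ max_order−1 nodes) |
| `library_degree` | max_order−1 | monomial degree cap; set to `max_order` for odd couplings around a symmetric base point (see above) |
| `lam` (λ) | preset-specific | STLSQ threshold, applied to unit-ℓ2-norm-column coefficients; 0 disables pruning (pure ε-sweep regime). The filtered Kuramoto preset uses 1e-3, chosen in the measured three-decade gap between true-candidate scores (≥ 2e-3) and numerical-noise scores (≤ ~2e-4) |
| `epsilon` (ε) | 0 | existence threshold; normally swept |
| `base_point_rule` | `auto` | the series' own sampling center when known, else the data mean; `zero`/`data_mean`/`data_median`/`user` available.  For polynomial fields any base point is exact in theory; centering on the data improves conditioning |
| `l_keep` | off | Pearson pair budget for large systems |
| `score_scale` | `normalized` | score = \|v\|·‖column‖ (effective contribution, comparable across monomial degrees inside a small sampling box); `original` scores raw coefficients, preferable when the data are O(1)-scaled or the field is polynomial with O(1) coefficients (the Lorenz preset uses it) |
| `box_side` (δ) | 0.1 (Kuramoto) / 0.7 (Lorenz init) | sampling hypercube side; must balance exploring nonlinearity against Taylor accuracy |

Units: phases in radians, Lorenz variables dimensionless, time in the
system's own time unit; sampling rates in Hz only in the sensor-array
pipeline.

## Synthetic data

`random_hypergraph(n, p2, p3, seed)` includes each pair/triple independently
(Bernoulli); `random_simplicial_complex` additionally closes every triple
downward.  The Kuramoto benchmark samples i.i.d. states from a side-0.1
hypercube at the origin and evaluates derivatives exactly from the field;
natural frequencies are Uniform(−1, 1) (the distribution is a free choice;
it only shifts the intercept column).  The Lorenz benchmark integrates 10
trajectories of 150 steps at dt = 0.01 from a side-0.7 box around a random
base point in [−1,1]^{3n}, with forward-difference derivatives.

Each unordered hyperedge contributes once to each member's equation;
`ordered_pairs=True` restores the sum-over-ordered-source-pairs convention
(an overall factor of two on triadic terms — irrelevant for binary
inference, exposed because the convention is genuinely ambiguous).

The trajectory integrator is adaptive RK45 evaluated on the fixed dt grid: a
fixed-step scheme at dt = 0.01 is outside its stability region once the
cubic coupling's −x³ damping meets attractor-scale states (|x| ≈ 10–50) and
trajectories blow up.  A fixed-step RK4 remains available (`method='rk4'`)
and is cross-checked against the adaptive reference on nonstiff cases in the
tests.

The band-limited multichannel generator (`synth_multichannel`) sums
random-phase sinusoids in [0.05, 0.8]×bandwidth (the margin keeps the band
clear of the low-pass roll-off) and can plant directed couplings by adding
the running integral of a source-product to a target channel, so the
target's derivative carries a known monomial.  What it does **not** emulate:
1/f spectra, nonstationarity, artifacts, volume conduction, or measurement
noise — passing controls on it validates the computational chain, not
real-recording performance.

## Correlation pre-filtering

For large systems the library is restricted to monomials whose every
internal variable pair (target included) is among the ℓ_keep pairs of
largest |Pearson correlation|.  The filter correlates the **derivative**
signals when available, falling back to the states: a shared hyperedge term
appears in every member's equation, so coupled nodes have correlated
derivatives even when the states are sampled i.i.d. (where state
correlations carry no signal at all).  The conservative all-pairs-kept rule
guarantees candidate sets shrink monotonically with ℓ_keep.  Filtered ROC
curves truncate at the ε→0⁺ point (excluded candidates can never be
inferred); a straight random-completion segment to (1,1) is available as an
option.  At 100 nodes the pair budget is scaled from 10,000 kept pairs at
300 nodes by the ratio of pair counts (→ 1,104).

## Numerical choices

* **STLSQ**: columns are normalized to unit ℓ2 norm before fitting; λ
  thresholds the normalized-scale coefficients (ties at exactly λ are kept);
  minimum-norm least squares for rank-deficient designs; iteration stops
  when the support stabilizes, hard cap 20; an empty support returns
  residual RMS(y), not an error.  Final coefficients equal the OLS solution
  restricted to the final support (asserted in tests).
* **ROC**: thresholds sweep ∞ plus the distinct positive scores with
  "score ≥ ε" semantics; unfiltered curves close with a final (1,1)
  tie-block point so the trapezoidal area equals the standard
  ties-at-half-credit AUC (validated against scikit-learn on random
  instances).  `endpoint()` always reports the ε→0⁺ operating point (all
  positively-scored candidates inferred).
* **Contribution ratios**: deviations from the inference base point on the
  fitting samples; unordered source sets counted once; time points with a
  zero denominator are excluded from medians and logged.
* **Forward differences** follow ẋ(tₖ) = (x(tₖ₊₁) − x(tₖ))/Δt within each
  series; the final sample of each series is dropped, and differences never
  span series boundaries.
* **Sensor pipeline order**: group → zero-phase Butterworth low-pass
  (order 4 default; only the passband/stopband contract is normative) →
  unit sample standard deviation → forward differences → Euclidean
  near-median selection (ties by time order), which sets the base point to
  the channel-wise median.  Differencing precedes selection so retained rows
  carry valid derivatives.

## Known limitations

* **Masking**: higher-order interactions contribute to lower-order Taylor
  coefficients, so a p-edge can induce lower-order false positives among its
  subsets.  On downward-closed structures (simplicial complexes) those
  candidates are true anyway, which is why the saturated seven-node
  benchmark uses one; on general hypergraphs masking caps precision.  This
  is documented, not asserted away.
* **Finite differences on fast chaotic dynamics**: the coupled-Lorenz
  benchmark at dt = 0.01 has a forward-difference error of 7–9% rms once
  trajectories reach the attractor, and that error is itself almost exactly
  representable in the degree-3 monomial span (regressing the pure
  derivative error onto the library leaves ≈ 0 residual while assigning
  large coefficients to false candidates).  On this trajectory-collinear
  design (condition number ≈ 3e14) coefficient ranking collapses below 1e-4
  relative derivative noise — with exact derivatives the same pipeline and
  data reach a median best-TPR of 0.8–1.0 at FPR < 0.2, with
  finite-difference derivatives it plateaus near 0.2 regardless of solver
  regularization (truncated SVD, λ sweeps, weighted rows, sample selection,
  alternative base points were all measured).  The benchmark is shipped
  as specified, with this gap stated rather than papered over; derivative
  quality, not the sparse regression, is its binding constraint.
* **Sampling-box balance**: data must explore beyond the linearizable
  region while staying inside the Taylor radius; the near-median selection
  stage is the practical tool for tuning this on real recordings.
* **Combinatorics**: the library grows as n^degree; beyond ~100 nodes at
  order 3 the correlation filter is required, and inference quality then
  depends on the filter keeping the true pairs.
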