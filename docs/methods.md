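# Methods

## Model and criterion

The package treats a two-class set of epoched trials `X ∈ R^{M×N}` and
designs `F` parameter sets `{w_i, h_i, b_i}` — spatial weights (length M),
FIR taps (length P), and a binary window over the `K = N − P + 1` filtered
samples. The score of a parameter set on one trial is the windowed variance
`α_X(w,h,b)` of the extracted scalar signal `x̃_n = wᵀA_n h`, where `A_n` is
the lagged data matrix; the design criterion is the ratio of the class-c
mean of `α` to the sum of both class means, plus a window-length reward
`(ε/K)‖b‖`. This generalizes CSP: for `P = 1` and an all-ones window the
criterion is exactly the CSP generalized Rayleigh quotient, and the bound
`0 ≤ Ĵ ≤ 1` with `Ĵ(c=1) + Ĵ(c=2) = 1` carries over.

Two formal choices deserve comment because the defining equations can be
read in more than one way:

* **Averaging denominator.** For a binary window, a true sample mean over
  the active region divides by the active-sample *count* `n_b = ‖b‖₀`,
  while a literal Euclidean norm reads `‖b‖₂ = √n_b`. All averaging
  denominators (in `α`, in the covariance constructions `R_d`/`Q_d`, and in
  the window score `g_d`) use the count by default; the Euclidean reading is
  available via `norm="euclidean"`. The regularizer always uses the literal
  Euclidean norm `√n_b` — it is a length reward, not an average. The choice
  of denominator rescales `α` identically for both classes, so the ratio
  term `Ĵ`, all argmaxes, and all eigenvectors are unaffected; only the
  absolute `α` values and the interaction between the ratio and the
  `ε`-reward change.
* **Centering.** `α` centers the lagged matrices by their *windowed* mean
  (the mean over active samples), making `α` invariant to constant offsets
  on the active region. A debug mode (`centering="global"`) centers by the
  mean over all K filtered samples instead; it exists for comparison only
  and is not used anywhere in the pipeline.

## Optimization

The F sets are designed sequentially. Filter `i` must be orthogonal to the
deflation subspace spanned by the previous filters `h_1..h_{i−1}` *and*
their one-sample circular shifts (a delayed copy of a previous filter has
the same magnitude response, so excluding the shift forces genuinely new
spectral content rather than a phase-shifted duplicate). The shift is
implemented as a one-tap delay (`np.roll(h, 1)`); a `shift_mode="last"`
variant deflates only the most recent filter's shift.

Within one filter the three blocks are cycled (default order w → h → b),
each solved *exactly* with the others fixed:

* **w-step**: `R_c w = λ(R₁+R₂)w`, where `R_d` is the class-mean windowed
  covariance of the band-filtered channels. The top eigenvalue equals `Ĵ`
  at the optimum.
* **h-step**: maximize `hᵀQ_c h / hᵀ(Q₁+Q₂)h` subject to `Vᵀh = 0`. The
  oblique-projection pencil `(GQ_c, Q₁+Q₂)` that expresses this constraint
  is not symmetric, so the implementation instead projects onto an
  orthonormal basis of the complement of `span(V)` (dimension `P − D_i`),
  solves the reduced symmetric-definite problem with `scipy.linalg.eigh`,
  and maps back. The two formulations share stationarity conditions; the
  reduced form is numerically stable and keeps the eigenvalues real.
* **b-step**: score every candidate window in one vectorized pass (per-class
  mean windowed variance of `x̃`) and take the argmax of
  `g_c/(g₁+g₂) + (ε/K)√n_b`; ties break to the first candidate in the
  deterministic enumeration order.

Because each step is an exact maximizer, the per-sweep objective trace is
non-decreasing; the test suite asserts this across seeds and the acceptance
script counts violations (zero). Iteration stops when the objective changes
by `< 1e-5` (tolerance exposed in the config) or after 100 sweeps, in which
case a warning is emitted and the last (monotone-best) iterate is kept.

Initialization: `h` is a seeded standard-normal draw orthogonalized against
the deflation subspace and normalized; `b` starts all-ones (the all-ones
vector need not be in the candidate set — the first recorded trace entry
comes after the first full sweep, when `b` is already a candidate, so
monotonicity of the recorded trace is preserved). Sign conventions (largest-
magnitude entry of `w` and `h` positive) remove the eigenvector sign
ambiguity and make serialized models comparable across runs.

Numerical safeguards: all GEVD inputs are symmetrized; if the right-hand
matrix has condition number above `1e10` a ridge `1e-10·(trace/dim)` is
added; rank-deficient deflation-subspace column sets are pruned by pivoted
QR with a warning (rank tolerance `1e-10`).

After all filters converge, the full w-step eigensystem at each final
`(h_i, b_i)` is recomputed and the top-r and bottom-r unit eigenvectors form
the per-filter spatial bank — its top eigenvector coincides with the
converged `w_i` up to sign, and the bottom eigenvectors capture the
class-2-dominant directions needed for symmetric features.

## Features and classification

A trial maps to the `2rF` vector `α_X(ŵ_i^{(m)}, h_i, b_i)` (filter-major,
top-r before bottom-r), natural-log transformed by default; a zero variance
is floored at `1e-12` with a warning before the log. Classification is
Fisher LDA: projector `S_w^{-1}(μ₁−μ₂)` from the pooled within-class
scatter (ridge `1e-8·trace/dim` if ill-conditioned), threshold at the
midpoint of the projected class means, and a projection exactly on the
threshold deterministically assigned to class 1 (the class the projector is
oriented toward). The cross-validation harness (stratified K-fold × repeats,
scikit-learn splitters) refits both the joint design and the LDA inside
every training fold; held-out trials are only transformed and scored.

## Synthetic data

The simulator draws trials `x[n] = Σ_i s_i[n]·a_i^{(d)} + η` with
`η_m ~ N(0, 0.1)` (variance 0.1 — the distribution is parameterized as
`N(mean, variance)`) and sources
`s_i[n] = t_i[n]·Re[Σ_k S_i[k] e^{jθ} e^{j2πkn/N}]`, θ uniform on [0, 2π),
drawn fresh per trial and per source (a shared-θ mode exists). Only bins
below Nyquist are populated; the real-part operator means a
conjugate-symmetric population would double amplitudes.

Because a *single* θ multiplies all bins, a wide spectral bump produces a
coherent wave packet (a transient pulse whose envelope is the inverse
transform of the bump), not a sustained rhythm. The default configurations
therefore use narrow Gaussian bumps (0.3 Hz against a 1 Hz bin spacing), so
each source is effectively a sustained sinusoid at its center bin — the
regime the windowed-variance model targets.

The default four-source configuration (10 channels, 100 samples at 100 Hz,
100 trials per class) places sources at 8, 14, 20 and 28 Hz with distinct
activity periods (source 1 silent for the first 25 samples, source 3 for the
last 25) and gives each source *different* Gaussian channel profiles for the
two classes (profile centers 5 channels apart, width 1 channel), so each
frequency band carries class information tied to its own spatial direction.
Quantities published only as figures in the source literature are replaced
by these explicit parametric stand-ins; nothing is read off a figure. A
smaller two-source configuration (6 channels, 80 samples, sources at 11.25
and 22.5 Hz) supports fast repeated cross-validation.

What the simulator does *not* emulate: volume-conduction forward models,
1/f background spectra, artifacts, non-stationary band power within the
active period, or trial-to-trial latency jitter. Passing the recovery and
decoding tests therefore shows the optimizer finds planted
spatio-spectro-temporal structure under white noise; it does not certify
performance on real EEG.

## Problem sizes and defaults

* `F = 4`, `r = 1`, `P = 41`, `tol = 1e-5`, `ε = 0.1` (0.05 in the
  four-source recovery experiment), `c = 1`, 100-sweep cap.
* Window schemes: block-combination (ten 6-sample blocks on K = 60 →
  1023 candidates) and contiguous onset/length grids (step 5, minimum
  length strictly above 50 for K = 60; smaller grids for the toy problems).
* The ascent check uses 50 random problems (M = 4, N = 60, P = 8, 10 trials
  per class); the exhaustive-search comparison uses instances small enough
  to bound globally (M ≤ 3, P ≤ 3, ≤ 7 candidates, 10 restarts); recovery
  uses 20 simulator seeds; decoding uses 5×5 CV on 60 trials. These sizes
  keep the full validation suite under a minute while leaving each check
  statistically meaningful.

## Known limitations

* The b-step is exhaustive in the candidate count L (vectorized, O(T·K·L)
  per sweep); combinatorial schemes beyond ~2^20 candidates would need a
  smarter search.
* Alternating ascent finds local optima; multi-start (`seed` in the config)
  is the provided remedy, and the exhaustive comparison on tiny instances
  bounds the gap there to 1e-3.
* Two classes only; multiclass extensions (one-vs-rest or joint) are out of
  scope, as are continuous (non-epoched) recordings and artifact handling.
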