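# cstfp

Joint design of **spatial weights, FIR bandpass filters, and binary time
windows** for two-class decoding of epoched multichannel neural signals
(EEG-style motor-imagery paradigms), with the feature-extraction and
classification pipeline around it and a synthetic-signal simulator for
validation.

## The problem

In cue-based brain–machine interfacing, the discriminative signal — e.g. a
mu-rhythm power change during imagined movement — lives in an unknown
spatial topography, an unknown frequency band, *and* an unknown time
interval after the cue (reaction times differ across users). Common spatial
patterns (CSP) learns only the spatial part and leaves the band and window
to be fixed by hand. This package learns all three jointly from labeled
trials.

## The method

A trial is `X ∈ R^{M×N}` (channels × samples) with label `d ∈ {1,2}`. One
parameter set `P_i = {w_i, h_i, b_i}` combines an order-`P` FIR filter `h`,
spatial weights `w`, and a binary window `b` over the `K = N − P + 1`
filtered samples. With the lagged matrices `[A_n]_{m,p} = X[m, n+P−p]`, the
extracted scalar signal is the bilinear form `x̃_n = wᵀA_n h`, and the
feature is its windowed variance

```
α_X(w,h,b) = (1/n_b) Σ_n b_n |wᵀÂ_n h|²,   Â_n = A_n − (1/n_b) Σ_m b_m A_m,
```

with `n_b` the number of active window samples. `F` parameter sets are
designed sequentially to maximize

```
J(P_i) = E_{X∈C_c}[α_X] / Σ_d E_{X∈C_d}[α_X]  +  (ε/K)·‖b_i‖ ,
```

subject to mutual orthonormality of the filters (each new filter is
constrained to the orthogonal complement of the previous filters and their
one-sample circular shifts, forcing spectral diversity). Each `P_i` is found
by block-coordinate ascent with three exact subproblem solvers:

* **w-step** — generalized eigenproblem `R_c w = λ(R₁+R₂)w` on windowed,
  band-filtered spatial covariances;
* **h-step** — constrained generalized eigenproblem on windowed lag
  covariances `Q_d`, solved in the complement of the deflation subspace;
* **b-step** — exhaustive scoring of a finite window-candidate set (all 0/1
  combinations of disjoint blocks, or contiguous onset/length grids).

Every step maximizes the objective exactly, so the objective trace is
non-decreasing; iteration stops when it changes by less than `1e-5`.
Features for classification are `α_X(ŵ_i^{(m)}, h_i, b_i)` for the top-r and
bottom-r spatial eigenvectors of each filter's final eigensystem (a `2rF`
vector, log-transformed), classified by Fisher LDA with the threshold at the
midpoint of the projected class means.

With the window fixed to all-ones the method reduces to a discriminative
filter-bank CSP (joint spatio-spectral design); with `P = 1` it reduces to
classic CSP.

## Worked example

```python
import numpy as np, cstfp

cfg = cstfp.default_paper_like_config(seed=1)   # 4 hidden sources, 200 trials
trials = cstfp.generate_trials(cfg)

model = cstfp.fit(trials, cstfp.CstfpConfig(
    F=4, r=1, P=41, eps=0.05,
    window_scheme="block_combination", window_params={"D": 6, "J": 10},
    seed=1))

for i, (p, trace) in enumerate(zip(model.parameter_sets, model.objective_trace)):
    active = np.flatnonzero(p.b)
    print(f"filter {i+1}: peak {cstfp.filter_peak_frequency(p.h, cfg.fs):5.2f} Hz, "
          f"window samples {active[0]}-{active[-1]} ({len(active)} active), "
          f"objective {trace[-1]:.4f} after {len(trace)} sweeps")

rm = cstfp.recovery_metrics(model, cfg)
print("matched frequency errors (Hz):", [round(e, 2) for e in rm["matched_freq_error_hz"]])
print("spatial correlations:", [round(r, 3) for r in rm["spatial_correlation"]])
```

Output:

```
filter 1: peak 13.92 Hz, window samples 0-59 (60 active), objective 1.0007 after 4 sweeps
filter 2: peak 20.02 Hz, window samples 0-47 (48 active), objective 0.9997 after 4 sweeps
filter 3: peak  8.03 Hz, window samples 12-59 (48 active), objective 1.0004 after 3 sweeps
filter 4: peak 27.98 Hz, window samples 0-59 (60 active), objective 1.0009 after 3 sweeps
matched frequency errors (Hz): [0.08, 0.02, 0.03, 0.02]
spatial correlations: [0.985, 0.972, 0.991, 0.995]
```

The simulator hides four narrowband sources at 8, 14, 20 and 28 Hz; the four
designed filters recover each center to within 0.1 Hz without being told the
bands. The learned windows track the sources' activity periods: filter 3
(8 Hz) drops the first 12 filtered samples because that source is silent for
the first quarter of every trial, and filter 2 (20 Hz) drops the last 12
because its source is silent at the end. Each objective is the
class-discriminability ratio (≈1 means the class-1/total variance ratio is
saturated) plus the small window-length reward. The spatial correlations
compare each source's true class-1 channel profile with the best matching
designed spatial vector.

A command-line layer wraps the same pipeline:

```bash
cstfp simulate --out data --seed 1
cstfp fit --data data/manifest.csv --out model.json --seed 1
cstfp transform --data data/manifest.csv --model model.json --out features.csv
cstfp evaluate --data data/manifest.csv --out cv.csv --folds 5 --repeats 5 --seed 1
```

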