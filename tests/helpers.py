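"""Independent oracle implementations shared across test modules.

These deliberately re-derive quantities along the definitional route
(explicit per-channel FIR loops, per-trial ratios) rather than through the
package's vectorized matrix forms, so agreement is a genuine cross-check.
"""

import numpy as np

from cstfp import CstfpConfig, Trial, TrialSet


def alpha_direct(X, w, h, b, norm="count", centering="windowed"):
    """Windowed variance via explicit filtering: filter each channel with h,
    combine with w, restrict to the active samples, centered mean square."""
    X = np.asarray(X, dtype=float)
    M, N = X.shape
    P = len(h)
    K = N - P + 1
    filt = np.zeros((M, K))
    for m in range(M):
        for n in range(K):
            filt[m, n] = sum(h[p] * X[m, n + P - 1 - p] for p in range(P))
    comb = np.asarray(w, dtype=float) @ filt
    b = np.asarray(b, dtype=float)
    act = np.flatnonzero(b)
    den = float(len(act)) if norm == "count" else float(np.sqrt(len(act)))
    if centering == "windowed":
        mu = comb[act].sum() / den
    else:
        mu = comb.mean()
    return float(((comb[act] - mu) ** 2).sum()) / den


def alpha_matrix_path(X, w, h, b, norm="count"):
    """Windowed variance via the explicit lagged-matrix bilinear form."""
    from cstfp import build_lag_tensor

    A = build_lag_tensor(np.asarray(X, dtype=float), len(h))  # (K, M, P)
    b = np.asarray(b, dtype=float)
    den = float(np.sum(b != 0)) if norm == "count" else float(np.sqrt(np.sum(b != 0)))
    Abar = np.tensordot(b, A, axes=(0, 0)) / den
    Ahat = A - Abar[None]
    vals = np.einsum("m,kmp,p->k", np.asarray(w, float), Ahat, np.asarray(h, float))
    return float(b @ vals**2) / den


def objective_direct(trials, w, h, b, eps, c, norm="count"):
    """Regularized ratio recomputed per trial through alpha_direct."""
    alphas = np.array([alpha_direct(t.data, w, h, b, norm=norm) for t in trials])
    m1 = alphas[trials.labels == 1].mean()
    m2 = alphas[trials.labels == 2].mean()
    j = (m1 if c == 1 else m2) / (m1 + m2)
    K = len(b)
    return j + (eps / K) * np.sqrt(np.sum(np.asarray(b) != 0))


def random_trialset(rng, M=3, N=20, per_class=4, scale2=1.0):
    """Gaussian trials; scale2 scales class-2 data to create class contrast."""
    trials = []
    for d in (1, 2):
        s = 1.0 if d == 1 else scale2
        for _ in range(per_class):
            trials.append(Trial(s * rng.standard_normal((M, N)), d))
    return TrialSet(trials)


def small_fit_config(seed, **overrides):
    """Quick optimizer settings for toy problems."""
    kw = dict(
        F=1,
        r=1,
        P=8,
        eps=0.1,
        c=1,
        window_scheme="contiguous",
        window_params={"step": 10, "min_len": 10},
        seed=seed,
        max_iter=50,
    )
    kw.update(overrides)
    return CstfpConfig(**kw)
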