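"""Joint spatio-time-frequency pattern design by alternating maximization.

The method designs ``F`` parameter sets ``P_i = {w_i, h_i, b_i}`` (spatial
weights, FIR taps, binary time window) that maximize the regularized
discriminative ratio

    J(P_i) = Jhat(P_i) + (eps / K) * ||b_i||,
    Jhat   = E_{X in C_c}[alpha_X] / sum_d E_{X in C_d}[alpha_X],

subject to mutual orthonormality of the FIR filters (enforced through a
deflation subspace spanned by the previously designed filters and their
one-sample circular shifts, so that later filters capture spectrally
distinct components).  The problem separates into three subproblems, each
solved exactly with the others fixed:

* w-step — generalized eigenproblem ``R_c w = lambda (R_1 + R_2) w`` on the
  windowed, band-filtered spatial covariances;
* h-step — generalized eigenproblem on the windowed, spatially combined lag
  covariances ``Q_d``, restricted to the orthogonal complement of the
  deflation subspace;
* b-step — exhaustive scoring of a finite candidate window set.

Because every step maximizes the objective exactly, the per-filter objective
trace is non-decreasing (block-coordinate ascent); iteration stops when the
objective changes by less than ``tol`` (default 1e-5).

After all F filters converge, the full spatial eigensystem at each final
``(h_i, b_i)`` provides a bank of ``2r`` spatial vectors (top-r and
bottom-r) used for feature extraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sla

from .csp import CspResult, gevd
from .signal_model import (
    CstfpError,
    DegenerateWindowError,
    NormConvention,
    ParameterSet,
    TrialSet,
    ValidationError,
    alpha_variance_set,
    fix_sign,
    window_denominator,
)
from .window_candidates import WindowCandidateSet, make_candidates

__all__ = [
    "CstfpConfig",
    "ObjectiveValue",
    "DeflationSubspace",
    "CstfpModel",
    "objective",
    "update_w",
    "update_h",
    "update_b",
    "build_deflation_subspace",
    "fit",
]

RANK_TOL = 1e-10


class DegenerateSignalError(CstfpError):
    """All windowed variances vanish; the ratio criterion is undefined."""


@dataclass
class CstfpConfig:
    """Hyperparameters of the joint design.

    F: number of (w, h, b) parameter sets (filters) to design.
    r: per-filter bank keeps the top-r and bottom-r spatial eigenvectors.
    P: FIR filter order (number of taps); filtered length K = N - P + 1.
    eps: window-length regularization weight (default 0.1).
    c: class label whose relative windowed power is maximized (default 1).
    window_scheme / window_params: candidate enumeration (see
        window_candidates); default contiguous grid with step 5 and strict
        minimum length 50.
    norm: averaging-denominator convention ("count" or "euclidean").
    tol: stop when the objective changes by less than this (1e-5).
    """

    F: int = 4
    r: int = 1
    P: int = 41
    eps: float = 0.1
    c: int = 1
    window_scheme: str = "contiguous"
    window_params: dict = field(default_factory=dict)
    norm: NormConvention = "count"
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    loop_order: str = "whb"
    shift_mode: str = "all"  # deflate shifts of all previous filters, or "last"

    def validate(self, M: int, N: int) -> None:
        if self.F < 1 or self.r < 1:
            raise ValidationError("F and r must be >= 1")
        if 2 * self.r > M:
            raise ValidationError(f"2r = {2 * self.r} exceeds M = {M}")
        if not 1 <= self.P <= N:
            raise ValidationError(f"P = {self.P} outside 1..N = {N}")
        if self.eps < 0:
            raise ValidationError("eps must be >= 0")
        if self.c not in (1, 2):
            raise ValidationError("c must be 1 or 2")
        if set(self.loop_order) != {"w", "h", "b"}:
            raise ValidationError("loop_order must be a permutation of 'whb'")


@dataclass(frozen=True)
class ObjectiveValue:
    """Ratio term, window-length penalty, and their sum."""

    j_hat: float
    penalty: float

    @property
    def total(self) -> float:
        return self.j_hat + self.penalty


@dataclass(frozen=True)
class DeflationSubspace:
    """Spanning vectors (columns of V) the next FIR filter must avoid."""

    V: np.ndarray  # (P, D_i), possibly zero columns for the first filter

    @property
    def dim(self) -> int:
        return self.V.shape[1]

    def complement_basis(self, P: int) -> np.ndarray:
        """Orthonormal basis of the orthogonal complement of span(V)."""
        if self.dim == 0:
            return np.eye(P)
        U = sla.null_space(self.V.T, rcond=RANK_TOL)
        if U.shape[1] == 0:
            raise ValidationError("deflation subspace fills the whole filter space")
        return U


# ---------------------------------------------------------------------------
# objective and the three exact subproblem solvers
# ---------------------------------------------------------------------------


def _class_means(values: np.ndarray, trials: TrialSet) -> tuple[float, float]:
    return (
        float(values[trials.class_mask(1)].mean()),
        float(values[trials.class_mask(2)].mean()),
    )


def objective(
    trials: TrialSet,
    params: ParameterSet,
    eps: float = 0.1,
    c: int = 1,
    norm: NormConvention = "count",
) -> ObjectiveValue:
    """Regularized discriminative ratio at one parameter set.

    Jhat is the class-c mean windowed variance over the sum of both class
    means; the penalty is ``(eps / K) * ||b||_2`` (for a binary window the
    Euclidean norm is the square root of the active count).
    """
    alphas = alpha_variance_set(trials, params.w, params.h, params.b, norm=norm)
    m1, m2 = _class_means(alphas, trials)
    if m1 + m2 <= 0:
        raise DegenerateSignalError("all windowed variances are zero")
    j_hat = (m1 if c == 1 else m2) / (m1 + m2)
    K = len(params.b)
    penalty = (eps / K) * float(np.sqrt(np.sum(params.b != 0)))
    return ObjectiveValue(j_hat=j_hat, penalty=penalty)


def _lagged_filtered(stack: np.ndarray, h: np.ndarray) -> np.ndarray:
    """FIR-filter every channel of every trial: (T, M, K) from (T, M, N)."""
    Z = sliding_window_view(stack, len(h), axis=2)[..., ::-1]
    return Z @ np.asarray(h, dtype=float)


def _spatial_covs(
    trials: TrialSet, h: np.ndarray, b: np.ndarray, norm: NormConvention
) -> tuple[np.ndarray, np.ndarray]:
    """Class means of the windowed covariance of band-filtered signals (R_d)."""
    b = np.asarray(b, dtype=float)
    den = window_denominator(b, norm)
    Y = _lagged_filtered(trials.stack, h)  # (T, M, K)
    Yc = Y - (Y @ b)[:, :, None] / den
    R = np.einsum("tmk,k,tlk->tml", Yc, b, Yc) / den
    R1 = R[trials.class_mask(1)].mean(axis=0)
    R2 = R[trials.class_mask(2)].mean(axis=0)
    return R1, R2


def _lag_covs(
    trials: TrialSet, w: np.ndarray, b: np.ndarray, P: int, norm: NormConvention
) -> tuple[np.ndarray, np.ndarray]:
    """Class means of the windowed lag covariance of the w-combined signal (Q_d)."""
    b = np.asarray(b, dtype=float)
    den = window_denominator(b, norm)
    U = np.einsum("m,tmn->tn", np.asarray(w, dtype=float), trials.stack)
    Z = sliding_window_view(U, P, axis=1)[:, :, ::-1]  # (T, K, P)
    Zc = Z - ((b @ Z) / den)[:, None, :]
    Q = np.einsum("tkp,k,tkq->tpq", Zc, b, Zc) / den
    Q1 = Q[trials.class_mask(1)].mean(axis=0)
    Q2 = Q[trials.class_mask(2)].mean(axis=0)
    return Q1, Q2


def update_w(
    trials: TrialSet,
    h: np.ndarray,
    b: np.ndarray,
    c: int = 1,
    norm: NormConvention = "count",
) -> tuple[np.ndarray, float, CspResult]:
    """Exact w-step: top generalized eigenvector of (R_c, R_1 + R_2).

    Returns the maximizing unit spatial vector, its eigenvalue (which equals
    Jhat at the optimum), and the full sorted eigensystem consumed by the
    feature bank.
    """
    R1, R2 = _spatial_covs(trials, h, b, norm)
    Rc = R1 if c == 1 else R2
    vals, vecs = gevd(Rc, R1 + R2)
    return vecs[:, 0], float(vals[0]), CspResult(eigenvectors=vecs, eigenvalues=vals)


def build_deflation_subspace(
    previous_h: list[np.ndarray],
    extra: np.ndarray | None = None,
    shift_mode: str = "all",
) -> DeflationSubspace:
    """Span of previous filters plus their one-sample circular shifts.

    The circular shift delays each filter by one tap (a delta at tap 1 maps
    to tap 2), excluding trivially time-shifted copies of already-designed
    filters from the next search space.  ``shift_mode="last"`` deflates only
    the most recent filter's shift.  Rank-deficient column sets are pruned
    (QR with pivoting) with a warning.
    """
    P = None
    cols = []
    for hj in previous_h:
        hj = np.asarray(hj, dtype=float)
        P = len(hj)
        cols.append(hj)
    if shift_mode == "all":
        cols += [np.roll(h, 1) for h in previous_h]
    elif shift_mode == "last":
        if previous_h:
            cols.append(np.roll(previous_h[-1], 1))
    else:
        raise ValidationError(f"unknown shift_mode: {shift_mode!r}")
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != (P or extra.shape[0]):
            extra = extra.T
        cols += [extra[:, j] for j in range(extra.shape[1])]
    if not cols:
        return DeflationSubspace(V=np.zeros((0, 0)))
    V = np.column_stack(cols)
    if V.shape[1] >= V.shape[0]:
        raise ValidationError("deflation subspace dimension must stay below P")
    rank = np.linalg.matrix_rank(V, tol=RANK_TOL * max(1.0, sla.norm(V, 2)))
    if rank < V.shape[1]:
        warnings.warn("deflation vectors linearly dependent; pruning columns")
        _, _, piv = sla.qr(V, pivoting=True)
        V = V[:, np.sort(piv[:rank])]
    return DeflationSubspace(V=V)


def update_h(
    trials: TrialSet,
    w: np.ndarray,
    b: np.ndarray,
    V: DeflationSubspace | None = None,
    c: int = 1,
    norm: NormConvention = "count",
    P: int | None = None,
) -> tuple[np.ndarray, float]:
    """Exact h-step: constrained GEVD on the lag covariances.

    Maximizes ``h^T Q_c h / h^T (Q_1 + Q_2) h`` subject to ``V^T h = 0`` by
    projecting onto an orthonormal basis of the complement of span(V),
    solving the reduced symmetric-definite eigenproblem there and mapping
    back.  Returns a unit-length, sign-fixed filter and its eigenvalue.
    """
    w = np.asarray(w, dtype=float)
    if P is None:
        P = V.V.shape[0] if (V is not None and V.dim > 0) else None
        if P is None:
            raise ValidationError("pass P explicitly when the subspace is empty")
    Q1, Q2 = _lag_covs(trials, w, b, P, norm)
    U = (V or DeflationSubspace(np.zeros((P, 0)))).complement_basis(P)
    vals, vecs = gevd(U.T @ (Q1 if c == 1 else Q2) @ U, U.T @ (Q1 + Q2) @ U)
    h = U @ vecs[:, 0]
    h = fix_sign(h / np.linalg.norm(h))
    return h, float(vals[0])


def update_b(
    trials: TrialSet,
    w: np.ndarray,
    h: np.ndarray,
    candidates: WindowCandidateSet,
    eps: float = 0.1,
    c: int = 1,
    norm: NormConvention = "count",
) -> tuple[np.ndarray, float]:
    """Exact b-step: exhaustive scoring of every candidate window.

    For each candidate the per-class mean windowed variance g_d of the
    extracted scalar signal ``x~_n = w^T A_n h`` is computed in a single
    vectorized pass; the score is ``g_1/(g_1+g_2)`` for c = 1 (its
    complement for c = 2) plus the window-length reward.  Ties break to the
    first candidate in the set's deterministic order.
    """
    if len(candidates) < 1:
        raise ValidationError("empty candidate set")
    B = candidates.candidates  # (L, K)
    U = np.einsum("m,tmn->tn", np.asarray(w, dtype=float), trials.stack)
    Z = sliding_window_view(U, len(h), axis=1)[:, :, ::-1]
    xt = Z @ np.asarray(h, dtype=float)  # (T, K)
    if xt.shape[1] != B.shape[1]:
        raise ValidationError(f"candidate length {B.shape[1]} != K = {xt.shape[1]}")
    n_act = B.sum(axis=1)
    den = n_act if norm == "count" else np.sqrt(n_act)
    S1 = xt @ B.T  # (T, L) windowed sums
    S2 = (xt**2) @ B.T
    mu = S1 / den
    g = (S2 - 2.0 * mu * S1 + mu**2 * n_act) / den  # per-trial windowed variance
    g1, g2 = (g[trials.class_mask(d)].mean(axis=0) for d in (1, 2))
    tot = g1 + g2
    if np.any(tot <= 0):
        raise DegenerateSignalError("a candidate yields zero total variance")
    K = B.shape[1]
    j3 = (g1 if c == 1 else g2) / tot + (eps / K) * np.sqrt(n_act)
    best = int(np.argmax(j3))
    return B[best].copy(), float(j3[best])


# ---------------------------------------------------------------------------
# the fitted model and the sequential-over-filters driver
# ---------------------------------------------------------------------------


@dataclass
class CstfpModel:
    """F designed parameter sets plus per-filter spatial feature banks."""

    parameter_sets: list[ParameterSet]
    csp_banks: list[np.ndarray]  # per filter: (M, 2r) unit columns
    csp_eigenvalues: list[np.ndarray]
    config: CstfpConfig
    objective_trace: list[list[float]]

    @property
    def F(self) -> int:
        return len(self.parameter_sets)

    @property
    def n_features(self) -> int:
        return sum(bank.shape[1] for bank in self.csp_banks)

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["window_params"] = {
            k: v for k, v in cfg["window_params"].items() if k != "onsets_lengths"
        }
        return {
            "config": cfg,
            "filters": [
                {
                    "w": p.w.tolist(),
                    "h": p.h.tolist(),
                    "b": p.b.astype(int).tolist(),
                    "csp_bank": bank.tolist(),
                    "csp_eigenvalues": vals.tolist(),
                }
                for p, bank, vals in zip(
                    self.parameter_sets, self.csp_banks, self.csp_eigenvalues
                )
            ],
            "objective_trace": self.objective_trace,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CstfpModel":
        cfg = CstfpConfig(**d["config"])
        psets, banks, vals = [], [], []
        for f in d["filters"]:
            psets.append(ParameterSet(np.array(f["w"]), np.array(f["h"]), np.array(f["b"])))
            banks.append(np.array(f["csp_bank"]))
            vals.append(np.array(f["csp_eigenvalues"]))
        return cls(psets, banks, vals, cfg, [list(t) for t in d["objective_trace"]])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CstfpModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _init_filter(rng: np.ndarray, P: int, V: DeflationSubspace) -> np.ndarray:
    """Random unit filter orthogonalized against the deflation subspace."""
    for _ in range(100):
        h0 = rng.standard_normal(P)
        if V.dim > 0:
            Ub = sla.orth(V.V)
            h0 = h0 - Ub @ (Ub.T @ h0)
        n = np.linalg.norm(h0)
        if n > 1e-12:
            return fix_sign(h0 / n)
    raise CstfpError("failed to draw a nonzero initial filter")  # pragma: no cover


def fit(
    trials: TrialSet,
    config: CstfpConfig | None = None,
    candidates: WindowCandidateSet | None = None,
    subspace_extra: np.ndarray | None = None,
) -> CstfpModel:
    """Design F parameter sets sequentially, alternating w/h/b per filter.

    Each filter starts from a seeded random FIR vector (orthonormalized
    against its deflation subspace) and the all-ones window, then cycles the
    three exact subproblem solvers until the objective changes by less than
    ``config.tol`` or ``config.max_iter`` sweeps elapse.  The recorded
    objective trace (initial value plus one entry per sweep) is
    non-decreasing by construction.
    """
    config = config or CstfpConfig()
    M, N = trials.n_channels, trials.n_samples
    config.validate(M, N)
    K = N - config.P + 1
    if candidates is None:
        candidates = make_candidates(config.window_scheme, K, **config.window_params)
    if candidates.K != K:
        raise ValidationError(f"candidate length {candidates.K} != K = {K}")
    rng = np.random.default_rng(config.seed)

    hs: list[np.ndarray] = []
    psets: list[ParameterSet] = []
    traces: list[list[float]] = []
    steps = {
        "w": lambda st: st.update(
            dict(zip(("w", "lam", "eig"), update_w(trials, st["h"], st["b"], config.c, config.norm)))
        ),
        "h": lambda st: st.update(
            dict(zip(("h", "zeta"), update_h(
                trials, st["w"], st["b"], st["V"], config.c, config.norm, P=config.P
            )))
        ),
        "b": lambda st: st.update(
            dict(zip(("b", "j3"), update_b(
                trials, st["w"], st["h"], candidates, config.eps, config.c, config.norm
            )))
        ),
    }

    for i in range(config.F):
        V = build_deflation_subspace(hs, extra=subspace_extra, shift_mode=config.shift_mode)
        st: dict = {"h": _init_filter(rng, config.P, V), "b": np.ones(K), "V": V}
        # the first step of the sweep supplies w before it is ever read
        order = config.loop_order
        if order[0] != "w":
            st["w"], _, _ = update_w(trials, st["h"], st["b"], config.c, config.norm)
        trace: list[float] = []
        prev = None
        for _ in range(config.max_iter):
            for stepname in order:
                steps[stepname](st)
            cur = objective(
                trials,
                ParameterSet(st["w"], st["h"], st["b"]),
                config.eps,
                config.c,
                config.norm,
            ).total
            trace.append(cur)
            if prev is not None and abs(cur - prev) < config.tol:
                prev = cur
                break
            prev = cur
        else:
            warnings.warn(f"filter {i + 1} did not converge in {config.max_iter} sweeps")
        pset = ParameterSet(st["w"], st["h"], st["b"])
        psets.append(pset)
        hs.append(pset.h)
        traces.append(trace)

    # Final spatial eigensystem per filter -> 2r-vector feature bank.
    banks, bank_vals = [], []
    for pset in psets:
        _, _, eig = update_w(trials, pset.h, pset.b, config.c, config.norm)
        banks.append(eig.bank(config.r))
        bank_vals.append(eig.eigenvalues)

    for i, hi in enumerate(hs):
        for j in range(i):
            if abs(hi @ hs[j]) > 1e-8:
                raise CstfpError(
                    f"filters {i + 1} and {j + 1} violate orthogonality at exit"
                )
    return CstfpModel(psets, banks, bank_vals, config, traces)
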