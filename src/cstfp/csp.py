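"""Common spatial patterns via the generalized eigenvalue problem.

CSP finds spatial weight vectors ``w`` maximizing the ratio of one class's
filtered-signal variance to the total, solved as the generalized
eigenproblem ``Sigma_c w = lambda (Sigma_1 + Sigma_2) w`` on the per-class
mean time-centered covariance matrices.  The same symmetric-definite GEVD
solver is reused by the joint optimizer for its spatial and spectral
subproblems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .signal_model import CstfpError, Trial, TrialSet, ValidationError, bandpass_butter, fix_sign

__all__ = ["CspResult", "class_covariances", "csp_fit", "gevd", "csp_bandpass_preset"]

RIDGE_DELTA = 1e-10
COND_LIMIT = 1e10


class IllConditionedError(CstfpError):
    """Singular covariance sum with ridge disabled."""


@dataclass(frozen=True)
class CspResult:
    """Full sorted eigensystem of the two-class covariance pencil.

    ``eigenvectors[:, m]`` is the unit-length generalized eigenvector for the
    m-th largest eigenvalue; eigenvalues lie in [0, 1] since both matrices
    are PSD and the right-hand side is their sum.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    def bank(self, r: int) -> np.ndarray:
        """Top-r and bottom-r eigenvectors as columns (the 2r feature bank)."""
        M = self.eigenvectors.shape[1]
        if 2 * r > M:
            raise ValidationError(f"2r = {2 * r} exceeds M = {M}")
        idx = list(range(r)) + list(range(M - 1, M - r - 1, -1))
        return self.eigenvectors[:, idx]


def class_covariances(trials: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean of time-centered per-trial scatter ``(1/N) Xc Xc^T``."""
    covs = []
    for d in (1, 2):
        mask = trials.class_mask(d)
        if not np.any(mask):
            raise ValidationError(f"class {d} empty")
        X = trials.stack[mask]
        Xc = X - X.mean(axis=2, keepdims=True)
        covs.append(np.einsum("tmn,tln->ml", Xc, Xc) / (X.shape[2] * X.shape[0]))
    return covs[0], covs[1]


def gevd(A: np.ndarray, B: np.ndarray, ridge: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Sorted symmetric-definite GEVD of the pencil (A, B).

    Inputs are symmetrized; if ``cond(B)`` exceeds 1e10 a ridge
    ``1e-10 * trace(B)/dim`` is added (or an error is raised when ``ridge``
    is off).  Returns eigenvalues descending and unit-length, sign-fixed
    eigenvectors as columns.
    """
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    if np.linalg.cond(B) > COND_LIMIT:
        if not ridge:
            raise IllConditionedError("covariance sum is ill-conditioned")
        B = B + RIDGE_DELTA * (np.trace(B) / B.shape[0] + 1.0) * np.eye(B.shape[0])
    vals, vecs = sla.eigh(A, B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    vecs = np.column_stack([fix_sign(vecs[:, i]) for i in range(vecs.shape[1])])
    return vals, vecs


def csp_fit(trials: TrialSet, c: int = 1, r: int | None = None) -> CspResult:
    """CSP eigensystem for class ``c`` against the total covariance.

    Solves ``Sigma_c w = lambda (Sigma_1 + Sigma_2) w`` and returns all M
    pairs sorted by descending eigenvalue; callers typically keep the top-r
    and bottom-r eigenvectors (:meth:`CspResult.bank`).  ``r`` is validated
    against 2r <= M when given.
    """
    if c not in (1, 2):
        raise ValidationError("class id must be 1 or 2")
    S1, S2 = class_covariances(trials)
    if r is not None and 2 * r > trials.n_channels:
        raise ValidationError(f"2r = {2 * r} exceeds M = {trials.n_channels}")
    Sc = S1 if c == 1 else S2
    vals, vecs = gevd(Sc, S1 + S2)
    return CspResult(eigenvectors=vecs, eigenvalues=vals)


def csp_bandpass_preset(
    trials: TrialSet, fs: float, lo_hz: float = 7.0, hi_hz: float = 30.0, c: int = 1
) -> tuple[CspResult, TrialSet]:
    """Classic CSP baseline: mu/beta (7-30 Hz) bandpass then CSP."""
    filtered = TrialSet([bandpass_butter(t, lo_hz, hi_hz, fs) for t in trials])
    return csp_fit(filtered, c=c), filtered
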