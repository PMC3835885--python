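"""Trial containers, lagged-matrix construction and the windowed variance.

A trial is an ``M x N`` real matrix (channels x samples).  The signal
extraction model combines three linear stages: an order-``P`` FIR filter with
coefficients ``h``, spatial weights ``w`` over the ``M`` channels, and a
binary time window ``b`` over the ``K = N - P + 1`` filtered samples.  The
single scalar every other module scores against is the windowed variance

    alpha_X(w, h, b) = (1/n_b) * sum_n b_n | w^T Ahat_n h |^2,

where ``A_n`` is the ``M x P`` lagged matrix with ``[A_n]_{m,p} =
X[m, n+P-p]`` (1-based), ``Ahat_n`` is ``A_n`` centered by the windowed mean
of the active lagged matrices, and the denominator ``n_b`` follows the
configured norm convention (see :data:`NormConvention`).  The bilinear form
``w^T A_n h`` is exactly the FIR-filtered, spatially combined signal at time
``n``, so ``alpha`` is the band-limited, time-windowed power that carries the
class information in event-related EEG paradigms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

__all__ = [
    "CstfpError",
    "ValidationError",
    "InvalidFilterOrderError",
    "DegenerateWindowError",
    "Trial",
    "TrialSet",
    "ParameterSet",
    "build_lag_tensor",
    "alpha_variance",
    "bandpass_preprocess",
    "window_denominator",
    "fix_sign",
    "write_trialset",
    "read_trialset",
]

#: Denominator convention for windowed averages.  ``"count"`` divides by the
#: number of active window samples (a true sample mean/variance); the printed
#: equations use the Euclidean norm of the binary window, which equals
#: sqrt(count).  All package defaults use ``"count"``; the regularizer of the
#: optimizer always uses the literal Euclidean norm.
NormConvention = Literal["count", "euclidean"]

DEFAULT_NORM: NormConvention = "count"


class CstfpError(ValueError):
    """Base class for all errors raised by this package."""


class ValidationError(CstfpError):
    """Malformed input (non-finite data, bad shapes, bad labels)."""


class InvalidFilterOrderError(CstfpError):
    """FIR order P outside 1..N."""


class DegenerateWindowError(CstfpError):
    """Binary window with fewer than 2 active samples."""


def window_denominator(b: np.ndarray, norm: NormConvention = DEFAULT_NORM) -> float:
    """Averaging denominator for window ``b`` under the given convention."""
    n_active = float(np.sum(b != 0))
    if norm == "count":
        return n_active
    if norm == "euclidean":
        return float(np.sqrt(n_active))
    raise ValidationError(f"unknown norm convention: {norm!r}")


def fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude entry is positive (ties: first)."""
    v = np.asarray(v, dtype=float)
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trial:
    """One epoched multichannel recording with a class label in {1, 2}."""

    data: np.ndarray
    label: int

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValidationError(f"trial data must be 2-D M x N, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValidationError("trial data contains non-finite values")
        if self.label not in (1, 2):
            raise ValidationError(f"label must be 1 or 2, got {self.label}")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class TrialSet:
    """Ordered collection of equal-shape trials from two nonempty classes.

    Internally the trials are also exposed as one stacked ``(T, M, N)`` array
    (:attr:`stack`), which the optimizer uses for vectorized updates.
    """

    def __init__(self, trials: Sequence[Trial]):
        trials = list(trials)
        if not trials:
            raise ValidationError("empty trial set")
        M, N = trials[0].n_channels, trials[0].n_samples
        for t in trials:
            if (t.n_channels, t.n_samples) != (M, N):
                raise ValidationError("all trials must share identical M and N")
        labels = np.array([t.label for t in trials])
        if not (np.any(labels == 1) and np.any(labels == 2)):
            raise ValidationError("both classes must be nonempty")
        self.trials = trials
        self.labels = labels
        self._stack: np.ndarray | None = None

    @classmethod
    def from_arrays(cls, data: np.ndarray, labels: Iterable[int]) -> "TrialSet":
        return cls([Trial(x, int(l)) for x, l in zip(np.asarray(data, dtype=float), labels)])

    @property
    def stack(self) -> np.ndarray:
        if self._stack is None:
            self._stack = np.stack([t.data for t in self.trials])
        return self._stack

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def class_counts(self) -> dict[int, int]:
        return {d: int(np.sum(self.labels == d)) for d in (1, 2)}

    def class_mask(self, d: int) -> np.ndarray:
        return self.labels == d

    def subset(self, indices: Sequence[int]) -> "TrialSet":
        return TrialSet([self.trials[i] for i in indices])

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


@dataclass
class ParameterSet:
    """One (w, h, b) triple: spatial weights, FIR taps, binary window.

    Invariants enforced at construction: ``b`` binary with at least one
    active sample; ``h`` unit Euclidean length; the largest-magnitude entry
    of ``w`` and of ``h`` is positive (sign convention).
    """

    w: np.ndarray
    h: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.w = fix_sign(np.asarray(self.w, dtype=float))
        h = np.asarray(self.h, dtype=float)
        nh = np.linalg.norm(h)
        if nh == 0:
            raise ValidationError("h must be nonzero")
        self.h = fix_sign(h / nh)
        b = np.asarray(self.b)
        if not np.all(np.isin(b, (0, 1))):
            raise ValidationError("b entries must be 0 or 1")
        if b.sum() < 1:
            raise ValidationError("b must have at least one active sample")
        self.b = b.astype(float)


# ---------------------------------------------------------------------------
# lagged matrices and the windowed variance functional
# ---------------------------------------------------------------------------


def build_lag_tensor(trial: Trial | np.ndarray, P: int) -> np.ndarray:
    """Stack of lagged matrices ``A_n`` as a ``(K, M, P)`` array.

    ``[A_n]_{m,p} = X[m, n+P-p]`` with 1-based paper indices; row ``m`` of
    ``A_n`` holds the reversed window ``x_m[n+P-1], ..., x_m[n]`` (0-based),
    so that ``w @ A_n @ h`` is the FIR convolution output at filtered time
    ``n``.
    """
    X = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected an M x N matrix")
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite input")
    N = X.shape[1]
    P = int(P)
    if P < 1 or P > N:
        raise InvalidFilterOrderError(f"filter order P={P} outside 1..N={N}")
    # (M, K, P) forward windows, reversed in the lag axis, then K-major.
    win = sliding_window_view(X, P, axis=1)[:, :, ::-1]
    return np.ascontiguousarray(np.swapaxes(win, 0, 1))


def filtered_series(X: np.ndarray, w: np.ndarray, h: np.ndarray) -> np.ndarray:
    """``x~_n = w^T A_n h`` for all n, via direct convolution (length K)."""
    u = np.asarray(w, dtype=float) @ X
    return np.convolve(u, np.asarray(h, dtype=float), mode="valid")


def alpha_variance(
    trial: Trial | np.ndarray,
    params: ParameterSet | None = None,
    *,
    w: np.ndarray | None = None,
    h: np.ndarray | None = None,
    b: np.ndarray | None = None,
    norm: NormConvention = DEFAULT_NORM,
    centering: Literal["windowed", "global"] = "windowed",
) -> float:
    """Windowed variance ``alpha_X(w, h, b)`` of the extracted signal.

    The canonical form centers the lagged matrices by their windowed mean
    (``centering="windowed"``); ``centering="global"`` is a debug option that
    centers by the mean over all K filtered samples instead.
    """
    X = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if params is not None:
        w, h, b = params.w, params.h, params.b
    if w is None or h is None or b is None:
        raise ValidationError("provide either a ParameterSet or w, h and b")
    b = np.asarray(b, dtype=float)
    n_active = int(np.sum(b != 0))
    if n_active == 0:
        raise ValidationError("all-zero window")
    if n_active < 2:
        raise DegenerateWindowError("window needs at least 2 active samples")
    K = X.shape[1] - len(h) + 1
    if len(b) != K:
        raise ValidationError(f"window length {len(b)} != K = {K}")
    den = window_denominator(b, norm)
    xt = filtered_series(X, w, h)
    if centering == "windowed":
        mean = float(b @ xt) / den
    else:
        mean = float(np.mean(xt))
    return float(b @ (xt - mean) ** 2) / den


def alpha_variance_set(
    trials: TrialSet,
    w: np.ndarray,
    h: np.ndarray,
    b: np.ndarray,
    norm: NormConvention = DEFAULT_NORM,
) -> np.ndarray:
    """Vectorized ``alpha`` for every trial in the set (windowed centering)."""
    b = np.asarray(b, dtype=float)
    den = window_denominator(b, norm)
    if np.sum(b != 0) < 2:
        raise DegenerateWindowError("window needs at least 2 active samples")
    U = np.einsum("m,tmn->tn", np.asarray(w, dtype=float), trials.stack)
    P = len(h)
    Z = sliding_window_view(U, P, axis=1)[:, :, ::-1]  # (T, K, P)
    xt = Z @ np.asarray(h, dtype=float)  # (T, K)
    mean = (xt @ b) / den
    dev = xt - mean[:, None]
    return (dev**2 @ b) / den


def filter_peak_frequency(h: np.ndarray, fs: float, nfft: int = 4096) -> float:
    """Frequency (Hz) at which the FIR magnitude response peaks."""
    mag = np.abs(np.fft.rfft(np.asarray(h, dtype=float), nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return float(freqs[int(np.argmax(mag))])


# ---------------------------------------------------------------------------
# optional preprocessing (low-pass + decimation), as used on raw recordings
# ---------------------------------------------------------------------------


def bandpass_preprocess(
    trial: Trial,
    cutoff_hz: float = 50.0,
    order: int = 4,
    fs: float = 1000.0,
    downsample_to: float = 100.0,
) -> Trial:
    """Butterworth low-pass (zero-phase) then integer decimation.

    Defaults: 50 Hz cutoff, order 4, 1000 Hz -> 100 Hz, matching common
    motor-imagery preprocessing.  The synthetic simulator already emits data
    at the target rate, so this stage is optional.
    """
    if not 0 < cutoff_hz < fs / 2:
        raise ValidationError(f"cutoff {cutoff_hz} must lie in (0, fs/2 = {fs / 2})")
    factor = fs / downsample_to
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValidationError(f"target rate {downsample_to} must divide fs {fs}")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trial.data, axis=1)
    return Trial(filtered[:, :: int(round(factor))], trial.label)


def bandpass_butter(
    trial: Trial, lo_hz: float, hi_hz: float, fs: float, order: int = 5
) -> Trial:
    """Zero-phase Butterworth bandpass, e.g. the 7-30 Hz mu/beta preset."""
    if not 0 < lo_hz < hi_hz < fs / 2:
        raise ValidationError("need 0 < lo < hi < fs/2")
    sos = sps.butter(order, (lo_hz, hi_hz), btype="bandpass", fs=fs, output="sos")
    return Trial(sps.sosfiltfilt(sos, trial.data, axis=1), trial.label)


# ---------------------------------------------------------------------------
# text round-trip: one delimited matrix per trial + a CSV manifest
# ---------------------------------------------------------------------------


def write_trialset(trials: TrialSet, out_dir: str | Path, fmt: str = "%.17g") -> Path:
    """Write trials as per-trial TSV matrices plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(trials):
        name = f"trial_{i:04d}.tsv"
        np.savetxt(out_dir / name, t.data, fmt=fmt, delimiter="\t")
        rows.append({"trial_id": i, "file": name, "label": t.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_trialset(manifest: str | Path) -> TrialSet:
    """Read a trial set written by :func:`write_trialset`."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    missing = {"trial_id", "file", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    trials = []
    for _, row in df.sort_values("trial_id").iterrows():
        data = np.loadtxt(manifest.parent / str(row["file"]), delimiter="\t", ndmin=2)
        trials.append(Trial(data, int(row["label"])))
    return TrialSet(trials)
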