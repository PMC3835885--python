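"""Log-variance feature extraction and LDA classification.

A fitted model maps each trial to a ``2rF``-dimensional vector of windowed
band-power features: for filter i and bank vector m, entry (i, m) is
``alpha_X(w_i^(m), h_i, b_i)``, laid out filter-major with the top-r
eigenvectors before the bottom-r.  The natural log is applied by default
(band power is approximately log-normal across trials).  Classification is
Fisher LDA onto one dimension with the decision threshold at the midpoint of
the two projected class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .optimizer import CstfpConfig, CstfpModel, fit as cstfp_fit
from .signal_model import Trial, TrialSet, ValidationError, alpha_variance_set

__all__ = [
    "FeatureVector",
    "LdaModel",
    "extract_features",
    "extract_features_set",
    "lda_fit",
    "classify",
    "cross_validate",
]

LOG_FLOOR = 1e-12
LDA_RIDGE = 1e-8


@dataclass(frozen=True)
class LdaModel:
    """One-dimensional Fisher projector with a midpoint threshold.

    The projector is oriented so class 1 projects above the threshold;
    a projection exactly on the threshold is assigned to class 1 (the class
    whose projected mean the orientation favors), deterministically.
    """

    projector: np.ndarray
    threshold: float
    class_means_projected: tuple[float, float]


def extract_features_set(
    trials: TrialSet, model: CstfpModel, log: bool = True, log_floor: float = LOG_FLOOR
) -> np.ndarray:
    """Feature matrix (T, 2rF) for a whole trial set."""
    cols = []
    for pset, bank in zip(model.parameter_sets, model.csp_banks):
        for m in range(bank.shape[1]):
            cols.append(
                alpha_variance_set(trials, bank[:, m], pset.h, pset.b, norm=model.config.norm)
            )
    feats = np.column_stack(cols)
    if log:
        if np.any(feats < log_floor):
            warnings.warn("zero-variance feature floored before log")
            feats = np.maximum(feats, log_floor)
        feats = np.log(feats)
    return feats


def extract_features(
    trial: Trial, model: CstfpModel, log: bool = True, log_floor: float = LOG_FLOOR
) -> np.ndarray:
    """Length-2rF feature vector for one trial (filter-major layout)."""
    singleton = TrialSet.__new__(TrialSet)
    singleton.trials = [trial]
    singleton.labels = np.array([trial.label])
    singleton._stack = trial.data[None]
    return extract_features_set(singleton, model, log=log, log_floor=log_floor)[0]


def lda_fit(features: np.ndarray, labels: np.ndarray) -> LdaModel:
    """Fisher discriminant from pooled within-class scatter, midpoint threshold."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    mu = {}
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for d in (1, 2):
        Xd = X[y == d]
        if Xd.shape[0] < 2:
            raise ValidationError(f"need >= 2 samples in class {d}")
        mu[d] = Xd.mean(axis=0)
        Xc = Xd - mu[d]
        Sw += Xc.T @ Xc
    if np.linalg.cond(Sw) > 1e12:
        Sw = Sw + LDA_RIDGE * (np.trace(Sw) / Sw.shape[0] + 1.0) * np.eye(Sw.shape[0])
    p = np.linalg.solve(Sw, mu[1] - mu[2])
    # orient so class 1 projects above class 2
    if p @ (mu[1] - mu[2]) < 0:  # pragma: no cover - solve already orients
        p = -p
    m1, m2 = float(p @ mu[1]), float(p @ mu[2])
    return LdaModel(projector=p, threshold=0.5 * (m1 + m2), class_means_projected=(m1, m2))


def classify(features: np.ndarray, model: LdaModel) -> np.ndarray | int:
    """Assign class 1 or 2 by which side of the threshold a trial projects.

    A single feature vector yields a scalar label, a matrix one label per row.
    """
    arr = np.asarray(features, dtype=float)
    X = np.atleast_2d(arr)
    if X.shape[1] != len(model.projector):
        raise ValidationError("feature dimension does not match the LDA model")
    labels = np.where(X @ model.projector >= model.threshold, 1, 2)
    return int(labels[0]) if arr.ndim == 1 else labels


def cross_validate(
    trials: TrialSet,
    config: CstfpConfig | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    log: bool = True,
) -> pd.DataFrame:
    """Repeated stratified K-fold accuracy of the full pipeline.

    The joint design and the LDA are refit inside every training fold; the
    held-out fold is only ever transformed and scored.  Returns a tidy frame
    with one row per (repeat, fold) and the accuracy in percent.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    config = config or CstfpConfig()
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for k, (tr, te) in enumerate(skf.split(np.zeros(len(trials)), trials.labels)):
            train, test = trials.subset(tr), trials.subset(te)
            model = cstfp_fit(train, config)
            lda = lda_fit(extract_features_set(train, model, log=log), train.labels)
            pred = classify(extract_features_set(test, model, log=log), lda)
            acc = 100.0 * float(np.mean(pred == test.labels))
            rows.append({"repeat": rep, "fold": k, "accuracy": acc})
    return pd.DataFrame(rows)
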