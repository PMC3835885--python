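"""Finite candidate sets of binary time windows.

The temporal subproblem of the joint optimizer is a discrete search over a
candidate set of binary windows of length ``K`` (the filtered-signal
length).  Two enumeration schemes are provided:

* ``block_combination`` — K is split into J disjoint blocks of width D and
  every nonzero 0/1 combination of blocks is a candidate (``2^J - 1`` of
  them for disjoint blocks), allowing non-contiguous windows.
* ``contiguous`` — windows of D leading zeros followed by O ones, with D and
  O on an arithmetic grid (step 5 by default) subject to ``O > min_len`` and
  ``D + O <= K``, i.e. long contiguous observation periods with a variable
  onset.

Candidates with fewer than 2 active samples are rejected at construction
time and the ordering is deterministic so that argmax tie-breaking (first
wins) is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_model import CstfpError, DegenerateWindowError, ValidationError

__all__ = [
    "GeometryError",
    "EmptyCandidateSetError",
    "WindowCandidateSet",
    "block_combination_candidates",
    "contiguous_candidates",
    "make_candidates",
]


class GeometryError(CstfpError):
    """Scheme parameters that do not fit in K samples."""


class EmptyCandidateSetError(CstfpError):
    """No candidate satisfies the scheme's constraints."""


@dataclass(frozen=True)
class WindowCandidateSet:
    """L binary window vectors of length K plus the scheme that built them."""

    candidates: np.ndarray  # (L, K) 0/1 float array
    scheme: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.candidates, dtype=float)
        if c.ndim != 2 or c.shape[0] < 1:
            raise ValidationError("candidate matrix must be (L >= 1, K)")
        if not np.all(np.isin(c, (0.0, 1.0))):
            raise ValidationError("candidates must be binary")
        if np.any(c.sum(axis=1) < 2):
            raise DegenerateWindowError("every candidate needs >= 2 active samples")
        if len(np.unique(c, axis=0)) != c.shape[0]:
            raise ValidationError("duplicate candidates")
        object.__setattr__(self, "candidates", c)

    @property
    def L(self) -> int:
        return self.candidates.shape[0]

    @property
    def K(self) -> int:
        return self.candidates.shape[1]

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.candidates, fmt="%d", delimiter="\t")

    def __len__(self) -> int:
        return self.L


def block_combination_candidates(K: int, D: int, J: int) -> WindowCandidateSet:
    """All nonzero 0/1 combinations of J disjoint blocks of width D.

    Block j (1-based) covers samples ``D(j-1)+1 .. Dj``; combination index
    l = 1..2^J-1 activates block j when bit j-1 of l is set, giving a
    deterministic lexicographic ordering.  Combinations with fewer than two
    active samples (only possible for D = 1) are dropped.
    """
    K, D, J = int(K), int(D), int(J)
    if D < 1 or J < 1:
        raise ValidationError("D and J must be positive")
    if J * D > K:
        raise GeometryError(f"J*D = {J * D} exceeds K = {K}")
    blocks = np.zeros((J, K))
    for j in range(J):
        blocks[j, D * j : D * (j + 1)] = 1.0
    combos = []
    for l in range(1, 2**J):
        bits = np.array([(l >> j) & 1 for j in range(J)], dtype=float)
        cand = bits @ blocks
        if cand.sum() >= 2:
            combos.append(cand)
    if not combos:
        raise EmptyCandidateSetError("no block combination has >= 2 active samples")
    return WindowCandidateSet(np.array(combos), "block_combination", {"K": K, "D": D, "J": J})


def contiguous_candidates(K: int, step: int = 5, min_len: int = 50) -> WindowCandidateSet:
    """Contiguous windows: D leading zeros then O ones, grid-constrained.

    D and O are drawn from the arithmetic grid {0, step, 2*step, ..., K}
    (K is included even when not a multiple of step), subject to the strict
    ``O > min_len`` and ``D + O <= K``.  Ordering is lexicographic in (D, O).
    """
    K, step, min_len = int(K), int(step), int(min_len)
    if step < 1:
        raise ValidationError("step must be >= 1")
    if min_len < 2:
        raise ValidationError("min_len must be >= 2")
    grid = list(range(0, K + 1, step))
    if grid[-1] != K:
        grid.append(K)
    cands = []
    params = []
    for D in grid:
        for O in grid:
            if O > min_len and D + O <= K:
                v = np.zeros(K)
                v[D : D + O] = 1.0
                cands.append(v)
                params.append((D, O))
    if not cands:
        raise EmptyCandidateSetError(
            f"no (D, O) on the step-{step} grid satisfies O > {min_len}, D + O <= {K}"
        )
    return WindowCandidateSet(
        np.array(cands),
        "contiguous",
        {"K": K, "step": step, "min_len": min_len, "onsets_lengths": params},
    )


def make_candidates(scheme: str, K: int, **params) -> WindowCandidateSet:
    """Dispatch by scheme name (used by the optimizer config)."""
    if scheme == "block_combination":
        return block_combination_candidates(K, **params)
    if scheme == "contiguous":
        return contiguous_candidates(K, **params)
    if scheme == "all_ones":
        return WindowCandidateSet(np.ones((1, K)), "all_ones", {"K": K})
    raise ValidationError(f"unknown window scheme: {scheme!r}")
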