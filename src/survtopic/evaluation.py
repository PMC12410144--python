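"""Time-dependent concordance and bootstrap confidence intervals.

Accuracy of a survival model is scored with the time-dependent
concordance index C_td (Antolini et al.): among pairs of subjects that
can be unambiguously ordered — subject i died at Y_i and subject j is
known to have survived past Y_i — the pair counts as concordant when
the model's curve for i is below the curve for j at time Y_i,
i.e. S(Y_i | x_i) < S(Y_i | x_j); exactly tied predictions earn 0.5.

Confidence intervals follow the resampling protocol used throughout
this package's evaluation: resample the test set with replacement
(default 1000 replicates), recompute C_td per replicate, and take the
2.5 / 97.5 nearest-rank percentiles.  Model comparisons use paired
differences on identical resamples.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

from .survival import SurvivalCurve

__all__ = [
    "PredictionSet",
    "BootstrapCI",
    "ctd_index",
    "bootstrap_ci",
    "bootstrap_diff_ci",
]


class UndefinedMetricError(ValueError):
    """Raised when no comparable pair exists."""


@dataclasses.dataclass
class PredictionSet:
    """Per-subject survival curves aligned with observed labels."""

    curves: Sequence[SurvivalCurve]
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.events = np.asarray(self.events).astype(bool)
        n = len(self.curves)
        if self.times.shape != (n,) or self.events.shape != (n,):
            raise ValueError("labels must align with the curves")
        self._matrix: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.curves)

    def curve_matrix(self) -> np.ndarray:
        """S[a, b] = curve of subject a evaluated at observed time Y_b."""
        if self._matrix is None:
            self._matrix = np.stack([np.atleast_1d(c(self.times)) for c in self.curves])
        return self._matrix


def _ctd_from_matrix(S: np.ndarray, Y: np.ndarray, events: np.ndarray) -> float:
    """C_td given the precomputed curve matrix S[a, b] = S_a(Y_b)."""
    n = Y.size
    concordant = 0.0
    comparable = 0
    for i in np.flatnonzero(events):
        mask = (Y > Y[i]) | ((Y == Y[i]) & ~events)
        mask[i] = False
        m = int(mask.sum())
        if m == 0:
            continue
        si = S[i, i]
        sj = S[mask, i]
        concordant += np.sum(si < sj) + 0.5 * np.sum(si == sj)
        comparable += m
    if comparable == 0:
        raise UndefinedMetricError("no comparable pair of subjects")
    return concordant / comparable


def ctd_index(preds: PredictionSet) -> float:
    """Time-dependent concordance index in [0, 1]; 1 is perfect ordering."""
    return _ctd_from_matrix(preds.curve_matrix(), preds.times, preds.events)


def _nearest_rank_percentile(sorted_vals: np.ndarray, p: float) -> float:
    """Nearest-rank empirical percentile (1-based rank ceil(p/100 * m))."""
    m = sorted_vals.size
    rank = max(1, int(np.ceil(p / 100.0 * m)))
    return float(sorted_vals[rank - 1])


class BootstrapCI(NamedTuple):
    lower: float
    upper: float
    n_skipped: int


def _bootstrap_replicates(
    preds: PredictionSet, B: int, seed: int, other: PredictionSet | None = None
) -> tuple[np.ndarray, int]:
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    S = preds.curve_matrix()
    S2 = other.curve_matrix() if other is not None else None
    vals = []
    skipped = 0
    n = preds.n
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = np.ix_(idx, idx)
        try:
            v = _ctd_from_matrix(S[sub], preds.times[idx], preds.events[idx])
            if S2 is not None:
                v -= _ctd_from_matrix(S2[sub], preds.times[idx], preds.events[idx])
        except UndefinedMetricError:
            skipped += 1
            continue
        vals.append(v)
    return np.sort(np.array(vals)), skipped


def bootstrap_ci(preds: PredictionSet, B: int = 1000, seed: int = 0) -> BootstrapCI:
    """95% percentile bootstrap CI for C_td (resampling subjects).

    Replicates without any comparable pair are skipped; the count of
    skipped replicates is reported alongside the interval.
    """
    vals, skipped = _bootstrap_replicates(preds, B, seed)
    if vals.size == 0:
        raise UndefinedMetricError("every bootstrap replicate was degenerate")
    return BootstrapCI(
        _nearest_rank_percentile(vals, 2.5), _nearest_rank_percentile(vals, 97.5), skipped
    )


def bootstrap_diff_ci(
    preds_a: PredictionSet, preds_b: PredictionSet, B: int = 1000, seed: int = 0
) -> BootstrapCI:
    """Paired bootstrap CI for C_td(A) - C_td(B) on identical resamples.

    Both prediction sets must cover the same subjects in the same
    order; a positive interval means model A is more accurate.
    """
    if preds_a.n != preds_b.n or not (
        np.array_equal(preds_a.times, preds_b.times)
        and np.array_equal(preds_a.events, preds_b.events)
    ):
        raise ValueError("prediction sets must be aligned on the same subjects")
    vals, skipped = _bootstrap_replicates(preds_a, B, seed, other=preds_b)
    if vals.size == 0:
        raise UndefinedMetricError("every bootstrap replicate was degenerate")
    return BootstrapCI(
        _nearest_rank_percentile(vals, 2.5), _nearest_rank_percentile(vals, 97.5), skipped
    )
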