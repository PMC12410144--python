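"""Survival heads operating on topic weights.

Two heads are provided, both linear in the topic-weight vector and both
constraining the last (k-th) topic's coefficient to zero so that it
acts as a *background topic* absorbing survival-irrelevant structure:

* Cox proportional hazards, fitted by the negative log partial
  likelihood with Breslow-style risk sets and a Breslow baseline-hazard
  estimate for survival curves.  A larger linear score beta'W means a
  pointwise lower survival curve (shorter survival).
* Log-logistic accelerated failure time (AFT): log T = mu + theta'W +
  sigma * eps with standard-logistic noise, fitted by the censored
  negative log likelihood, optionally regularized by a pairwise
  ranking loss that lower-bounds concordance.  Here a larger theta
  coefficient means *longer* survival — the opposite sign convention
  from Cox.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "CoxHead",
    "AFTHead",
    "BaselineSurvival",
    "SurvivalCurve",
    "linear_score",
    "cox_partial_likelihood_loss",
    "breslow_baseline",
    "cox_survival_curve",
    "aft_nll",
    "ranking_loss",
    "loglogistic_survival",
    "loglogistic_survival_curve",
]

LN2 = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class CoxHead:
    """Cox regression coefficients over topics; the background entry is 0."""

    beta: np.ndarray  # full length-k vector, beta[-1] == 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=np.float64)
        object.__setattr__(self, "beta", beta)
        if beta.ndim != 1 or beta.size < 1:
            raise ValueError("beta must be a vector")
        if beta[-1] != 0.0:
            raise ValueError("the background topic coefficient beta[k-1] must be 0")

    @classmethod
    def from_free(cls, free: np.ndarray) -> "CoxHead":
        """Build from the k-1 trainable coefficients."""
        return cls(np.append(np.asarray(free, dtype=np.float64), 0.0))


@dataclasses.dataclass(frozen=True)
class AFTHead:
    """Log-logistic AFT parameters; the background theta entry is 0."""

    theta: np.ndarray  # full length-k vector, theta[-1] == 0
    mu: float
    log_sigma: float

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=np.float64)
        object.__setattr__(self, "theta", theta)
        if theta.ndim != 1 or theta.size < 1:
            raise ValueError("theta must be a vector")
        if theta[-1] != 0.0:
            raise ValueError("the background topic coefficient theta[k-1] must be 0")

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @classmethod
    def from_free(cls, free: np.ndarray, mu: float, log_sigma: float) -> "AFTHead":
        return cls(np.append(np.asarray(free, dtype=np.float64), 0.0), mu, log_sigma)


class SurvivalCurve:
    """A subject-specific survival function S(t), evaluable on any grid."""

    def __init__(self, fn, label: str = ""):
        self._fn = fn
        self.label = label

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        return self._fn(t)


@dataclasses.dataclass(frozen=True)
class BaselineSurvival:
    """Breslow baseline: step function S0(t) = exp(-sum_{t_i <= t} h_i)."""

    death_times: np.ndarray  # strictly increasing unique event times
    hazards: np.ndarray  # nonnegative hazard increments, one per death time

    def __post_init__(self) -> None:
        dt = np.asarray(self.death_times, dtype=np.float64)
        hz = np.asarray(self.hazards, dtype=np.float64)
        object.__setattr__(self, "death_times", dt)
        object.__setattr__(self, "hazards", hz)
        if dt.size != hz.size:
            raise ValueError("death_times and hazards must align")
        if dt.size > 1 and np.any(np.diff(dt) <= 0):
            raise ValueError("death_times must be strictly increasing")
        if np.any(hz < 0):
            raise ValueError("hazards must be nonnegative")

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        idx = np.searchsorted(self.death_times, t, side="right")
        csum = np.concatenate([[0.0], np.cumsum(self.hazards)])
        return csum[idx]

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cumulative_hazard(t))


# ---------------------------------------------------------------------------
# scores and losses


def linear_score(W: np.ndarray, head: CoxHead | AFTHead) -> np.ndarray | float:
    """Linear predictor on topic weights.

    Cox: beta'W (risk score; higher = shorter survival).
    AFT: theta'W + mu (location of log survival time; higher = longer).
    """
    W = np.asarray(W, dtype=np.float64)
    coef = head.beta if isinstance(head, CoxHead) else head.theta
    if W.shape[-1] != coef.size:
        raise ValueError(f"topic dimension mismatch: W has {W.shape[-1]}, head has {coef.size}")
    out = W @ coef
    if isinstance(head, AFTHead):
        out = out + head.mu
    return float(out) if np.ndim(out) == 0 else out


def _check_labels(scores_len: int, Y: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Y = np.asarray(Y, dtype=np.float64)
    delta = np.asarray(delta)
    if Y.shape != (scores_len,) or delta.shape != (scores_len,):
        raise ValueError("scores, Y and delta must have equal length")
    if not np.isin(delta, [0, 1]).all():
        raise ValueError("delta must contain only 0/1")
    return Y, delta.astype(bool)


def _cox_loss_t(scores: Tensor, Y: np.ndarray, delta: np.ndarray) -> Tensor:
    """Negative mean log partial likelihood, risk set {j : Y_j >= Y_i}."""
    n = scores.shape[0]
    Y, ev = _check_labels(n, Y, delta)
    if not ev.any():
        warnings.warn("no uncensored subjects; Cox loss is 0", RuntimeWarning)
        return scores.sum() * 0.0
    order = np.argsort(-Y, kind="stable")  # descending time
    sorted_scores = scores[order]
    m = float(sorted_scores.value.max())
    log_risk = ad.log(ad.cumsum(ad.exp(sorted_scores - m))) + m
    # risk set of subject i = all j with Y_j >= Y_i = first count_i entries
    Y_asc = np.sort(Y)
    count = n - np.searchsorted(Y_asc, Y, side="left")
    ev_idx = np.flatnonzero(ev)
    contrib = scores[ev_idx] - log_risk[count[ev_idx] - 1]
    return -contrib.sum() / n


def cox_partial_likelihood_loss(scores, Y, delta) -> float:
    """Cox negative log partial likelihood, averaged over all n subjects.

    Ties are handled by the plain risk-set rule (every subject with
    Y_j >= Y_i is at risk at Y_i), i.e. Breslow-style.  The loss is
    invariant to adding a constant to all scores.
    """
    scores = np.asarray(scores, dtype=np.float64)
    return _cox_loss_t(Tensor(scores), Y, delta).item()


def breslow_baseline(scores, Y, delta) -> BaselineSurvival:
    """Breslow estimate of the baseline hazard given fitted risk scores.

    At each unique death time t_i with d_i deaths, the hazard increment
    is d_i / sum_{j : Y_j >= t_i} exp(score_j).
    """
    scores = np.asarray(scores, dtype=np.float64)
    Y, ev = _check_labels(scores.size, Y, delta)
    if not ev.any():
        warnings.warn("no deaths observed; baseline survival is identically 1", RuntimeWarning)
        return BaselineSurvival(np.array([]), np.array([]))
    death_times = np.unique(Y[ev])
    # exp-score mass at risk at each death time, via a suffix sum over ascending Y
    order = np.argsort(Y, kind="stable")
    exp_sorted = np.exp(scores[order] - scores.max())
    suffix = np.cumsum(exp_sorted[::-1])[::-1]
    first_at_risk = np.searchsorted(Y[order], death_times, side="left")
    risk_mass = suffix[first_at_risk] * np.exp(scores.max())
    d_counts = np.array([np.sum((Y == t) & ev) for t in death_times], dtype=np.float64)
    return BaselineSurvival(death_times, d_counts / risk_mass)


def cox_survival_curve(score: float, baseline: BaselineSurvival) -> SurvivalCurve:
    """Subject curve S(t) = S0(t)^exp(score): larger score, lower survival."""
    factor = float(np.exp(score))
    return SurvivalCurve(
        lambda t: np.exp(-factor * baseline.cumulative_hazard(t)),
        label=f"cox(score={score:.4g})",
    )


def _aft_nll_t(locations: Tensor, log_sigma: Tensor, Y: np.ndarray, delta: np.ndarray) -> Tensor:
    """Censored log-logistic NLL.

    With z = (log Y - location) / sigma and standard-logistic noise:
    event terms     -[log f_eps(z) - log sigma] = -(z - 2 softplus(z)) + log sigma
    censored terms  -log(1 - F_eps(z))          = softplus(z)
    """
    n = locations.shape[0]
    Y, ev = _check_labels(n, Y, delta)
    if np.any(Y <= 0):
        raise ValueError("AFT likelihood requires strictly positive observed times")
    sigma = ad.exp(log_sigma)
    z = (np.log(Y) - locations) / sigma
    sp = ad.softplus(z)
    ev_f = ev.astype(np.float64)
    per_subject = ev_f * (-(z - 2.0 * sp) + log_sigma) + (1.0 - ev_f) * sp
    return per_subject.sum() / n


def aft_nll(locations, log_sigma: float, Y, delta) -> float:
    """Mean negative log likelihood of the log-logistic AFT model."""
    locations = np.asarray(locations, dtype=np.float64)
    return _aft_nll_t(Tensor(locations), Tensor(float(log_sigma)), Y, delta).item()


def _ranking_pairs(Y: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Comparable pairs (i, j): death observed for i and Y_j > Y_i."""
    ev_idx = np.flatnonzero(delta)
    ii, jj = [], []
    for i in ev_idx:
        later = np.flatnonzero(Y > Y[i])
        ii.append(np.full(later.size, i))
        jj.append(later)
    if not ii:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(ii), np.concatenate(jj)


def _ranking_loss_t(locations: Tensor, Y: np.ndarray, delta: np.ndarray) -> Tensor:
    n = locations.shape[0]
    Y, ev = _check_labels(n, Y, delta)
    ii, jj = _ranking_pairs(Y, ev)
    if ii.size == 0:
        return locations.sum() * 0.0
    diff = locations[ii] - locations[jj]
    return ad.softplus(diff).mean() / LN2 - 1.0


def ranking_loss(locations, Y, delta) -> float:
    """Pairwise surrogate whose negation lower-bounds concordance.

    Over pairs E = {(i, j) : delta_i = 1, Y_j > Y_i} the loss is
    -1 + mean log2(1 + exp(location_i - location_j)); it is 0 when all
    locations are equal or when E is empty, and decreases as concordant
    gaps (location_j > location_i for longer-lived j) widen.
    """
    locations = np.asarray(locations, dtype=np.float64)
    return _ranking_loss_t(Tensor(locations), Y, delta).item()


# ---------------------------------------------------------------------------
# log-logistic survival function


def loglogistic_survival(location: float, sigma: float, t) -> np.ndarray | float:
    """Closed-form S(t) = 1 / (1 + t^(1/sigma) * exp(-location/sigma)).

    The median survival time is exp(location).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    with np.errstate(divide="ignore"):
        # work on the log scale to avoid overflow for large t or small sigma
        log_odds = np.where(t > 0, (np.log(t) - location) / sigma, -np.inf)
    out = 1.0 / (1.0 + np.exp(np.clip(log_odds, -745, 745)))
    out = np.where(t == 0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def loglogistic_survival_curve(location: float, sigma: float) -> SurvivalCurve:
    return SurvivalCurve(
        lambda t: np.asarray(loglogistic_survival(location, sigma, t)),
        label=f"aft(loc={location:.4g}, sigma={sigma:.4g})",
    )


def export_curve_csv(curve: SurvivalCurve, grid, path) -> None:
    """Write (time, survival) pairs for a user-supplied time grid."""
    import pandas as pd

    grid = np.asarray(grid, dtype=np.float64)
    pd.DataFrame({"time": grid, "survival": np.atleast_1d(curve(grid))}).to_csv(
        path, index=False
    )
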