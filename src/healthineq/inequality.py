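"""Weighted fractional ranks, the concentration index, and the concentration curve.

The concentration index C quantifies socioeconomic inequality in a health
outcome y.  Individuals are ranked from poorest to richest by a continuous
living-standards score; with fractional ranks R_i in (0, 1) and outcome mean
mu, the index is

    C = (2 / mu) * cov_w(y, R)

where cov_w is the *population* weighted covariance (divide by total weight,
not total minus one).  C is negative when the outcome is concentrated among
the poor and positive when concentrated among the rich; |C| <= 1, and for a
binary outcome with mean mu the attainable range shrinks to [mu - 1, 1 - mu].

The concentration curve plots the cumulative outcome share L(p) against the
cumulative population share p, poorest first; C equals one minus twice the
area under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedIndexError

__all__ = [
    "fractional_rank",
    "weighted_mean",
    "weighted_cov",
    "concentration_index",
    "generalized_concentration_index",
    "concentration_curve",
    "RankedSample",
    "ConcentrationResult",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _normalized_weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.full(n, 1.0 / n)
    w = _as_float_array(w, "weights")
    if len(w) != n:
        raise DomainError(f"weights length {len(w)} != data length {n}")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DomainError("weights must be finite and strictly positive")
    return w / w.sum()


def fractional_rank(scores, weights=None) -> np.ndarray:
    """Weighted fractional rank in (0, 1), poorest first.

    Each individual receives the cumulative (normalized) weight of all
    strictly poorer individuals plus half of their own weight.  Tied scores
    share the midpoint rank of the tied group's pooled weight span, so the
    rank depends only on the ordering of scores, never on their spacing.
    With equal weights and distinct scores this reduces to (i - 0.5) / n.

    Parameters
    ----------
    scores : array-like
        Living-standards scores (e.g. a wealth index).  Ties allowed.
    weights : array-like, optional
        Positive sampling weights; equal weights if omitted.

    Returns
    -------
    numpy.ndarray
        Ranks aligned with the input order.
    """
    s = _as_float_array(scores, "scores")
    if np.any(~np.isfinite(s)):
        raise DomainError("scores must be finite")
    w = _normalized_weights(weights, len(s))

    order = np.argsort(s, kind="mergesort")
    sw = w[order]
    cum = np.cumsum(sw)
    # midpoint of each individual's own weight span
    ranks_sorted = cum - sw / 2.0

    # pool tied groups: every member gets the midpoint of the group's span
    ss = s[order]
    boundaries = np.flatnonzero(np.diff(ss) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(ss)]))
    for a, b in zip(starts, stops):
        if b - a > 1:
            lo = cum[a] - sw[a]
            hi = cum[b - 1]
            ranks_sorted[a:b] = (lo + hi) / 2.0

    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    return ranks


def weighted_mean(y, weights=None) -> float:
    y = _as_float_array(y, "y")
    w = _normalized_weights(weights, len(y))
    return float(np.dot(w, y))


def weighted_cov(a, b, weights=None) -> float:
    """Population-weighted covariance: sum w_i (a_i - ā)(b_i - b̄) with Σw = 1."""
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if len(a) != len(b):
        raise DomainError("vectors must have equal length")
    w = _normalized_weights(weights, len(a))
    am = np.dot(w, a)
    bm = np.dot(w, b)
    return float(np.dot(w, (a - am) * (b - bm)))


@dataclass(frozen=True)
class RankedSample:
    """An outcome vector paired with fractional ranks and normalized weights.

    Attributes
    ----------
    y : numpy.ndarray
        Outcome values (binary or real).
    ranks : numpy.ndarray
        Fractional ranks in (0, 1).
    weights : numpy.ndarray
        Normalized weights summing to one.
    """

    y: np.ndarray
    ranks: np.ndarray
    weights: np.ndarray

    @classmethod
    def from_scores(cls, y, scores, weights=None) -> "RankedSample":
        y = _as_float_array(y, "y")
        w = _normalized_weights(weights, len(y))
        r = fractional_rank(scores, w)
        return cls(y=y, ranks=r, weights=w)

    def __post_init__(self):
        y = _as_float_array(self.y, "y")
        r = _as_float_array(self.ranks, "ranks")
        w = _normalized_weights(self.weights, len(y))
        if len(r) != len(y):
            raise DomainError("ranks and y must have equal length")
        if np.any((r <= 0) | (r >= 1)):
            raise DomainError("fractional ranks must lie strictly in (0, 1)")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "ranks", r)
        object.__setattr__(self, "weights", w)

    @property
    def mu(self) -> float:
        return float(np.dot(self.weights, self.y))


@dataclass(frozen=True)
class ConcentrationResult:
    """Concentration index together with curve coordinates."""

    index: float
    curve_points: pd.DataFrame = field(repr=False)
    n_effective: int
    mean_outcome: float

    @property
    def orientation(self) -> str:
        """Neutral description of the sign: where the outcome is concentrated."""
        if self.index < 0:
            return "concentrated among the poor"
        if self.index > 0:
            return "concentrated among the rich"
        return "no socioeconomic concentration"


def generalized_concentration_index(sample: RankedSample) -> float:
    """GC = 2 * cov_w(y, R): the rank covariance term without the 1/mu scale.

    Defined for any outcome, including mean-zero regression residuals, where
    the standard index would be undefined.
    """
    if np.allclose(sample.ranks, sample.ranks[0]):
        raise UndefinedIndexError("ranks are constant; index undefined")
    return 2.0 * weighted_cov(sample.y, sample.ranks, sample.weights)


def concentration_index(sample: RankedSample) -> float:
    """Concentration index C = 2 cov_w(y, R) / mu.

    Raises
    ------
    UndefinedIndexError
        If the outcome mean is zero or the ranks are constant.
    """
    mu = sample.mu
    if mu == 0:
        raise UndefinedIndexError("outcome mean is zero; concentration index undefined")
    return generalized_concentration_index(sample) / mu


def concentration_curve(sample: RankedSample) -> pd.DataFrame:
    """Concentration-curve coordinates (cumulative population vs outcome share).

    Records are sorted poorest to richest (by rank); the returned frame has
    columns ``pop_share`` and ``outcome_share``, starts at (0, 0) and ends at
    (1, 1), and both columns are non-decreasing for non-negative outcomes.
    """
    mu = sample.mu
    if mu == 0:
        raise UndefinedIndexError("outcome mean is zero; curve undefined")
    order = np.argsort(sample.ranks, kind="mergesort")
    w = sample.weights[order]
    y = sample.y[order]
    p = np.concatenate(([0.0], np.cumsum(w)))
    L = np.concatenate(([0.0], np.cumsum(w * y) / mu))
    p[-1] = 1.0
    L[-1] = 1.0
    return pd.DataFrame({"pop_share": p, "outcome_share": L})


def concentration(y, scores, weights=None) -> ConcentrationResult:
    """One-call convenience: rank, index, and curve from raw columns."""
    sample = RankedSample.from_scores(y, scores, weights)
    return ConcentrationResult(
        index=concentration_index(sample),
        curve_points=concentration_curve(sample),
        n_effective=len(sample.y),
        mean_outcome=sample.mu,
    )
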