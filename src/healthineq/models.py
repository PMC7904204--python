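"""Design matrices, logistic association models, and linear probability fits.

Categorical covariates are dummy-coded against an explicit reference
category (the first listed), mirroring the "Ref." rows of conventional
odds-ratio tables.  Two fitting routes are provided:

* ``fit_logistic`` — maximum-likelihood logistic regression reported as
  odds ratios with 95% Wald intervals, for association tables;
* ``fit_lpm`` — weighted ordinary least squares of a (typically binary)
  outcome on the dummies: the linear probability model whose exact residual
  orthogonality underpins the regression-based decomposition of the
  concentration index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, RankDeficiencyError, SeparationError

__all__ = ["FactorSpec", "RegressionFit", "build_design", "fit_logistic", "fit_lpm"]

LABEL_SEP = ":"


@dataclass(frozen=True)
class FactorSpec:
    """A categorical covariate: ordered categories, first one the reference."""

    name: str
    categories: Sequence[str]

    def __post_init__(self):
        cats = list(self.categories)
        if len(cats) < 2:
            raise DomainError(f"factor {self.name!r} needs >= 2 categories")
        if len(set(cats)) != len(cats):
            raise DomainError(f"factor {self.name!r} has duplicate categories")
        object.__setattr__(self, "categories", tuple(cats))

    @property
    def reference(self) -> str:
        return self.categories[0]

    @property
    def dummy_labels(self) -> list[str]:
        return [f"{self.name}{LABEL_SEP}{c}" for c in self.categories[1:]]


def split_label(label: str) -> tuple[str, str]:
    """Inverse of the ``factor:category`` dummy-label convention."""
    factor, _, category = label.partition(LABEL_SEP)
    return factor, category


def build_design(records: pd.DataFrame, factor_specs: Sequence[FactorSpec]) -> pd.DataFrame:
    """Dummy-coded design matrix (no intercept column).

    One indicator column per non-reference category, ordered by spec order;
    columns labeled ``factor:category``.  A category present in the data but
    absent from its spec raises a labeled error.
    """
    cols: dict[str, np.ndarray] = {}
    for spec in factor_specs:
        if spec.name not in records.columns:
            raise DomainError(f"records table has no column {spec.name!r}")
        values = records[spec.name].astype(str)
        unseen = set(values.unique()) - set(map(str, spec.categories))
        if unseen:
            raise DomainError(
                f"factor {spec.name!r} contains categories not in its spec: {sorted(unseen)}"
            )
        for cat in spec.categories[1:]:
            cols[f"{spec.name}{LABEL_SEP}{cat}"] = (values == str(cat)).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=records.index)


@dataclass
class RegressionFit:
    """A fitted regression feeding the decomposition.

    Attributes
    ----------
    alpha : float
        Intercept.
    betas : pandas.Series
        Coefficient per dummy column (for the logistic kind these are the
        average partial effects on the probability scale, so the linear
        decomposition algebra applies approximately).
    residuals : numpy.ndarray
        Per-record residuals on the outcome scale.
    xbar : pandas.Series
        Weighted mean of each dummy column.
    fitted : numpy.ndarray
        Per-record predictions on the outcome scale.
    kind : str
        ``"linear"`` or ``"logistic"``.
    """

    alpha: float
    betas: pd.Series
    residuals: np.ndarray = field(repr=False)
    xbar: pd.Series
    fitted: np.ndarray = field(repr=False)
    kind: str
    mu: float


def _norm_weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise DomainError("weights must be strictly positive")
    return w / w.sum()


def _check_separation(y: np.ndarray, X: pd.DataFrame) -> None:
    for label in X.columns:
        x = X[label].to_numpy()
        if set(np.unique(x)) <= {0.0, 1.0}:
            if np.array_equal(x, y) or np.array_equal(1.0 - x, y):
                raise SeparationError(
                    f"column {label!r} perfectly predicts the outcome (separation)"
                )
            # quasi-separation: an empty cell in the column's 2x2 with y
            # sends the ML coefficient to infinity
            if y.min() != y.max():
                for side in (0.0, 1.0):
                    ys = y[x == side]
                    if len(ys) and ys.min() == ys.max() and len(ys) < len(y):
                        raise SeparationError(
                            f"column {label!r} separates the outcome "
                            f"(y constant at {ys[0]:g} where column == {side:g})"
                        )


def fit_logistic(
    y, X: pd.DataFrame, weights=None, *, max_iter: int = 100
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression as an odds-ratio table.

    Returns a frame with one row per dummy column: ``factor, category, beta,
    se, or_, ci_low, ci_high`` where the interval is the 95% Wald interval
    exp(beta ± 1.96 se).

    Raises
    ------
    SeparationError
        When a dummy column perfectly (or quasi-) separates the outcome.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("logistic outcome must be binary 0/1")
    if (X.nunique() <= 1).any():
        const = list(X.columns[X.nunique() <= 1])
        raise DomainError(f"constant design columns: {const}")
    _check_separation(y, X)
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True)
    if weights is None:
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=max_iter)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise DomainError("weights must be strictly positive")
        res = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w).fit(
            maxiter=max_iter
        )
    if not res.converged:
        grad = np.linalg.norm(res.model.score(res.params))
        raise SeparationError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(gradient norm {grad:.3g})"
        )
    beta = res.params[1:]
    se = res.bse[1:]
    rows = []
    for label, b, s in zip(X.columns, beta, se):
        factor, category = split_label(label)
        rows.append(
            {
                "factor": factor,
                "category": category,
                "beta": b,
                "se": s,
                "or_": np.exp(b),
                "ci_low": np.exp(b - 1.96 * s),
                "ci_high": np.exp(b + 1.96 * s),
            }
        )
    return pd.DataFrame(rows)


def fit_lpm(y, X: pd.DataFrame, weights=None) -> RegressionFit:
    """Weighted OLS linear probability model.

    The fit guarantees (up to numerical precision) that weighted residuals
    sum to zero and are orthogonal to every design column — the property
    that makes the decomposition's adding-up identity exact.

    Raises
    ------
    RankDeficiencyError
        Listing (near-)collinear columns when the design with intercept is
        rank deficient.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = _norm_weights(weights, n)
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True)

    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # pivoted QR on the weighted design points at the offending columns
        from scipy.linalg import qr

        _, R, piv = qr(np.sqrt(w)[:, None] * Xc, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xc.shape) * np.finfo(float).eps
        bad = sorted(piv[np.flatnonzero(diag < tol)])
        labels = ["(intercept)"] + list(X.columns)
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: "
            f"{[labels[i] for i in bad]}"
        )

    res = sm.WLS(y, Xc, weights=w).fit()
    fitted = res.fittedvalues
    resid = y - fitted
    xbar = pd.Series(
        {label: float(np.dot(w, X[label].to_numpy(dtype=float))) for label in X.columns}
    )
    return RegressionFit(
        alpha=float(res.params[0]),
        betas=pd.Series(res.params[1:], index=list(X.columns)),
        residuals=resid,
        xbar=xbar,
        fitted=fitted,
        kind="linear",
        mu=float(np.dot(w, y)),
    )


def logistic_average_partial_effects(
    y, X: pd.DataFrame, weights=None
) -> RegressionFit:
    """Logistic fit summarized as average partial effects on the probability scale.

    An alternative decomposition engine: betas are weighted means of
    p_i (1 - p_i) beta_k.  Residuals y - p do not satisfy exact orthogonality
    to X, so a decomposition built on this fit carries the approximation
    error in its residual term.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = _norm_weights(weights, n)
    _check_separation(y, X)
    Xc = sm.add_constant(X.to_numpy(dtype=float), prepend=True)
    res = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w * n).fit()
    p = res.fittedvalues
    scale = float(np.dot(w, p * (1.0 - p)))
    betas = pd.Series(res.params[1:] * scale, index=list(X.columns))
    xbar = pd.Series(
        {label: float(np.dot(w, X[label].to_numpy(dtype=float))) for label in X.columns}
    )
    mu = float(np.dot(w, y))
    alpha = mu - float(np.dot(betas.to_numpy(), xbar.to_numpy()))
    return RegressionFit(
        alpha=alpha,
        betas=betas,
        residuals=y - p,
        xbar=xbar,
        fitted=p,
        kind="logistic",
        mu=mu,
    )
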