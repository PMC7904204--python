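"""Regression-based (Wagstaff) decomposition of the concentration index.

Given a linear model y_i = alpha + sum_k beta_k x_ki + eps_i, the
concentration index of y decomposes exactly as

    C = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_eps / mu

where eta_k = beta_k xbar_k / mu is the elasticity of y with respect to
covariate k, C_k is the concentration index of x_k over the same wealth
ranks, and GC_eps = 2 cov_w(eps, R) is the generalized concentration index
of the residual.  With an OLS fit the residual is orthogonal to every
column, so the identity

    calculated CI  +  residual  =  actual CI

holds to machine precision; the "calculated" (explained) part is the sum of
the per-covariate absolute contributions eta_k * C_k, and each covariate's
percentage contribution is reported relative to the calculated CI — the
convention under which per-factor totals sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .inequality import (
    RankedSample,
    concentration_index,
    fractional_rank,
    generalized_concentration_index,
    weighted_cov,
)
from .models import (
    FactorSpec,
    RegressionFit,
    build_design,
    fit_lpm,
    logistic_average_partial_effects,
    split_label,
)

__all__ = [
    "elasticity",
    "covariate_ci",
    "wagstaff_decompose",
    "format_decomposition_table",
    "DecompositionRow",
    "DecompositionResult",
    "round_half_away",
]

IDENTITY_TOL = 1e-10


def elasticity(beta_k: float, xbar_k: float, mu: float) -> float:
    """Elasticity eta_k = beta_k * xbar_k / mu of the outcome w.r.t. covariate k."""
    if mu == 0:
        raise DomainError("outcome mean is zero; elasticity undefined")
    return beta_k * xbar_k / mu


def covariate_ci(x_k, ranks, weights=None) -> float:
    """Concentration index of a covariate over the given wealth ranks.

    Same estimator as the outcome index: 2 cov_w(x_k, R) / xbar_k.  For a
    top-quintile dummy under equal weights this tends to 0.8 as n grows
    (and to -0.8 for a bottom-quintile dummy).
    """
    sample = RankedSample(y=np.asarray(x_k, dtype=float), ranks=ranks, weights=weights)
    return concentration_index(sample)


@dataclass(frozen=True)
class DecompositionRow:
    """One covariate's contribution to the explained concentration index."""

    factor: str
    category: str
    elasticity: float
    covariate_ci: float  # NaN when the category is empty (xbar = 0)
    absolute_contribution: float
    pct_contribution: float


@dataclass
class DecompositionResult:
    """Full decomposition output.

    ``calculated_ci + residual == actual_ci`` to numerical precision when the
    OLS engine is used; ``residual_from_error`` recomputes the residual
    directly as GC_eps / mu and must agree.
    """

    rows: list[DecompositionRow]
    group_totals: pd.Series
    calculated_ci: float
    actual_ci: float
    residual: float
    residual_from_error: float
    mu: float
    engine: str
    n: int
    fit: RegressionFit = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor": r.factor,
                    "category": r.category,
                    "elasticity": r.elasticity,
                    "ci_k": r.covariate_ci,
                    "absolute": r.absolute_contribution,
                    "pct": r.pct_contribution,
                }
                for r in self.rows
            ]
        )


def wagstaff_decompose(
    y,
    records: pd.DataFrame,
    factor_specs: Sequence[FactorSpec],
    scores,
    weights=None,
    *,
    engine: str = "ols",
) -> DecompositionResult:
    """Decompose the concentration index of ``y`` into covariate contributions.

    Parameters
    ----------
    y : array-like
        Outcome (binary for the linear probability model).
    records : pandas.DataFrame
        Table holding the categorical covariates named in ``factor_specs``.
    factor_specs : sequence of FactorSpec
        Dummy coding plan; first category of each factor is the reference.
    scores : array-like
        Continuous living-standards scores used for ranking.
    weights : array-like, optional
        Positive sampling weights.
    engine : {"ols", "logit_ape"}
        Regression engine.  ``"ols"`` (default) gives the exact adding-up
        identity; ``"logit_ape"`` uses logistic average partial effects and
        pushes the linearization error into the residual.
    """
    X = build_design(records, factor_specs)
    return _decompose_design(y, X, scores, weights, engine=engine)


def decompose_design(y, X: pd.DataFrame, scores, weights=None, *, engine: str = "ols"):
    """Decomposition from an already-built dummy design matrix."""
    return _decompose_design(y, X, scores, weights, engine=engine)


def _decompose_design(y, X, scores, weights, *, engine):
    y = np.asarray(y, dtype=float)
    ranks = fractional_rank(scores, weights)
    # empty categories (all-zero dummies) would make the design singular;
    # they are excluded from the fit and reported with a zero coefficient
    empty_cols = [c for c in X.columns if not X[c].to_numpy().any()]
    X_fit = X.drop(columns=empty_cols)
    if engine == "ols":
        fit = fit_lpm(y, X_fit, weights)
    elif engine == "logit_ape":
        fit = logistic_average_partial_effects(y, X_fit, weights)
    else:
        raise DomainError(f"unknown engine {engine!r}; use 'ols' or 'logit_ape'")
    if empty_cols:
        zeros = pd.Series(0.0, index=empty_cols)
        nonempty = [s for s in (fit.betas, zeros) if len(s)]
        fit.betas = pd.concat(nonempty) if len(nonempty) > 1 else nonempty[0]
        nonempty = [s for s in (fit.xbar, zeros) if len(s)]
        fit.xbar = pd.concat(nonempty) if len(nonempty) > 1 else nonempty[0]
    mu = fit.mu
    if mu == 0:
        raise DomainError("outcome mean is zero; concentration index undefined")

    w = weights
    rows: list[DecompositionRow] = []
    contributions: list[float] = []
    for label in X.columns:
        x = X[label].to_numpy(dtype=float)
        beta = float(fit.betas[label])
        xbar = float(fit.xbar[label])
        if xbar == 0.0:
            # empty category: C_k undefined, but the contribution
            # 2 beta cov(x, R) / mu is still well defined (and zero here)
            contrib = 2.0 * beta * weighted_cov(x, ranks, w) / mu
            ck = float("nan")
            eta = 0.0
        else:
            eta = elasticity(beta, xbar, mu)
            ck = covariate_ci(x, ranks, w)
            contrib = eta * ck
        factor, category = split_label(label)
        rows.append(
            DecompositionRow(
                factor=factor,
                category=category,
                elasticity=eta,
                covariate_ci=ck,
                absolute_contribution=contrib,
                pct_contribution=float("nan"),  # filled below
            )
        )
        contributions.append(contrib)

    calculated = float(np.sum(contributions))
    actual = concentration_index(RankedSample(y=y, ranks=ranks, weights=w))
    resid_gc = generalized_concentration_index(
        RankedSample(y=fit.residuals, ranks=ranks, weights=w)
    )
    residual_from_error = resid_gc / mu
    residual = actual - calculated

    pct = [
        (c / calculated * 100.0) if calculated != 0 else float("nan")
        for c in contributions
    ]
    rows = [
        DecompositionRow(
            factor=r.factor,
            category=r.category,
            elasticity=r.elasticity,
            covariate_ci=r.covariate_ci,
            absolute_contribution=r.absolute_contribution,
            pct_contribution=p,
        )
        for r, p in zip(rows, pct)
    ]
    frame = pd.DataFrame({"factor": [r.factor for r in rows], "pct": pct})
    group_totals = frame.groupby("factor", sort=False)["pct"].sum()

    return DecompositionResult(
        rows=rows,
        group_totals=group_totals,
        calculated_ci=calculated,
        actual_ci=actual,
        residual=residual,
        residual_from_error=residual_from_error,
        mu=mu,
        engine=engine,
        n=len(y),
        fit=fit,
    )


def round_half_away(x, decimals: int):
    """Round half away from zero (so -0.0235 -> -0.024 at 3 d.p.)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def format_decomposition_table(
    result: DecompositionResult,
    factor_specs: Sequence[FactorSpec] | None = None,
    *,
    value_decimals: int = 3,
    pct_decimals: int = 1,
) -> pd.DataFrame:
    """Publication-style table: one row per category, references blank.

    Elasticity, covariate CI and absolute contribution are rounded to
    ``value_decimals`` (default 3) and percentages to ``pct_decimals``
    (default 1), half away from zero.  Reference-category rows are emitted
    with blank cells; summary rows for the calculated CI, actual CI and
    residual are appended.
    """
    by_key = {(r.factor, r.category): r for r in result.rows}
    records = []

    def _fmt(v, d):
        return "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{round_half_away(v, d):.{d}f}"

    if factor_specs is None:
        # reconstruct factor/category order from the rows themselves
        layout: list[tuple[str, list[str | None]]] = []
        for r in result.rows:
            if not layout or layout[-1][0] != r.factor:
                layout.append((r.factor, [None]))  # None marks the reference slot
            layout[-1][1].append(r.category)
        specs_iter = [(f, cats) for f, cats in layout]
    else:
        specs_iter = [(s.name, list(s.categories)) for s in factor_specs]

    for factor, cats in specs_iter:
        for i, cat in enumerate(cats):
            is_ref = i == 0
            if is_ref:
                records.append(
                    {"factor": factor, "category": cat if cat is not None else "(ref)",
                     "elasticity": "", "ci_k": "", "absolute": "", "pct": "", "group_total": ""}
                )
                continue
            r = by_key[(factor, cat)]
            is_last = i == len(cats) - 1
            group_total = result.group_totals[factor] if is_last else None
            records.append(
                {
                    "factor": factor,
                    "category": cat,
                    "elasticity": _fmt(r.elasticity, value_decimals),
                    "ci_k": _fmt(r.covariate_ci, value_decimals),
                    "absolute": _fmt(r.absolute_contribution, value_decimals),
                    "pct": _fmt(r.pct_contribution, pct_decimals),
                    "group_total": _fmt(group_total, pct_decimals) if group_total is not None else "",
                }
            )
    for label, value, pct in (
        ("Calculated CI", result.calculated_ci, 100.0),
        ("Actual CI", result.actual_ci, None),
        ("Residual", result.residual, None),
    ):
        records.append(
            {
                "factor": label,
                "category": "",
                "elasticity": "",
                "ci_k": "",
                "absolute": _fmt(value, value_decimals),
                "pct": _fmt(pct, pct_decimals) if pct is not None else "",
                "group_total": "",
            }
        )
    return pd.DataFrame(records)
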