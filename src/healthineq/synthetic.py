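"""Synthetic survey-like populations with controllable socioeconomic gradients.

Real adolescent-nutrition microdata of the kind this package analyses are
typically restricted-access, so every downstream stage (ranking, the
concentration index, the regression-based decomposition, the report tables)
is exercised on generated populations whose ground truth is known.

Two generators are provided:

* :func:`generate_population` — a latent-z model: each adolescent receives a
  continuous wealth score, covariates whose category probabilities depend on
  the wealth rank through logistic/softmax links, and latent BMI-for-age and
  height-for-age z-scores that are linear in the wealth rank (the
  ``gradient_strength``) and the covariate dummies plus Gaussian noise.
  Outcome flags are then classified from the z-scores with the standard
  cut-offs, and the latent intercept is calibrated so the achieved
  prevalences match the configured targets.

* :func:`generate_lpm_population` — an exactly linear probability model
  E[y|x] = alpha + sum_k beta_k x_k, for parameter-recovery tests where the
  decomposition's ground-truth contributions must be known analytically.

Default configuration mirrors a two-state adolescent survey: 20,594 records
(5,969 boys, 14,625 girls), thinness targets 25.8% / 13.1% and stunting
targets 25.6% / 39.3% (boys / girls), covariates whose marginals follow the
survey's descriptive profile, and a wealth gradient of 0.65 latent SD per
unit rank chosen to match the survey's poorest-to-richest mean z-score gap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .inequality import fractional_rank

__all__ = [
    "SimulationConfig",
    "CovariateSpec",
    "generate_population",
    "generate_lpm_population",
    "lpm_ground_truth",
    "make_lms_fixture",
    "DEFAULT_COVARIATES",
    "STUDY_N",
]

logger = logging.getLogger(__name__)

#: study-scale sample sizes by sex
STUDY_N = {"boy": 5969, "girl": 14625}

THINNESS_CUTOFF = -2.0  # strict: z < -2
STUNTING_CUTOFF = -2.0  # inclusive: z <= -2


@dataclass(frozen=True)
class CovariateSpec:
    """One categorical covariate and its dependence on the wealth rank.

    Category probabilities follow a softmax over ``base_logits + rank_slopes
    * (r - 0.5)``, where r is the individual's wealth fractional rank, so a
    positive slope concentrates that category among the rich.
    """

    name: str
    categories: tuple[str, ...]
    base_logits: tuple[float, ...]
    rank_slopes: tuple[float, ...]

    def __post_init__(self):
        k = len(self.categories)
        if k < 2:
            raise ConfigurationError(f"covariate {self.name!r} needs >= 2 categories")
        if len(self.base_logits) != k or len(self.rank_slopes) != k:
            raise ConfigurationError(
                f"covariate {self.name!r}: logits/slopes must match categories"
            )

    def probabilities(self, rank: np.ndarray) -> np.ndarray:
        logits = np.asarray(self.base_logits) + np.outer(
            rank - 0.5, np.asarray(self.rank_slopes)
        )
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# Marginals follow the descriptive profile of a two-state adolescent survey;
# slopes encode plausible wealth dependence (education and media exposure
# rise with wealth, working status and rural residence fall).
DEFAULT_COVARIATES: dict[str, tuple[CovariateSpec, ...]] = {
    "boy": (
        CovariateSpec("age_group", ("early", "late"), (0.0, _logit(0.651)), (0.0, 0.2)),
        CovariateSpec(
            "education",
            ("no_schooling", "1-7", "8-9", "10+"),
            (np.log(0.032), np.log(0.418), np.log(0.294), np.log(0.256)),
            (-1.5, -0.6, 0.3, 1.2),
        ),
        CovariateSpec("working", ("no", "yes"), (0.0, _logit(0.267)), (0.0, -0.8)),
        CovariateSpec(
            "media",
            ("no_exposure", "rare", "frequent"),
            (np.log(0.056), np.log(0.181), np.log(0.763)),
            (-1.8, -0.9, 0.8),
        ),
        CovariateSpec("caste", ("sc_st", "non_sc_st"), (_logit(0.269), 0.0), (0.0, 1.0)),
        CovariateSpec("religion", ("hindu", "non_hindu"), (_logit(0.842), 0.0), (0.0, -0.2)),
        CovariateSpec("residence", ("urban", "rural"), (_logit(0.173), 0.0), (0.0, -1.6)),
        CovariateSpec("state", ("uttar_pradesh", "bihar"), (_logit(0.682), 0.0), (0.0, -0.3)),
    ),
    "girl": (
        CovariateSpec("age_group", ("early", "late"), (0.0, _logit(0.887)), (0.0, 0.2)),
        CovariateSpec(
            "education",
            ("no_schooling", "1-7", "8-9", "10+"),
            (np.log(0.129), np.log(0.269), np.log(0.280), np.log(0.322)),
            (-1.5, -0.6, 0.3, 1.2),
        ),
        CovariateSpec("working", ("no", "yes"), (0.0, _logit(0.167)), (0.0, -0.8)),
        CovariateSpec(
            "media",
            ("no_exposure", "rare", "frequent"),
            (np.log(0.185), np.log(0.288), np.log(0.527)),
            (-1.8, -0.9, 0.8),
        ),
        CovariateSpec("caste", ("sc_st", "non_sc_st"), (_logit(0.259), 0.0), (0.0, 1.0)),
        CovariateSpec("religion", ("hindu", "non_hindu"), (_logit(0.789), 0.0), (0.0, -0.2)),
        CovariateSpec("residence", ("urban", "rural"), (_logit(0.161), 0.0), (0.0, -1.6)),
        CovariateSpec("state", ("uttar_pradesh", "bihar"), (_logit(0.674), 0.0), (0.0, -0.3)),
    ),
}

#: latent z-score shifts (in SD) per covariate category, shared across sexes;
#: modest effects so the wealth gradient dominates, as in the survey tables
DEFAULT_LATENT_EFFECTS: dict[str, dict[str, float]] = {
    "education": {"no_schooling": -0.10, "1-7": -0.08, "8-9": 0.0, "10+": 0.10},
    "media": {"no_exposure": -0.08, "rare": -0.06, "frequent": 0.0},
    "caste": {"sc_st": -0.10, "non_sc_st": 0.0},
    "residence": {"urban": 0.10, "rural": 0.0},
}

DEFAULT_PREVALENCE = {
    "thinness": {"boy": 0.258, "girl": 0.131},
    "stunting": {"boy": 0.256, "girl": 0.393},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the latent-z population generator.

    Attributes
    ----------
    n : int
        Number of records (default: the study-scale 20,594).
    seed : int
        Seed for all randomness; identical configs give identical tables.
    sex_ratio : float
        Proportion of boys, in [0, 1].
    prevalence_targets : mapping
        ``outcome -> proportion`` or ``outcome -> {sex: proportion}`` for
        ``thinness`` and ``stunting``; ``both`` emerges from the joint latent
        model and is not targeted directly.
    gradient_strength : float
        Latent z-score shift (SD) per unit wealth rank; 0 removes the
        socioeconomic gradient entirely.
    covariate_specs : mapping sex -> sequence of CovariateSpec
    weight_scheme : {"equal", "variable"}
        Variable weights are lognormal(sigma=0.5), mean-normalized.
    tie_fraction : float
        Fraction of records whose wealth score is duplicated from another
        record, to exercise tie handling in the ranking.
    latent_noise_sd : float
        SD of the idiosyncratic component of the latent z-scores.
    latent_correlation : float
        Correlation between the BMI-for-age and height-for-age noise terms
        (drives the prevalence of co-existence).
    """

    n: int = sum(STUDY_N.values())
    seed: int = 0
    sex_ratio: float = STUDY_N["boy"] / sum(STUDY_N.values())
    prevalence_targets: Mapping = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCE.items()}
    )
    gradient_strength: float = 0.65
    covariate_specs: Mapping[str, Sequence[CovariateSpec]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    weight_scheme: str = "equal"
    tie_fraction: float = 0.0
    latent_noise_sd: float = 1.0
    latent_correlation: float = 0.55
    latent_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LATENT_EFFECTS.items()}
    )

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if self.weight_scheme not in ("equal", "variable"):
            raise ConfigurationError("weight_scheme must be 'equal' or 'variable'")
        if not (0.0 <= self.tie_fraction < 1.0):
            raise ConfigurationError("tie_fraction must lie in [0, 1)")
        for outcome, target in self.prevalence_targets.items():
            values = target.values() if isinstance(target, Mapping) else [target]
            for p in values:
                if not (0.0 < p < 1.0):
                    raise ConfigurationError(
                        f"prevalence target for {outcome!r} must lie in (0, 1), got {p}"
                    )


def _target_for(config: SimulationConfig, outcome: str, sex: str) -> float:
    t = config.prevalence_targets[outcome]
    return float(t[sex]) if isinstance(t, Mapping) else float(t)


def _weighted_quantile_shift(latent: np.ndarray, w: np.ndarray, p: float, cutoff: float,
                             inclusive: bool) -> np.ndarray:
    """Shift latent values so the weighted share below/at ``cutoff`` equals p.

    Deterministic calibration: subtracting (q_p - cutoff), where q_p is the
    weighted p-quantile of the latent values, places a weight-p mass at or
    below the cutoff.
    """
    order = np.argsort(latent)
    cw = np.cumsum(w[order]) / w.sum()
    idx = np.searchsorted(cw, p, side="left" if inclusive else "right")
    idx = min(idx, len(latent) - 1)
    q = latent[order][idx]
    return latent - (q - cutoff)


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate a survey-like table of adolescent records.

    Returns a DataFrame with one row per individual: ``id, sex, age_group,
    education, working, media, caste, religion, residence, state,
    wealth_score, wealth_quintile, weight, z_bmi_age, z_height_age,
    thinness, stunting, both``.  Deterministic given the config (including
    its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < config.sex_ratio, "boy", "girl")
    wealth = rng.standard_normal(n)
    if config.tie_fraction > 0:
        n_tie = int(round(config.tie_fraction * n))
        if n_tie and n > 1:
            dup_to = rng.choice(n, size=n_tie, replace=False)
            dup_from = rng.integers(0, n, size=n_tie)
            wealth[dup_to] = wealth[dup_from]

    if config.weight_scheme == "equal":
        weight = np.ones(n)
    else:
        weight = rng.lognormal(mean=0.0, sigma=0.5, size=n)
        weight /= weight.mean()

    rank = fractional_rank(wealth, weight)
    quintile = np.minimum(np.ceil(rank * 5).astype(int), 5)

    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sex,
            "wealth_score": wealth,
            "wealth_quintile": quintile,
            "weight": weight,
        }
    )

    # covariates: softmax on wealth rank, per sex
    cov_names = [spec.name for spec in next(iter(config.covariate_specs.values()))]
    for name in cov_names:
        frame[name] = ""
    for s, specs in config.covariate_specs.items():
        mask = sex == s
        if not mask.any():
            continue
        r = rank[mask]
        for spec in specs:
            probs = spec.probabilities(r)
            u = rng.random(mask.sum())
            choice = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            frame.loc[mask, spec.name] = np.asarray(spec.categories)[choice]

    # latent z-scores: gradient in rank + covariate shifts + correlated noise
    systematic = config.gradient_strength * (rank - 0.5)
    for name, effects in config.latent_effects.items():
        if name in frame.columns:
            systematic = systematic + frame[name].map(dict(effects)).fillna(0.0).to_numpy()
    rho = config.latent_correlation
    shared = rng.standard_normal(n)
    eps_b = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    eps_h = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
    latent_bmi = systematic + config.latent_noise_sd * eps_b
    latent_haz = systematic + config.latent_noise_sd * eps_h

    z_bmi = np.empty(n)
    z_haz = np.empty(n)
    for s in np.unique(sex):
        mask = sex == s
        z_bmi[mask] = _weighted_quantile_shift(
            latent_bmi[mask], weight[mask], _target_for(config, "thinness", s),
            THINNESS_CUTOFF, inclusive=False,
        )
        z_haz[mask] = _weighted_quantile_shift(
            latent_haz[mask], weight[mask], _target_for(config, "stunting", s),
            STUNTING_CUTOFF, inclusive=True,
        )
    frame["z_bmi_age"] = z_bmi
    frame["z_height_age"] = z_haz
    frame["thinness"] = (z_bmi < THINNESS_CUTOFF).astype(int)
    frame["stunting"] = (z_haz <= STUNTING_CUTOFF).astype(int)
    frame["both"] = (frame["thinness"] & frame["stunting"]).astype(int)
    return frame


def generate_lpm_population(
    alpha: float,
    betas: Mapping[str, float],
    covariate_dists: Mapping[str, tuple],
    n: int,
    seed: int,
    *,
    weight_scheme: str = "equal",
) -> pd.DataFrame:
    """Population whose outcome follows an exact linear probability model.

    ``covariate_dists`` maps each covariate name to one of:

    * ``("rank_indicator", lo, hi)`` — deterministic dummy 1{lo < rank <= hi}
      (e.g. ``(0.8, 1.0)`` for a top-quintile indicator);
    * ``("bernoulli_rank", intercept, slope)`` — Bernoulli with logistic
      probability ``sigmoid(intercept + slope * (rank - 0.5))``.

    The outcome is Bernoulli with mean alpha + sum_k beta_k x_k clipped to
    [0, 1]; a clip rate above 10% logs a warning, and an infeasible baseline
    (alpha outside [0, 1]) raises a configuration error.  Returns columns
    ``wealth_score, rank, weight``, one column per covariate, and ``outcome``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError(f"infeasible baseline probability alpha={alpha}")
    if set(betas) != set(covariate_dists):
        raise ConfigurationError("betas and covariate_dists must name the same covariates")
    rng = np.random.default_rng(seed)
    wealth = rng.standard_normal(n)
    if weight_scheme == "equal":
        weight = np.ones(n)
    elif weight_scheme == "variable":
        weight = rng.lognormal(0.0, 0.5, n)
        weight /= weight.mean()
    else:
        raise ConfigurationError("weight_scheme must be 'equal' or 'variable'")
    rank = fractional_rank(wealth, weight)

    frame = pd.DataFrame({"wealth_score": wealth, "rank": rank, "weight": weight})
    p = np.full(n, alpha)
    for name, dist in covariate_dists.items():
        kind = dist[0]
        if kind == "rank_indicator":
            lo, hi = dist[1], dist[2]
            x = ((rank > lo) & (rank <= hi)).astype(float)
        elif kind == "bernoulli_rank":
            a, b = dist[1], dist[2]
            prob = 1.0 / (1.0 + np.exp(-(a + b * (rank - 0.5))))
            x = (rng.random(n) < prob).astype(float)
        else:
            raise ConfigurationError(f"unknown covariate distribution kind {kind!r}")
        frame[name] = x
        p = p + betas[name] * x

    clip_rate = float(np.mean((p < 0) | (p > 1)))
    if clip_rate > 0.10:
        warnings.warn(
            f"linear probability model clipped for {clip_rate:.1%} of records",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("LPM clip rate %.1f%% exceeds 10%%", 100 * clip_rate)
    p = np.clip(p, 0.0, 1.0)
    frame["outcome"] = (rng.random(n) < p).astype(int)
    frame.attrs["clip_rate"] = clip_rate
    return frame


def lpm_ground_truth(
    frame: pd.DataFrame, alpha: float, betas: Mapping[str, float]
) -> pd.DataFrame:
    """True per-covariate contributions implied by the generating model.

    Uses the *generator's* coefficients with the realized covariate means,
    covariate concentration indices and realized outcome mean, giving the
    ground truth that a decomposition run on the sample should recover.
    """
    from .decomposition import covariate_ci, elasticity  # local to avoid cycle

    w = frame["weight"].to_numpy()
    wn = w / w.sum()
    rank = frame["rank"].to_numpy()
    mu = float(np.dot(wn, frame["outcome"].to_numpy()))
    rows = []
    for name, beta in betas.items():
        x = frame[name].to_numpy(dtype=float)
        xbar = float(np.dot(wn, x))
        ck = covariate_ci(x, rank, w) if xbar > 0 else float("nan")
        eta = elasticity(beta, xbar, mu)
        rows.append(
            {"covariate": name, "elasticity": eta, "ci_k": ck, "absolute": eta * ck}
        )
    out = pd.DataFrame(rows)
    explained = out["absolute"].sum()
    out["pct"] = out["absolute"] / explained * 100.0
    return out


def make_lms_fixture() -> pd.DataFrame:
    """Small growth-reference table for tests and examples.

    Two sexes x six ages x two indicators, including L = 0 rows (ages 144
    and 156 months) to exercise the logarithmic branch of the z-score
    formula.  Values are synthetic but in the physiological ballpark for
    adolescents; they are NOT a published growth standard.
    """
    rows = []
    ages = [120, 132, 144, 156, 168, 180]
    for sex, bmi_m0, haz_m0 in (("boy", 16.0, 137.0), ("girl", 16.3, 138.0)):
        for i, age in enumerate(ages):
            L_bmi = 0.0 if age in (144, 156) else 1.0 - 0.5 * i / len(ages)
            rows.append(
                {
                    "sex": sex,
                    "age_months": age,
                    "indicator": "bmi_age",
                    "L": round(L_bmi, 3),
                    "M": round(bmi_m0 + 0.35 * i, 2),
                    "S": round(0.10 + 0.004 * i, 3),
                }
            )
            rows.append(
                {
                    "sex": sex,
                    "age_months": age,
                    "indicator": "height_age",
                    "L": 1.0,
                    "M": round(haz_m0 + 3.0 * i, 1),
                    "S": round(0.045 + 0.001 * i, 4),
                }
            )
    # one exact anchor row used by round-trip tests
    fixture = pd.DataFrame(rows)
    anchor = (fixture["sex"] == "boy") & (fixture["age_months"] == 120) & (
        fixture["indicator"] == "bmi_age"
    )
    fixture.loc[anchor, ["L", "M", "S"]] = [1.0, 16.0, 0.1]
    return fixture
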