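"""BMI, LMS growth-reference z-scores, and undernutrition classification.

Growth references tabulate, for each sex, age in months and indicator
(BMI-for-age or height-for-age), the Box-Cox power L, median M and
coefficient of variation S.  A measurement x maps to a z-score via

    z = ((x / M)**L - 1) / (L * S)    if L != 0
    z = ln(x / M) / S                 if L == 0

which is continuous in L at zero.  Classification follows the conventional
school-age cut-offs: thinness is a BMI-for-age z-score strictly below -2 SD;
stunting is a height-for-age z-score at or below -2 SD (note the asymmetric
boundary: exactly -2 is stunted but not thin); their co-existence is both
flags in the same individual.

The reference table is user-supplied CSV with columns
``sex, age_months, indicator, L, M, S``; ages between tabulated rows are
linearly interpolated parameter-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, OutOfRangeError

__all__ = [
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "load_reference",
    "lookup_reference",
    "classify_nutrition",
    "classify_table",
    "NutritionStatus",
    "REFERENCE_COLUMNS",
    "INDICATORS",
]

REFERENCE_COLUMNS = ("sex", "age_months", "indicator", "L", "M", "S")
INDICATORS = ("bmi_age", "height_age")

#: |z| beyond this is flagged biologically implausible (not dropped by default)
IMPLAUSIBLE_Z = 5.0


def compute_bmi(weight_kg, height_cm):
    """Body-mass index in kg/m² from weight in kg and height in cm."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError("weight_kg and height_cm must be strictly positive")
    bmi = w / (h / 100.0) ** 2
    return float(bmi) if bmi.ndim == 0 else bmi


def lms_zscore(x, L, M, S):
    """LMS z-score; uses the logarithmic branch when L == 0.

    Vectorized over all arguments.  Raises DomainError for non-positive
    measurements, medians or coefficients of variation.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise DomainError("measurement x must be strictly positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise DomainError("M and S must be strictly positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            L == 0,
            np.log(ratio) / S,
            (np.power(ratio, np.where(L == 0, 1.0, L)) - 1.0) / (np.where(L == 0, 1.0, L) * S),
        )
    return float(z) if z.ndim == 0 else z


def lms_inverse(z, L, M, S):
    """Measurement corresponding to z-score z: M(1 + L S z)^{1/L}, or M e^{Sz} at L=0."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    x = np.where(
        L == 0,
        M * np.exp(S * z),
        M * np.power(1.0 + np.where(L == 0, 1.0, L) * S * z, 1.0 / np.where(L == 0, 1.0, L)),
    )
    return float(x) if x.ndim == 0 else x


def age_years_to_months(age_years) -> np.ndarray:
    """Completed months from age in years (floor of age in days / 30.4375)."""
    days = np.asarray(age_years, dtype=float) * 365.25
    months = np.floor(days / 30.4375).astype(int)
    return int(months) if months.ndim == 0 else months


def load_reference(path_or_df) -> pd.DataFrame:
    """Load and validate a growth-reference table (CSV path or DataFrame)."""
    ref = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in REFERENCE_COLUMNS if c not in ref.columns]
    if missing:
        raise DomainError(f"reference table missing required columns: {missing}")
    if ref.duplicated(subset=["sex", "age_months", "indicator"]).any():
        raise DomainError("reference table has duplicate (sex, age_months, indicator) keys")
    if (ref["M"] <= 0).any() or (ref["S"] <= 0).any():
        raise DomainError("reference table requires M > 0 and S > 0")
    return ref.sort_values(["sex", "indicator", "age_months"]).reset_index(drop=True)


def lookup_reference(ref: pd.DataFrame, sex: str, age_months: float, indicator: str):
    """(L, M, S) at the given key; linear interpolation in age between rows.

    Raises OutOfRangeError (naming the tabulated bounds) when the age falls
    outside the reference range for that sex and indicator.
    """
    sub = ref[(ref["sex"] == sex) & (ref["indicator"] == indicator)]
    if sub.empty:
        raise OutOfRangeError(f"no reference rows for sex={sex!r}, indicator={indicator!r}")
    ages = sub["age_months"].to_numpy(dtype=float)
    lo, hi = ages.min(), ages.max()
    if not (lo <= age_months <= hi):
        raise OutOfRangeError(
            f"age {age_months} months outside reference range [{lo:g}, {hi:g}] "
            f"for sex={sex!r}, indicator={indicator!r}"
        )
    L = float(np.interp(age_months, ages, sub["L"].to_numpy(dtype=float)))
    M = float(np.interp(age_months, ages, sub["M"].to_numpy(dtype=float)))
    S = float(np.interp(age_months, ages, sub["S"].to_numpy(dtype=float)))
    return L, M, S


@dataclass(frozen=True)
class NutritionStatus:
    """Binary undernutrition flags; ``both`` is the logical AND of the other two."""

    thinness: int
    stunting: int
    both: int

    def __post_init__(self):
        if self.both != int(self.thinness and self.stunting):
            raise DomainError("both must equal thinness AND stunting")


def classify_nutrition(z_bmi: float, z_haz: float) -> NutritionStatus:
    """Classify one individual from BMI-for-age and height-for-age z-scores.

    Thinness: z_bmi < -2 (strict).  Stunting: z_haz <= -2 (inclusive).
    """
    if not (math.isfinite(z_bmi) and math.isfinite(z_haz)):
        raise DomainError("z-scores must be finite; handle missing values upstream")
    thin = int(z_bmi < -2.0)
    stunt = int(z_haz <= -2.0)
    return NutritionStatus(thinness=thin, stunting=stunt, both=int(thin and stunt))


def classify_table(
    df: pd.DataFrame,
    z_bmi_col: str = "z_bmi_age",
    z_haz_col: str = "z_height_age",
    drop_implausible: bool = False,
) -> pd.DataFrame:
    """Vectorized classification of a records table.

    Adds ``thinness``, ``stunting``, ``both`` (nullable Int64: missing z gives
    missing flags, excluded from denominators downstream) and an
    ``implausible_z`` flag for |z| > 5.  With ``drop_implausible`` flagged
    rows have their outcome flags set missing instead of merely flagged.
    """
    out = df.copy()
    zb = pd.to_numeric(out[z_bmi_col], errors="coerce")
    zh = pd.to_numeric(out[z_haz_col], errors="coerce")
    thin = (zb < -2.0).astype("Int64").where(zb.notna())
    stunt = (zh <= -2.0).astype("Int64").where(zh.notna())
    both = (thin.astype("Float64") * stunt.astype("Float64")).astype("Int64")
    implausible = (zb.abs() > IMPLAUSIBLE_Z) | (zh.abs() > IMPLAUSIBLE_Z)
    if drop_implausible:
        thin = thin.where(~implausible)
        stunt = stunt.where(~implausible)
        both = both.where(~implausible)
    out["thinness"] = thin
    out["stunting"] = stunt
    out["both"] = both
    out["implausible_z"] = implausible.fillna(False)
    return out
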