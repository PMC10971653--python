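"""Predicted lung gas volumes from height, age and sex.

Without a spirometer, the gas volume in the lungs during a weighing trial
is taken from reference equations: total lung capacity (TLC, maximal
inhale) as a linear function of height, and residual volume (RV, maximal
exhale) as a linear function of height and age, each sex-specific.
Equations consume height in metres; the I/O boundary accepts centimetres
(stadiometer convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .participants import Sex, as_sex

#: TLC (L) = a * height_m + b
TLC_COEF = {Sex.MALE: (7.99, -7.08), Sex.FEMALE: (6.60, -5.79)}

#: RV (L) = a * height_m + b * age_yr + c
RV_COEF = {Sex.MALE: (1.31, 0.022, -1.232), Sex.FEMALE: (1.812, 0.016, -2.003)}

HEIGHT_RANGE_M = (1.0, 2.5)
AGE_RANGE_YR = (18.0, 100.0)


def _check_height(height_m: float) -> None:
    lo, hi = HEIGHT_RANGE_M
    if not (lo < height_m < hi):
        raise ValueError(f"height {height_m} m outside the supported range ({lo}, {hi}) m")


def predict_tlc(sex, height_m: float) -> float:
    """Predicted total lung capacity in litres."""
    sex = as_sex(sex)
    _check_height(height_m)
    a, b = TLC_COEF[sex]
    return a * height_m + b


def predict_rv(sex, height_m: float, age_yr: float) -> float:
    """Predicted residual volume in litres (adults only)."""
    sex = as_sex(sex)
    _check_height(height_m)
    lo, hi = AGE_RANGE_YR
    if not (lo <= age_yr <= hi):
        raise ValueError(f"age {age_yr} yr outside the supported range [{lo}, {hi}] yr")
    a, b, c = RV_COEF[sex]
    return a * height_m + b * age_yr + c


@dataclass(frozen=True)
class LungVolumes:
    """Predicted TLC and RV with the inputs that produced them."""

    tlc_l: float
    rv_l: float
    height_m: float
    age_yr: float
    sex: Sex


def predict_lung_volumes(sex, height_m: float, age_yr: float) -> LungVolumes:
    """Predict both lung volumes; warns if TLC <= RV (implausible inputs)."""
    sex = as_sex(sex)
    tlc = predict_tlc(sex, height_m)
    rv = predict_rv(sex, height_m, age_yr)
    if not (tlc > rv > 0):
        warnings.warn(
            f"predicted lung volumes implausible (TLC={tlc:.3f} L, RV={rv:.3f} L)",
            stacklevel=2,
        )
    return LungVolumes(tlc_l=tlc, rv_l=rv, height_m=height_m, age_yr=age_yr, sex=sex)
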