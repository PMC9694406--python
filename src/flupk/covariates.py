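"""Patient-level covariates feeding the fludarabine clearance model.

The individual clearance model consumes four derived quantities: fat-free
mass (the allometric size metric), creatinine clearance indexed to 1.73 m2
and capped at 150 mL/min/1.73 m2, an age-driven maturation fraction, and a
linear renal-function multiplier centred at CrCL = 100. Body surface area is
additionally needed for mg/m2 dosing and for indexing the Cockcroft-Gault
estimate.

Conventions: age in years, weight in kg, height in cm, serum creatinine in
mg/dL, CrCL in mL/min/1.73 m2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import AgeExtrapolationWarning, ValidationError

__all__ = [
    "Subject",
    "fat_free_mass",
    "creatinine_clearance",
    "body_surface_area",
    "maturation_factor",
    "crcl_clearance_factor",
    "CRCL_CAP_DEFAULT",
    "THETA_MATURATION_DEFAULT",
    "CRCL_EFFECT_DEFAULT",
]

CRCL_CAP_DEFAULT = 150.0
THETA_MATURATION_DEFAULT = 3.54
CRCL_EFFECT_DEFAULT = 0.00186

#: below this age (5 months) the maturation function is an extrapolation
MATURATION_VALIDATED_MIN_AGE = 5.0 / 12.0


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0) or not math.isfinite(v):
            raise ValidationError(f"{name} must be a positive finite number, got {v!r}")


def _normalize_sex(sex) -> str:
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("male", "m"):
            return "male"
        if s in ("female", "f"):
            return "female"
    elif sex in (0, 1):
        # dataset convention: 0 = male, 1 = female
        return "male" if sex == 0 else "female"
    raise ValidationError(f"sex must be 'male'/'female' (or 0/1), got {sex!r}")


def body_surface_area(weight: float, height: float, formula: str = "mosteller") -> float:
    """Body surface area in m2.

    Mosteller by default (sqrt(height*weight/3600)); DuBois available via
    ``formula='dubois'``.
    """
    _require_positive(weight=weight, height=height)
    if formula == "mosteller":
        return math.sqrt(height * weight / 3600.0)
    if formula == "dubois":
        return 0.007184 * weight**0.425 * height**0.725
    raise ValidationError(f"unknown BSA formula {formula!r}")


def fat_free_mass(
    age: float,
    sex,
    weight: float,
    height: float,
    *,
    young_age_cutoff: float = 3.0,
    adult_age: float = 18.0,
) -> float:
    """Fat-free mass (kg) by the Al-Sallami sex-specific maturation model.

    The pediatric FFM is the adult FFM formula (a weight/BMI hyperbola)
    scaled by a sex-specific sigmoidal maturation multiplier in age. The
    model is applied between ``young_age_cutoff`` and ``adult_age``; below
    the cutoff total body weight is returned (no referenced infant FFM
    equation), at or above ``adult_age`` the plain adult formula is used.
    The result is never allowed to exceed total body weight.
    """
    sex = _normalize_sex(sex)
    _require_positive(weight=weight, height=height)
    if age < 0 or not math.isfinite(age):
        raise ValidationError(f"age must be non-negative, got {age!r}")
    if age < young_age_cutoff:
        return weight
    bmi = weight / (height / 100.0) ** 2
    if sex == "male":
        adult = 9270.0 * weight / (6680.0 + 216.0 * bmi)
        mult = 0.88 + (1.0 - 0.88) / (1.0 + (age / 13.4) ** -12.7)
    else:
        adult = 9270.0 * weight / (8780.0 + 244.0 * bmi)
        mult = 1.11 + (1.0 - 1.11) / (1.0 + (age / 7.1) ** -1.1)
    ffm = adult if age >= adult_age else mult * adult
    return min(ffm, weight)


def creatinine_clearance(
    age: float,
    sex,
    weight: float,
    height: float,
    scr: float,
    cap: float = CRCL_CAP_DEFAULT,
) -> float:
    """Estimated creatinine clearance, mL/min/1.73 m2, capped.

    Bedside Schwartz (0.413*height/SCr, already indexed to 1.73 m2) up to
    the 18th birthday; Cockcroft-Gault thereafter, indexed by 1.73/BSA
    (Mosteller). The estimate is capped (default 150 mL/min/1.73 m2) before
    use in the clearance model.
    """
    sex = _normalize_sex(sex)
    _require_positive(weight=weight, height=height, scr=scr)
    if age < 0 or not math.isfinite(age):
        raise ValidationError(f"age must be non-negative, got {age!r}")
    if age < 18.0:
        crcl = 0.413 * height / scr
    else:
        cg = (140.0 - age) * weight / (72.0 * scr)
        if sex == "female":
            cg *= 0.85
        crcl = cg * 1.73 / body_surface_area(weight, height)
    return min(crcl, cap)


def maturation_factor(age: float, theta: float = THETA_MATURATION_DEFAULT) -> float:
    """Fraction of adult-equivalent clearance attained at a given age.

    Fmat = 1 - exp(-age * theta); monotone in age, 0 at birth, -> 1 with
    age. Warns (does not fail) below 5 months of age, where the function is
    an extrapolation beyond the ages it was estimated on.
    """
    if age < 0 or not math.isfinite(age):
        raise ValidationError(f"age must be non-negative, got {age!r}")
    if not (theta > 0):
        raise ValidationError(f"theta must be positive, got {theta!r}")
    if age < MATURATION_VALIDATED_MIN_AGE:
        warnings.warn(
            f"maturation function evaluated at age {age:.3f} y (< 5 months); "
            "the model is not validated this young and may under-predict clearance",
            AgeExtrapolationWarning,
            stacklevel=2,
        )
    return 1.0 - math.exp(-age * theta)


def crcl_clearance_factor(
    crcl: float,
    crcl_eff: float = CRCL_EFFECT_DEFAULT,
    floor: float = 0.01,
) -> float:
    """Linear renal-function multiplier on clearance: 1 + (CrCL - 100) * eff.

    ``crcl`` is expected to be the capped estimate. The raw linear form is
    unguarded, so the result is floored at a small positive value to keep
    clearance positive for pathological inputs.
    """
    if not math.isfinite(crcl) or crcl < 0:
        raise ValidationError(f"crcl must be non-negative, got {crcl!r}")
    return max(1.0 + (crcl - 100.0) * crcl_eff, floor)


@dataclass(frozen=True)
class Subject:
    """Demographics, labs and (optionally pre-computed) derived covariates.

    ``crcl`` and ``ffm`` override the internally computed values when given
    (mirroring optional CRCL/FFM dataset columns); the CrCL override is
    still capped before model use.
    """

    id: str
    age: float
    sex: str
    weight: float
    height: float
    serum_creatinine: float
    crcl: Optional[float] = None
    ffm: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "sex", _normalize_sex(self.sex))
        _require_positive(
            age=self.age,
            weight=self.weight,
            height=self.height,
            serum_creatinine=self.serum_creatinine,
        )
        if self.crcl is not None and not (self.crcl > 0):
            raise ValidationError(f"crcl override must be positive, got {self.crcl!r}")
        if self.ffm is not None:
            if not (self.ffm > 0):
                raise ValidationError(f"ffm override must be positive, got {self.ffm!r}")
            if self.ffm > self.weight * (1 + 1e-9):
                raise ValidationError("ffm override exceeds total body weight")

    def fat_free_mass(self) -> float:
        if self.ffm is not None:
            return self.ffm
        return fat_free_mass(self.age, self.sex, self.weight, self.height)

    def creatinine_clearance(self, cap: float = CRCL_CAP_DEFAULT) -> float:
        if self.crcl is not None:
            return min(self.crcl, cap)
        return creatinine_clearance(
            self.age, self.sex, self.weight, self.height, self.serum_creatinine, cap=cap
        )

    def bsa(self, formula: str = "mosteller") -> float:
        return body_surface_area(self.weight, self.height, formula=formula)

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2
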