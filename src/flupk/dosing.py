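"""Individualized dosing: MAP estimation from sparse levels and dose rules.

MAP (maximum a posteriori) estimation finds the posterior mode of a
subject's random effects eta = (eta_CL, eta_Vc) given observed plasma
concentrations and the population prior:

    objective(eta) = sum_j r_j(eta)^2 / sigma^2 + eta' Omega^{-1} eta

with residuals r_j on the scale of the configured error model (log
concentration by default). Below-quantitation observations are excluded
from the objective and reported in the fit.

Dose individualization inverts the linear-PK exposure identity
cAUC = total dose / CL: daily dose = target_cAUC * CL / n_days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .covariates import Subject, body_surface_area
from .errors import ConvergenceError, ValidationError
from .pk import (
    NG_PER_ML_TO_MG_PER_L,
    DoseRegimen,
    PKParameters,
    PopulationModel,
    concentration_profile,
    individual_parameters,
)

__all__ = [
    "PKObservation",
    "DoseRecommendation",
    "DoseRule",
    "BSA_40",
    "MAPFit",
    "map_estimate",
    "model_based_dose",
    "traditional_dose",
    "dose_accuracy",
]

LLOQ_NG_ML_DEFAULT = 2.0

#: multi-start grid for the simplex optimizer (deterministic)
_MAP_STARTS = ((0.0, 0.0), (0.5, 0.0), (-0.5, 0.0), (0.0, 0.5), (0.0, -0.5))


@dataclass(frozen=True)
class PKObservation:
    """One plasma level: time (h since first dose), value (ng/mL), BLQ flag.

    The BLQ flag defaults to value < LLOQ (2 ng/mL).
    """

    time: float
    value: float
    blq: Optional[bool] = None
    lloq: float = LLOQ_NG_ML_DEFAULT

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.time!r}")
        if self.value < 0:
            raise ValidationError(f"observation value must be >= 0, got {self.value!r}")
        if self.blq is None:
            object.__setattr__(self, "blq", bool(self.value < self.lloq))

    @property
    def value_mg_per_l(self) -> float:
        return self.value * NG_PER_ML_TO_MG_PER_L


@dataclass(frozen=True)
class DoseRecommendation:
    """A daily dose (mg) over n_days aiming at target_cauc (mg*h/L)."""

    daily_dose: float
    n_days: int
    target_cauc: float
    basis: str  # 'typical' | 'map' | 'bsa' | 'weight'

    @property
    def total_dose(self) -> float:
        return self.daily_dose * self.n_days

    def regimen(self, duration: float = 1.0, interval: float = 24.0) -> DoseRegimen:
        return DoseRegimen.daily(self.daily_dose, self.n_days, duration, interval)


@dataclass(frozen=True)
class DoseRule:
    """Traditional dosing rule: rate in mg/m2 ('bsa') or mg/kg ('weight')."""

    kind: str
    rate: float

    def __post_init__(self):
        if self.kind not in ("bsa", "weight"):
            raise ValidationError(f"dose rule kind must be 'bsa' or 'weight', got {self.kind!r}")
        if not (self.rate > 0):
            raise ValidationError(f"dose rate must be positive, got {self.rate!r}")

    @property
    def label(self) -> str:
        unit = "mg/m2" if self.kind == "bsa" else "mg/kg"
        return f"{self.rate:g} {unit}"


#: the most common traditional rule in the cohort
BSA_40 = DoseRule("bsa", 40.0)


@dataclass(frozen=True)
class MAPFit:
    """Result of a MAP estimation: posterior-mode eta and individual parameters."""

    eta: Tuple[float, float]
    params: PKParameters
    objective: float
    converged: bool
    n_obs_used: int
    n_blq_excluded: int


def _validate_n_days(n_days: int) -> int:
    n = int(n_days)
    if n != n_days or not (3 <= n <= 5):
        raise ValidationError(f"n_days must be an integer in 3..5, got {n_days!r}")
    return n


def map_objective(
    model: PopulationModel,
    subject: Subject,
    regimen: DoseRegimen,
    times: np.ndarray,
    obs_mg_l: np.ndarray,
):
    """Build the MAP objective function over eta (used by the optimizer and tests)."""
    omega_inv = np.linalg.inv(model.omega_matrix())
    sigma = model.sigma
    if not (sigma > 0):
        raise ValidationError("residual sigma must be positive for MAP estimation")
    base = individual_parameters(model, subject, (0.0, 0.0))
    log_obs = np.log(np.maximum(obs_mg_l, 1e-12))

    def objective(eta: np.ndarray) -> float:
        e = np.asarray(eta, dtype=float)
        params = PKParameters(
            cl=base.cl * math.exp(e[0]),
            vc=base.vc * math.exp(e[1]),
            q=base.q,
            vp=base.vp,
        )
        pred = concentration_profile(params, regimen, times)
        if model.residual_model == "lognormal":
            r = (log_obs - np.log(np.maximum(pred, 1e-12))) / sigma
        else:
            r = (obs_mg_l - pred) / sigma
        return float(r @ r + e @ omega_inv @ e)

    return objective


def map_estimate(
    model: PopulationModel,
    subject: Subject,
    regimen: DoseRegimen,
    observations: Sequence[PKObservation],
    include_blq: bool = False,
) -> MAPFit:
    """Posterior-mode random effects from sparse concentrations.

    Deterministic: derivative-free simplex from a fixed start grid
    {0, +-0.5 per axis}; ties broken by lowest objective then lexicographic
    eta. With no usable observations the prior mode (eta = 0) is returned.
    """
    usable = [o for o in observations if include_blq or not o.blq]
    n_blq = len(observations) - len(usable)
    if not usable:
        return MAPFit(
            eta=(0.0, 0.0),
            params=individual_parameters(model, subject, (0.0, 0.0)),
            objective=0.0,
            converged=True,
            n_obs_used=0,
            n_blq_excluded=n_blq,
        )
    times = np.array([o.time for o in usable], dtype=float)
    obs = np.array([o.value_mg_per_l for o in usable], dtype=float)
    objective = map_objective(model, subject, regimen, times, obs)

    candidates = []
    for start in _MAP_STARTS:
        res = minimize(
            objective,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000, "maxfev": 8000},
        )
        if res.success:
            candidates.append((round(float(res.fun), 9), tuple(np.round(res.x, 12)), res))
    if not candidates:
        raise ConvergenceError(
            f"MAP optimizer failed from all {len(_MAP_STARTS)} starts "
            f"(subject {subject.id!r}, {len(usable)} observations)"
        )
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = candidates[0][2]
    eta = (float(best.x[0]), float(best.x[1]))
    return MAPFit(
        eta=eta,
        params=individual_parameters(model, subject, eta),
        objective=float(best.fun),
        converged=True,
        n_obs_used=len(usable),
        n_blq_excluded=n_blq,
    )


def model_based_dose(
    model: PopulationModel,
    subject: Subject,
    target_cauc: float,
    n_days: int = 4,
    eta: Optional[Sequence[float]] = None,
    round_mg: bool = False,
) -> DoseRecommendation:
    """Daily dose achieving the cAUC target under the subject's clearance.

    Uses the typical clearance (eta omitted) or the MAP-individual clearance
    (eta given): daily_dose = target_cauc * CL / n_days, exact algebra.
    """
    if not (target_cauc > 0):
        raise ValidationError(f"target_cauc must be positive, got {target_cauc!r}")
    n = _validate_n_days(n_days)
    basis = "typical" if eta is None else "map"
    params = individual_parameters(model, subject, (0.0, 0.0) if eta is None else eta)
    daily = target_cauc * params.cl / n
    if round_mg:
        daily = float(round(daily))
    return DoseRecommendation(daily_dose=daily, n_days=n, target_cauc=target_cauc, basis=basis)


def traditional_dose(
    subject: Subject,
    rule: DoseRule = BSA_40,
    n_days: int = 4,
) -> DoseRecommendation:
    """BSA-based (mg/m2) or weight-based (mg/kg) daily dose.

    Convention: BSA-based dosing for patients over 10 kg and 2 years,
    weight-based below; a mismatched rule warns but is honoured.
    """
    n = _validate_n_days(n_days)
    big = subject.weight > 10.0 and subject.age > 2.0
    if rule.kind == "bsa" and not big:
        warnings.warn(
            f"BSA-based rule applied to a small/young subject "
            f"({subject.weight} kg, {subject.age} y); weight-based dosing is customary",
            UserWarning,
            stacklevel=2,
        )
    if rule.kind == "weight" and big:
        warnings.warn(
            f"weight-based rule applied to a larger/older subject "
            f"({subject.weight} kg, {subject.age} y); BSA-based dosing is customary",
            UserWarning,
            stacklevel=2,
        )
    if rule.kind == "bsa":
        daily = rule.rate * body_surface_area(subject.weight, subject.height)
    else:
        daily = rule.rate * subject.weight
    return DoseRecommendation(daily_dose=daily, n_days=n, target_cauc=float("nan"), basis=rule.kind)


def dose_accuracy(predicted_cauc: float, target_cauc: float) -> float:
    """Exposure-target attainment as a percentage: 100 * predicted / target."""
    if not (target_cauc > 0):
        raise ValidationError(f"target_cauc must be positive, got {target_cauc!r}")
    return 100.0 * predicted_cauc / target_cauc
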