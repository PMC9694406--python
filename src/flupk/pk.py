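"""Two-compartment IV-infusion population PK model for f-ara-a.

Structural model: linear two-compartment disposition with zero-order
infusion input into the central compartment. Individual clearance follows

    CL_i = CL_pop * Fmat(age) * (FFM/12)^0.75 * (1 + (CrCL - 100)*CrCL_eff) * exp(eta_CL)

with volumes scaled linearly in FFM/12 and the intercompartmental clearance
allometrically (exponent 0.75). Interindividual variability is a bivariate
log-normal on (CL, Vc).

Concentrations are central-compartment amounts over Vc, in mg/L (dataset
observations in ng/mL are converted by the exact factor 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .covariates import Subject, crcl_clearance_factor, maturation_factor
from .errors import ConfigError, ValidationError

__all__ = [
    "PopulationModel",
    "PKParameters",
    "DoseEvent",
    "DoseRegimen",
    "ExposureSummary",
    "individual_parameters",
    "concentration_profile",
    "ode_oracle",
    "cumulative_auc",
    "NG_PER_ML_TO_MG_PER_L",
]

#: exact unit conversion for observed concentrations
NG_PER_ML_TO_MG_PER_L = 0.001

_OMEGA_DEFAULT = ((0.117, 0.141), (0.141, 0.303))


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, IIV covariance and residual model of the refined popPK model.

    ``cl_pop`` (typical clearance, L/h per 12 kg FFM) has no default: it is
    not printed in the source estimates table and must be supplied
    explicitly. All other defaults are the refined-model estimates.

    ``omega`` entries are variances/covariance of log-normal random effects
    on (CL, Vc); set ``omega_cl_vc_is_correlation=True`` to reinterpret the
    off-diagonal as a correlation instead.

    ``residual_model``: 'lognormal' (additive on log concentration, sigma
    ~= proportional CV) or 'additive' (sigma in mg/L).
    """

    cl_pop: float
    vc_ref: float = 11.5
    q_ref: float = 1.47
    vp_ref: float = 8.48
    crcl_eff: float = 0.00186
    theta_mat: float = 3.54
    omega: Tuple[Tuple[float, float], Tuple[float, float]] = _OMEGA_DEFAULT
    omega_cl_vc_is_correlation: bool = False
    sigma: float = 0.36
    residual_model: str = "lognormal"
    ffm_ref: float = 12.0
    allo_exp_cl: float = 0.75
    allo_exp_v: float = 1.0
    crcl_cap: float = 150.0
    lloq_ng_ml: float = 2.0
    molar_factor: float = 1.0

    def __post_init__(self):
        if self.cl_pop is None:
            raise ConfigError(
                "cl_pop (typical clearance, L/h per 12 kg FFM) is required; it is "
                "not part of the published estimates table and has no default"
            )
        for name in ("cl_pop", "vc_ref", "q_ref", "vp_ref", "theta_mat", "ffm_ref"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ConfigError(f"{name} must be positive and finite, got {v!r}")
        if self.sigma < 0:
            raise ConfigError("sigma must be non-negative")
        if self.residual_model not in ("lognormal", "additive"):
            raise ConfigError(f"unknown residual_model {self.residual_model!r}")
        om = self.omega_matrix()
        if not np.allclose(om, om.T):
            raise ConfigError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(om) <= 0):
            raise ConfigError("omega must be positive-definite")

    def omega_matrix(self) -> np.ndarray:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2):
            raise ConfigError(f"omega must be 2x2, got shape {om.shape}")
        if self.omega_cl_vc_is_correlation:
            om = om.copy()
            cov = om[0, 1] * math.sqrt(om[0, 0] * om[1, 1])
            om[0, 1] = om[1, 0] = cov
        return om

    def with_(self, **changes) -> "PopulationModel":
        return replace(self, **changes)


@dataclass(frozen=True)
class PKParameters:
    """One individual's two-compartment parameters (L/h and L)."""

    cl: float
    vc: float
    q: float
    vp: float

    def __post_init__(self):
        for name in ("cl", "vc", "q", "vp"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")

    def micro_constants(self) -> Tuple[float, float, float]:
        """(k10, k12, k21) in 1/h."""
        return self.cl / self.vc, self.q / self.vc, self.q / self.vp

    def macro_constants(self) -> Tuple[float, float, float, float]:
        """Disposition exponents and central-compartment coefficients.

        Returns (lambda1, lambda2, A1, A2) with lambda1 > lambda2 > 0 and
        A1 + A2 = 1: a unit IV bolus gives C(t) = (A1 e^{-l1 t} + A2 e^{-l2 t})/Vc.
        """
        k10, k12, k21 = self.micro_constants()
        s = k10 + k12 + k21
        disc2 = s * s - 4.0 * k10 * k21
        disc = math.sqrt(max(disc2, 0.0))
        lam1 = 0.5 * (s + disc)
        lam2 = 0.5 * (s - disc)
        if lam1 - lam2 <= 1e-12 * lam1:
            raise ValidationError("degenerate disposition (repeated eigenvalues)")
        a1 = (lam1 - k21) / (lam1 - lam2)
        a2 = (k21 - lam2) / (lam1 - lam2)
        return lam1, lam2, a1, a2

    @property
    def terminal_half_life(self) -> float:
        return math.log(2.0) / self.macro_constants()[1]


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order IV infusion: amount (mg), start (h), duration (h)."""

    amount: float
    start: float
    duration: float = 1.0

    def __post_init__(self):
        if not (self.amount > 0):
            raise ValidationError(f"dose amount must be positive, got {self.amount!r}")
        if self.start < 0:
            raise ValidationError(f"dose start must be non-negative, got {self.start!r}")
        if not (self.duration > 0):
            raise ValidationError(f"infusion duration must be positive, got {self.duration!r}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DoseRegimen:
    """Ordered IV infusion events; default convention is one dose per day."""

    events: Tuple[DoseEvent, ...]

    def __post_init__(self):
        evs = tuple(self.events)
        object.__setattr__(self, "events", evs)
        if not evs:
            raise ValidationError("a regimen needs at least one dose event")
        starts = [e.start for e in evs]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValidationError("dose start times must be non-decreasing")

    @classmethod
    def daily(
        cls,
        daily_dose: float,
        n_days: int,
        duration: float = 1.0,
        interval: float = 24.0,
    ) -> "DoseRegimen":
        """n_days equal doses at t = 0, interval, 2*interval, ..."""
        if not (n_days >= 1):
            raise ValidationError("n_days must be >= 1")
        return cls(
            tuple(DoseEvent(daily_dose, i * interval, duration) for i in range(int(n_days)))
        )

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    @property
    def last_end(self) -> float:
        return max(e.end for e in self.events)


@dataclass(frozen=True)
class ExposureSummary:
    """Cumulative and per-dose AUC (mg*h/L) for one subject under one regimen."""

    cauc: float
    per_dose_auc: Tuple[float, ...]
    method: str


def individual_parameters(
    model: PopulationModel,
    subject: Subject,
    eta: Sequence[float] = (0.0, 0.0),
) -> PKParameters:
    """Individual PK parameters from covariates and log-normal random effects.

    eta = (eta_CL, eta_Vc); Q and Vp carry no IIV.
    """
    e1, e2 = float(eta[0]), float(eta[1])
    if not (math.isfinite(e1) and math.isfinite(e2)):
        raise ValidationError(f"eta must be finite, got {eta!r}")
    ffm = subject.fat_free_mass()
    crcl = subject.creatinine_clearance(cap=model.crcl_cap)
    fmat = maturation_factor(subject.age, model.theta_mat)
    fren = crcl_clearance_factor(crcl, model.crcl_eff)
    size_cl = (ffm / model.ffm_ref) ** model.allo_exp_cl
    size_v = (ffm / model.ffm_ref) ** model.allo_exp_v
    return PKParameters(
        cl=model.cl_pop * fmat * size_cl * fren * math.exp(e1),
        vc=model.vc_ref * size_v * math.exp(e2),
        q=model.q_ref * size_cl,
        vp=model.vp_ref * size_v,
    )


def _times_array(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size and t.min() < 0:
        raise ValidationError("times must be non-negative")
    return t


def concentration_profile(
    params: PKParameters,
    regimen: DoseRegimen,
    times,
) -> np.ndarray:
    """Central-compartment concentration (mg/L) at the requested times.

    Biexponential closed form with superposition over infusion events: for
    time tau since an event's start,

        C(tau) = (R0/Vc) * sum_i (A_i/l_i) (1 - e^{-l_i min(tau,T)}) e^{-l_i max(tau-T,0)}
    """
    t = _times_array(times)
    lam1, lam2, a1, a2 = params.macro_constants()
    c = np.zeros_like(t)
    for ev in regimen.events:
        tau = t - ev.start
        rate = ev.amount / ev.duration
        for lam, a in ((lam1, a1), (lam2, a2)):
            tin = np.clip(tau, 0.0, ev.duration)
            tpost = np.clip(tau - ev.duration, 0.0, None)
            c += (rate / params.vc) * (a / lam) * (1.0 - np.exp(-lam * tin)) * np.exp(
                -lam * tpost
            )
    return c


def ode_oracle(
    params: PKParameters,
    regimen: Optional[DoseRegimen],
    times,
    full_output: bool = False,
):
    """Numeric-integration reference for :func:`concentration_profile`.

    Integrates the two-compartment amounts (plus cumulative elimination as a
    third state for mass-balance checks) piecewise between infusion
    boundaries with tight tolerances. A ``None`` regimen means no drug.
    Intended as an independent cross-check, not for production simulation.
    """
    from scipy.integrate import solve_ivp

    t = _times_array(times)
    if regimen is None or not regimen.events:
        zeros = np.zeros_like(t)
        return (zeros, np.zeros((t.size, 3))) if full_output else zeros

    k10, k12, k21 = params.micro_constants()
    events = regimen.events

    def rate_at(a: float, b: float) -> float:
        # constant total infusion rate on the open segment (a, b)
        mid = 0.5 * (a + b)
        return sum(e.amount / e.duration for e in events if e.start < mid < e.end)

    breaks = {0.0}
    for e in events:
        breaks.add(e.start)
        breaks.add(e.end)
    breaks.update(float(x) for x in t)
    grid = sorted(breaks)

    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    states = np.zeros((t.size, 3))
    y = np.zeros(3)
    pos = 0
    # record any t == 0 evaluations
    while pos < t_sorted.size and t_sorted[pos] == 0.0:
        pos += 1

    for a, b in zip(grid, grid[1:]):
        r = rate_at(a, b)

        def rhs(_t, yy, r=r):
            a1c, a2c, _ = yy
            return [
                r - (k10 + k12) * a1c + k21 * a2c,
                k12 * a1c - k21 * a2c,
                k10 * a1c,
            ]

        t_eval = [x for x in t_sorted[pos:] if a < x <= b]
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval + ([b] if not t_eval or t_eval[-1] != b else []),
            rtol=1e-11,
            atol=1e-13,
            max_step=np.inf,
        )
        if not sol.success:
            raise RuntimeError(f"ODE oracle integration failed on [{a}, {b}]: {sol.message}")
        for i, x in enumerate(t_eval):
            states[order[pos + i]] = sol.y[:, i]
        pos += len(t_eval)
        y = sol.y[:, -1]
        if pos >= t_sorted.size and b >= t_sorted.max():
            break

    conc = states[:, 0] / params.vc
    return (conc, states) if full_output else conc


def cumulative_auc(
    params: PKParameters,
    regimen: DoseRegimen,
    method: str = "closed_form",
    horizon: Optional[float] = None,
    grid_step: float = 0.02,
) -> ExposureSummary:
    """Cumulative AUC (mg*h/L) to infinity.

    closed_form: exact linear-PK identity sum(amount)/CL (per-dose AUCs are
    amount/CL). trapezoid: fine-grid numeric integral of the concentration
    profile out to ``horizon`` (default: end of last infusion plus 10
    terminal half-lives).
    """
    if method == "closed_form":
        per = tuple(e.amount / params.cl for e in regimen.events)
        return ExposureSummary(cauc=sum(per), per_dose_auc=per, method=method)
    if method == "trapezoid":
        if horizon is None:
            horizon = regimen.last_end + 10.0 * params.terminal_half_life
        t = np.arange(0.0, horizon + grid_step, grid_step)
        c = concentration_profile(params, regimen, t)
        cauc = float(np.trapezoid(c, t))
        per = tuple(e.amount / params.cl for e in regimen.events)
        return ExposureSummary(cauc=cauc, per_dose_auc=per, method=method)
    raise ValidationError(f"unknown AUC method {method!r}")
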