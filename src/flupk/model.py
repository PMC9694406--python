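"""Model/Results interface for individual (MAP) fludarabine PK fitting.

`FludarabineModel` binds the population model to one subject's dose history
and sparse plasma levels; `fit()` returns a `MAPResults` carrying the
posterior-mode random effects, their approximate uncertainty (inverse
curvature of the posterior at the mode), the individual PK parameters, and
dose-individualization helpers.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .covariates import Subject
from .dosing import (
    DoseRecommendation,
    MAPFit,
    PKObservation,
    map_estimate,
    map_objective,
    model_based_dose,
)
from .errors import DatasetError
from .pk import (
    DoseRegimen,
    ExposureSummary,
    PKParameters,
    PopulationModel,
    concentration_profile,
    cumulative_auc,
)
from .synthetic import subjects_from_dataset

__all__ = ["FludarabineModel", "MAPResults"]


class FludarabineModel:
    """Individual PK model: population prior + one subject's data.

    Parameters
    ----------
    population : PopulationModel
        Fixed effects, Omega and residual model.
    subject : Subject
        Demographics and labs (drives the covariate model).
    regimen : DoseRegimen
        Administered IV infusion events.
    observations : sequence of PKObservation, optional
        Sparse plasma levels (ng/mL). With no observations, `fit()` returns
        the prior mode (typical-subject parameters).
    """

    def __init__(
        self,
        population: PopulationModel,
        subject: Subject,
        regimen: DoseRegimen,
        observations: Sequence[PKObservation] = (),
    ):
        self.population = population
        self.subject = subject
        self.regimen = regimen
        self.observations = tuple(observations)

    @classmethod
    def from_dataframe(
        cls,
        population: PopulationModel,
        data: pd.DataFrame,
        subject_id: Optional[str] = None,
    ) -> "FludarabineModel":
        """Build from a NONMEM-style dataset (one subject's rows)."""
        records = {r.subject.id: r for r in subjects_from_dataset(data)}
        if subject_id is None:
            if len(records) != 1:
                raise DatasetError(
                    f"dataset holds {len(records)} subjects; pass subject_id"
                )
            subject_id = next(iter(records))
        if str(subject_id) not in records:
            raise DatasetError(f"subject {subject_id!r} not found in dataset")
        rec = records[str(subject_id)]
        obs = [
            PKObservation(time=float(t), value=float(v), lloq=population.lloq_ng_ml)
            for t, v in zip(rec.obs_times, rec.obs_ng_ml)
        ]
        return cls(population, rec.subject, rec.regimen, obs)

    def fit(self) -> "MAPResults":
        """MAP-estimate the subject's random effects; returns results."""
        mapfit = map_estimate(
            self.population, self.subject, self.regimen, self.observations
        )
        eta_se = self._eta_se(mapfit)
        return MAPResults(self, mapfit, eta_se)

    def _eta_se(self, mapfit: MAPFit) -> np.ndarray:
        """Approximate posterior SDs of eta from the curvature at the mode.

        The objective is -2 log posterior (up to a constant), so the
        covariance is 2 * H^{-1} with H its Hessian.
        """
        usable = [o for o in self.observations if not o.blq]
        if not usable:
            om = self.population.omega_matrix()
            return np.sqrt(np.diag(om))
        times = np.array([o.time for o in usable])
        obs = np.array([o.value_mg_per_l for o in usable])
        f = map_objective(self.population, self.subject, self.regimen, times, obs)
        x = np.asarray(mapfit.eta, dtype=float)
        h = 1e-4
        hess = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                hess[i, j] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h * h)
        try:
            cov = 2.0 * np.linalg.inv(hess)
            d = np.diag(cov)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(2, np.nan)


class MAPResults:
    """Posterior-mode estimates for one subject, with dosing helpers."""

    def __init__(self, model: FludarabineModel, mapfit: MAPFit, eta_se: np.ndarray):
        self.model = model
        self.eta = np.asarray(mapfit.eta, dtype=float)
        self.eta_se = np.asarray(eta_se, dtype=float)
        self.params: PKParameters = mapfit.params
        self.objective = mapfit.objective
        self.converged = mapfit.converged
        self.n_obs_used = mapfit.n_obs_used
        self.n_blq_excluded = mapfit.n_blq_excluded

    def predict(self, times) -> np.ndarray:
        """Individual concentration prediction (mg/L) at the given times."""
        return self.model.population.molar_factor * concentration_profile(
            self.params, self.model.regimen, times
        )

    def cumulative_auc(self, method: str = "closed_form") -> ExposureSummary:
        """Predicted cAUC (mg*h/L) under the administered regimen."""
        summ = cumulative_auc(self.params, self.model.regimen, method=method)
        mf = self.model.population.molar_factor
        if mf != 1.0:
            summ = ExposureSummary(
                cauc=summ.cauc * mf,
                per_dose_auc=tuple(a * mf for a in summ.per_dose_auc),
                method=summ.method,
            )
        return summ

    def recommend_dose(self, target_cauc: float, n_days: int = 4) -> DoseRecommendation:
        """Daily dose hitting the target cAUC under the MAP clearance."""
        return model_based_dose(
            self.model.population, self.model.subject, target_cauc, n_days, eta=self.eta
        )

    def summary(self, target_cauc: Optional[float] = None) -> str:
        """Plain-text summary table of the fit."""
        s = self.model.subject
        exp = self.cumulative_auc()
        lines = [
            "Fludarabine individual PK (MAP) results",
            "=" * 55,
            f"subject: {s.id}   age {s.age:.2f} y   sex {s.sex}   "
            f"wt {s.weight:.1f} kg   ht {s.height:.1f} cm",
            f"FFM {s.fat_free_mass():.2f} kg   "
            f"CrCL (capped) {s.creatinine_clearance(self.model.population.crcl_cap):.1f} "
            "mL/min/1.73m2",
            f"observations used: {self.n_obs_used}   BLQ excluded: {self.n_blq_excluded}",
            f"converged: {self.converged}   objective: {self.objective:.4f}",
            "-" * 55,
            f"{'':14s}{'estimate':>12s}{'approx. SE':>12s}",
            f"{'eta_CL':14s}{self.eta[0]:>12.4f}{self.eta_se[0]:>12.4f}",
            f"{'eta_Vc':14s}{self.eta[1]:>12.4f}{self.eta_se[1]:>12.4f}",
            "-" * 55,
            f"CL {self.params.cl:.3f} L/h   Vc {self.params.vc:.2f} L   "
            f"Q {self.params.q:.3f} L/h   Vp {self.params.vp:.2f} L",
            f"predicted cAUC under administered regimen: {exp.cauc:.2f} mg*h/L",
        ]
        if target_cauc:
            rec = self.recommend_dose(target_cauc)
            lines.append(
                f"dose to reach {target_cauc:g} mg*h/L over {rec.n_days} days: "
                f"{rec.daily_dose:.1f} mg/day"
            )
        return "\n".join(lines)
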