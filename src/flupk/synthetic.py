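"""Virtual cohorts and sparse PK datasets with the study's statistical structure.

The cohort generator emulates a pediatric-through-young-adult HCT population
(median age ~8 y including infants, median weight ~24 kg, supra-normal
creatinine clearance typical of conditioning patients) using a parametric
growth model: piecewise-linear median height and median BMI as functions of
age with a sex offset and log-normal spread, plus an age-typical log-normal
serum-creatinine model. This is a deliberate stand-in for CDC LMS growth
tables so the package stays download-free; `height_median`/`bmi_median`
hooks accept user-supplied curves.

The sparse sampling design mirrors the study: two draws per subject, the
first 0-2 h and the second 2-24 h after the end of an infusion (by default
the final one), corrupted by the configured residual-error model and
flagged below the 2 ng/mL LLOQ.

Datasets are NONMEM-style longitudinal tables with the exact header
ID,TIME,EVID,AMT,DUR,DV,MDV,BLQ,AGE,SEX,WT,HT,SCR (TIME h, AMT mg, DV
ng/mL, missing DV coded '.').
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .covariates import Subject
from .errors import ConfigError, DatasetError, ValidationError
from .pk import (
    DoseEvent,
    DoseRegimen,
    PopulationModel,
    concentration_profile,
    individual_parameters,
)

__all__ = [
    "CohortSpec",
    "SparseDesign",
    "generate_cohort",
    "generate_sparse_dataset",
    "read_dataset",
    "write_dataset",
    "subjects_from_dataset",
    "SubjectRecord",
    "model_based_regimen",
    "bsa_regimen",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "DUR", "DV", "MDV", "BLQ",
    "AGE", "SEX", "WT", "HT", "SCR",
]

STRATA = ("reference", "age_lt_2", "bmi_gt_30")

# median growth curves: knots in age (y)
_AGE_KNOTS = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 15.0, 18.0, 25.0])
_HT_KNOTS = np.array([50.0, 67.0, 75.0, 86.5, 95.0, 109.0, 122.0, 149.0, 163.0, 169.0, 170.0])
_BMI_KNOTS = np.array([13.3, 16.8, 17.3, 16.4, 15.8, 15.4, 15.9, 17.8, 20.0, 21.8, 23.0])
_SCR_AGE = np.array([0.0, 1.0, 2.0, 5.0, 8.0, 12.0, 16.0, 25.0])
_SCR_KNOTS = np.array([0.25, 0.27, 0.28, 0.31, 0.33, 0.45, 0.59, 0.72])


def height_median(age, sex) -> np.ndarray:
    """Median height (cm) at age; sex offset grows toward +-6 cm by age 16."""
    age = np.asarray(age, dtype=float)
    base = np.interp(age, _AGE_KNOTS, _HT_KNOTS)
    off = 6.0 * np.minimum(age / 16.0, 1.0)
    sgn = np.where(np.asarray(sex) == "male", 1.0, -1.0)
    return base + sgn * off


def bmi_median(age) -> np.ndarray:
    """Median body-mass index (kg/m2) at age."""
    return np.interp(np.asarray(age, dtype=float), _AGE_KNOTS, _BMI_KNOTS)


def scr_median(age) -> np.ndarray:
    """Age-typical median serum creatinine (mg/dL) for conditioning patients."""
    return np.interp(np.asarray(age, dtype=float), _SCR_AGE, _SCR_KNOTS)


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a virtual cohort.

    Default (reference) ages mix 13% infants/toddlers Uniform(0.4, 2) with a
    scaled Beta bulk over 2-22 y, giving a median near 8 y. ``age_lt_2``
    draws Uniform(0.25, 2); ``bmi_gt_30`` draws adolescent/young-adult ages
    with BMI Uniform(30.5, 42).
    """

    n: int
    stratum: str = "reference"
    seed: object = 0
    p_male: float = 0.5
    infant_fraction: float = 0.13
    age_range: Tuple[float, float] = (0.4, 22.0)
    sd_log_height: float = 0.04
    sd_log_bmi: float = 0.17
    sd_log_scr: float = 0.22

    def __post_init__(self):
        if not (self.n > 0):
            raise ConfigError(f"cohort size must be positive, got {self.n!r}")
        if self.stratum not in STRATA:
            raise ConfigError(f"unknown stratum {self.stratum!r}; choose from {STRATA}")
        if not (0.0 <= self.p_male <= 1.0):
            raise ConfigError("p_male must be in [0, 1]")


def generate_cohort(spec: CohortSpec) -> List[Subject]:
    """Draw a deterministic (per seed) cohort of validated subjects."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sex = np.where(rng.random(n) < spec.p_male, "male", "female")

    if spec.stratum == "age_lt_2":
        age = rng.uniform(0.25, 2.0, n)
    elif spec.stratum == "bmi_gt_30":
        age = rng.uniform(14.0, 22.0, n)
    else:
        lo, hi = spec.age_range
        is_infant = rng.random(n) < spec.infant_fraction
        age_inf = rng.uniform(max(lo, 0.25), 2.0, n)
        age_bulk = 2.0 + (hi - 2.0) * rng.beta(1.4, 2.6, n)
        age = np.where(is_infant, age_inf, age_bulk)

    height = height_median(age, sex) * np.exp(rng.normal(0.0, spec.sd_log_height, n))
    if spec.stratum == "bmi_gt_30":
        bmi = rng.uniform(30.5, 42.0, n)
    else:
        bmi = bmi_median(age) * np.exp(rng.normal(0.0, spec.sd_log_bmi, n))
    weight = bmi * (height / 100.0) ** 2
    scr = scr_median(age) * np.exp(rng.normal(0.0, spec.sd_log_scr, n))

    return [
        Subject(
            id=f"S{i + 1:04d}",
            age=float(age[i]),
            sex=str(sex[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            serum_creatinine=float(scr[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class SparseDesign:
    """Two post-infusion draws per subject inside the study's windows (h)."""

    window1: Tuple[float, float] = (0.0, 2.0)
    window2: Tuple[float, float] = (2.0, 24.0)
    after: str = "final_dose"  # or 'first_dose'

    def __post_init__(self):
        for w in (self.window1, self.window2):
            if not (0.0 <= w[0] < w[1]):
                raise ConfigError(f"invalid sampling window {w!r}")
        if self.after not in ("final_dose", "first_dose"):
            raise ConfigError(f"unknown sampling-day rule {self.after!r}")


def model_based_regimen(
    model: PopulationModel,
    target_cauc: float = 20.0,
    n_days: int = 4,
    duration: float = 1.0,
) -> Callable[[Subject], DoseRegimen]:
    """Regimen rule: dose from the typical model clearance to a cAUC target."""

    def rule(subject: Subject) -> DoseRegimen:
        cl = individual_parameters(model, subject, (0.0, 0.0)).cl
        return DoseRegimen.daily(target_cauc * cl / n_days, n_days, duration)

    return rule


def bsa_regimen(
    rate_mg_m2: float = 40.0,
    n_days: int = 4,
    duration: float = 1.0,
) -> Callable[[Subject], DoseRegimen]:
    """Regimen rule: fixed mg/m2 daily dosing."""

    def rule(subject: Subject) -> DoseRegimen:
        return DoseRegimen.daily(rate_mg_m2 * subject.bsa(), n_days, duration)

    return rule


def generate_sparse_dataset(
    model: PopulationModel,
    cohort: Sequence[Subject],
    regimen_rule: Optional[Callable[[Subject], DoseRegimen]] = None,
    design: SparseDesign = SparseDesign(),
    seed: object = 0,
    true_eta_out: bool = False,
):
    """Simulate the sparse study design over a cohort.

    Returns a NONMEM-style DataFrame (and, with ``true_eta_out``, a truth
    table of each subject's eta, clearance and noise-free cAUC for recovery
    tests). Per subject: dose events from ``regimen_rule`` (default:
    model-based dosing to 20 mg*h/L over 4 days), eta drawn from Omega, two
    observation times drawn uniformly inside the design windows after the
    anchoring infusion ends, concentrations corrupted by the configured
    residual model and flagged below the LLOQ.
    """
    if regimen_rule is None:
        regimen_rule = model_based_regimen(model)
    rng = np.random.default_rng(seed)
    omega = model.omega_matrix()
    rows = []
    truth = []
    for subj in cohort:
        regimen = regimen_rule(subj)
        eta = rng.multivariate_normal((0.0, 0.0), omega)
        params = individual_parameters(model, subj, eta)
        anchor_ev = regimen.events[-1] if design.after == "final_dose" else regimen.events[0]
        anchor = anchor_ev.end
        t_obs = np.array(
            [
                anchor + rng.uniform(*design.window1),
                anchor + rng.uniform(*design.window2),
            ]
        )
        conc = model.molar_factor * concentration_profile(params, regimen, t_obs)
        if model.sigma > 0:
            if model.residual_model == "lognormal":
                dv_mg_l = conc * np.exp(rng.normal(0.0, model.sigma, 2))
            else:
                dv_mg_l = np.maximum(conc + rng.normal(0.0, model.sigma, 2), 0.0)
        else:
            dv_mg_l = conc
        dv_ng_ml = dv_mg_l * 1000.0
        cov = dict(
            AGE=subj.age,
            SEX=0 if subj.sex == "male" else 1,
            WT=subj.weight,
            HT=subj.height,
            SCR=subj.serum_creatinine,
        )
        for ev in regimen.events:
            rows.append(
                dict(
                    ID=subj.id, TIME=ev.start, EVID=1, AMT=ev.amount, DUR=ev.duration,
                    DV=np.nan, MDV=1, BLQ=0, **cov,
                )
            )
        for t, dv in zip(t_obs, dv_ng_ml):
            rows.append(
                dict(
                    ID=subj.id, TIME=float(t), EVID=0, AMT=0.0, DUR=0.0,
                    DV=float(dv), MDV=0, BLQ=int(dv < model.lloq_ng_ml), **cov,
                )
            )
        if true_eta_out:
            truth.append(
                dict(
                    ID=subj.id,
                    ETA_CL=float(eta[0]),
                    ETA_VC=float(eta[1]),
                    CL=params.cl,
                    CAUC=model.molar_factor * regimen.total_dose / params.cl,
                )
            )
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    if true_eta_out:
        return df, pd.DataFrame(truth)
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset CSV; missing DV is coded '.' with MDV=1."""
    _validate_columns(df)
    out = df.copy()
    out["DV"] = out["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and strictly validate a dataset CSV (see DATASET_COLUMNS)."""
    df = pd.read_csv(path, dtype={"ID": str}, na_values=["."], keep_default_na=True)
    _validate_columns(df)
    for col in ("TIME", "AMT", "DUR", "DV", "WT", "HT", "SCR", "AGE"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("EVID", "MDV", "BLQ", "SEX"):
        df[col] = df[col].astype(int)
    if (df["TIME"] < 0).any():
        bad = df.index[df["TIME"] < 0].tolist()[:5]
        raise DatasetError(f"negative TIME values at rows {bad}")
    if ((df["MDV"] == 0) & df["DV"].isna()).any():
        raise DatasetError("rows with MDV=0 must carry a numeric DV")
    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetError(f"TIME not non-decreasing within subject {sid!r}")
    return df


def _validate_columns(df: pd.DataFrame) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in DATASET_COLUMNS]
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"missing required columns: {missing}")
        if extra:
            msg.append(f"unexpected columns: {extra}")
        raise DatasetError("; ".join(msg))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's parsed dataset slice: covariates, doses, observations."""

    subject: Subject
    regimen: DoseRegimen
    obs_times: np.ndarray  # h
    obs_ng_ml: np.ndarray
    blq: np.ndarray


def subjects_from_dataset(df: pd.DataFrame) -> List[SubjectRecord]:
    """Split a validated dataset into per-subject records."""
    _validate_columns(df)
    records = []
    for sid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        subj = Subject(
            id=str(sid),
            age=float(first["AGE"]),
            sex=int(first["SEX"]),
            weight=float(first["WT"]),
            height=float(first["HT"]),
            serum_creatinine=float(first["SCR"]),
        )
        doses = grp[grp["EVID"] == 1]
        if doses.empty:
            raise DatasetError(f"subject {sid!r} has no dose events")
        regimen = DoseRegimen(
            tuple(
                DoseEvent(float(r["AMT"]), float(r["TIME"]), float(r["DUR"]))
                for _, r in doses.iterrows()
            )
        )
        obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
        records.append(
            SubjectRecord(
                subject=subj,
                regimen=regimen,
                obs_times=obs["TIME"].to_numpy(dtype=float),
                obs_ng_ml=obs["DV"].to_numpy(dtype=float),
                blq=obs["BLQ"].to_numpy(dtype=bool),
            )
        )
    return records
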