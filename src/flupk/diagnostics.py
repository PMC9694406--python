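"""Model-evaluation metrics and plots-as-data.

Percent error is the signed mean relative error of predictions,
PE = (100/n) * sum((pred - obs)/obs); an absolute variant is provided under
a distinct name. Variance comparisons use Levene's test (one-way ANOVA on
absolute deviations from the group mean; median-centred Brown-Forsythe via
``center='median'``). The prediction-corrected VPC normalises observations
by the typical-subject prediction (pcY = Y * median(PRED in bin) / PRED)
and compares observed percentiles to envelopes of percentiles simulated
from the model with interindividual variability and residual error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DatasetError, ValidationError
from .pk import (
    NG_PER_ML_TO_MG_PER_L,
    DoseRegimen,
    PopulationModel,
    concentration_profile,
    individual_parameters,
)
from .synthetic import SubjectRecord, subjects_from_dataset

__all__ = [
    "percent_error",
    "absolute_percent_error",
    "levene_test",
    "pc_vpc",
    "VPCResult",
    "time_after_dose",
    "DEFAULT_VPC_BINS",
]

#: bin edges (h after end of infusion) matching the sparse design's windows
DEFAULT_VPC_BINS = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0)


def percent_error(predictions: Sequence[float], observations: Sequence[float]) -> float:
    """Signed mean relative error in percent: (100/n) sum((pred-obs)/obs)."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValidationError(
            f"predictions and observations must be equal-length 1-d sequences, "
            f"got shapes {pred.shape} and {obs.shape}"
        )
    if pred.size == 0:
        raise ValidationError("percent_error needs at least one pair")
    zeros = np.flatnonzero(obs == 0)
    if zeros.size:
        raise ValidationError(f"observation is zero at index {int(zeros[0])}")
    return float(100.0 * np.mean((pred - obs) / obs))


def absolute_percent_error(predictions, observations) -> float:
    """Mean absolute relative error in percent."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size == 0:
        raise ValidationError("predictions and observations must be equal-length 1-d sequences")
    zeros = np.flatnonzero(obs == 0)
    if zeros.size:
        raise ValidationError(f"observation is zero at index {int(zeros[0])}")
    return float(100.0 * np.mean(np.abs((pred - obs) / obs)))


def levene_test(groups: Sequence[Sequence[float]], center: str = "mean") -> Tuple[float, float]:
    """Levene's test for equality of variances across >=2 groups.

    One-way ANOVA on absolute deviations from each group's mean (classic
    Levene) or median (Brown-Forsythe). Returns (statistic, p_value).
    """
    if len(groups) < 2:
        raise ValidationError("levene_test needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if a.ndim != 1 or a.size < 2:
            raise ValidationError(f"group {i} is degenerate (need >= 2 values per group)")
    if center not in ("mean", "median"):
        raise ValidationError(f"center must be 'mean' or 'median', got {center!r}")
    centers = [np.mean(a) if center == "mean" else np.median(a) for a in arrays]
    if all(np.allclose(a, c) for a, c in zip(arrays, centers)):
        raise ValidationError("all groups are constant; variance comparison is degenerate")
    stat, p = stats.levene(*arrays, center=center)
    # identical (or proportionally identical-deviation) groups: 0/0 -> define as no evidence
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    return float(stat), float(p)


def time_after_dose(times: np.ndarray, regimen: DoseRegimen) -> np.ndarray:
    """Hours after the end of the most recent infusion started at or before t.

    Samples drawn during an infusion map to 0 (start of the first bin).
    """
    t = np.asarray(times, dtype=float)
    starts = np.array([e.start for e in regimen.events])
    ends = np.array([e.end for e in regimen.events])
    idx = np.searchsorted(starts, t, side="right") - 1
    if np.any(idx < 0):
        raise DatasetError("observation precedes the first dose")
    return np.maximum(t - ends[idx], 0.0)


@dataclass(frozen=True)
class VPCResult:
    """Prediction-corrected VPC summaries, ready for any plotting layer.

    ``observed`` has shape (n_bins, n_percentiles); ``sim_lower``/``sim_upper``
    bound the simulated envelope of each percentile per bin.
    """

    bin_edges: Tuple[float, ...]
    percentiles: Tuple[float, ...]
    observed: np.ndarray
    sim_lower: np.ndarray
    sim_upper: np.ndarray
    n_replicates: int
    bin_counts: Tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (bin, percentile)."""
        rows = []
        for b in range(len(self.bin_edges) - 1):
            for j, q in enumerate(self.percentiles):
                rows.append(
                    {
                        "bin_left": self.bin_edges[b],
                        "bin_right": self.bin_edges[b + 1],
                        "n_obs": self.bin_counts[b],
                        "percentile": q,
                        "observed": self.observed[b, j],
                        "sim_lower": self.sim_lower[b, j],
                        "sim_upper": self.sim_upper[b, j],
                    }
                )
        return pd.DataFrame(rows)

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells whose observed value falls
        inside the simulated envelope."""
        inside = (self.observed >= self.sim_lower) & (self.observed <= self.sim_upper)
        return float(np.mean(inside))


def _bin_index(tad: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.digitize(tad, edges[1:-1], right=False)
    return np.clip(idx, 0, len(edges) - 2)


def pc_vpc(
    model: PopulationModel,
    dataset: pd.DataFrame,
    n_replicates: int = 500,
    bin_edges: Sequence[float] = DEFAULT_VPC_BINS,
    seed: object = 0,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
    envelope: Tuple[float, float] = (2.5, 97.5),
) -> VPCResult:
    """Prediction-corrected visual predictive check of a dataset.

    Observations (ng/mL) are pooled across days on a time-after-dose axis,
    corrected by the typical prediction, and summarised per bin; simulated
    replicates use the same subjects, regimens and sampling times with eta
    drawn from Omega and residual error applied per the model.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError(f"bin_edges must be strictly increasing, got {bin_edges!r}")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    records = subjects_from_dataset(dataset)
    records = [r for r in records if r.obs_times.size]
    if not records:
        raise DatasetError("dataset contains no quantified observations")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        tads, preds, ys = [], [], []
        for rec in records:
            p_typ = individual_parameters(model, rec.subject, (0.0, 0.0))
            pred = model.molar_factor * concentration_profile(p_typ, rec.regimen, rec.obs_times)
            tads.append(time_after_dose(rec.obs_times, rec.regimen))
            preds.append(pred)
            ys.append(rec.obs_ng_ml * NG_PER_ML_TO_MG_PER_L)
        tad = np.concatenate(tads)
        pred = np.concatenate(preds)
        y = np.concatenate(ys)

        bins = _bin_index(tad, edges)
        n_bins = len(edges) - 1
        counts = np.bincount(bins, minlength=n_bins)
        empty = [
            (float(edges[b]), float(edges[b + 1])) for b in range(n_bins) if counts[b] == 0
        ]
        if empty:
            raise DatasetError(f"empty VPC bins for edges {empty}; adjust bin_edges")

        med_pred = np.array([np.median(pred[bins == b]) for b in range(n_bins)])
        factor = med_pred[bins] / np.maximum(pred, 1e-12)
        pcy = y * factor

        q = np.asarray(percentiles, dtype=float)
        observed = np.vstack(
            [np.percentile(pcy[bins == b], q) for b in range(n_bins)]
        )

        rng = np.random.default_rng(seed)
        omega = model.omega_matrix()
        sim_stats = np.empty((n_replicates, n_bins, q.size))
        for r in range(n_replicates):
            sim_y = np.empty_like(y)
            pos = 0
            for rec, pr in zip(records, preds):
                k = rec.obs_times.size
                eta = rng.multivariate_normal((0.0, 0.0), omega)
                p_ind = individual_parameters(model, rec.subject, eta)
                c = model.molar_factor * concentration_profile(
                    p_ind, rec.regimen, rec.obs_times
                )
                if model.sigma > 0:
                    if model.residual_model == "lognormal":
                        c = c * np.exp(rng.normal(0.0, model.sigma, k))
                    else:
                        c = np.maximum(c + rng.normal(0.0, model.sigma, k), 0.0)
                sim_y[pos : pos + k] = c
                pos += k
            sim_pc = sim_y * factor
            for b in range(n_bins):
                sim_stats[r, b] = np.percentile(sim_pc[bins == b], q)

    lo, hi = envelope
    sim_lower = np.percentile(sim_stats, lo, axis=0)
    sim_upper = np.percentile(sim_stats, hi, axis=0)
    return VPCResult(
        bin_edges=tuple(float(e) for e in edges),
        percentiles=tuple(float(x) for x in q),
        observed=observed,
        sim_lower=sim_lower,
        sim_upper=sim_upper,
        n_replicates=int(n_replicates),
        bin_counts=tuple(int(c) for c in counts),
    )
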