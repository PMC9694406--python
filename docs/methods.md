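# Methods

## Model

f-ara-a disposition is a linear two-compartment model with zero-order IV
infusion input. Central-compartment concentrations are evaluated by the
biexponential closed form (macro-constants from k10 = CL/Vc, k12 = Q/Vc,
k21 = Q/Vp) with superposition over dose events; an independent
`scipy.integrate.solve_ivp` oracle (piecewise integration between infusion
boundaries, rtol 1e-11) exists solely to cross-check the closed form and
the mass balance in tests.

Individual clearance:

    CL_i = CL_pop · (1 − e^{−age·θ}) · (FFM/12)^0.75 · [1 + (CrCL−100)·CrCL_eff] · e^{η_CL}

with θ = 3.54 y⁻¹ and CrCL_eff = 0.00186 per mL/min/1.73 m². Volumes scale
linearly in FFM/12 kg (Vc 11.5 L, Vp 8.48 L at reference), intercompartmental
clearance allometrically (Q 1.47 L/h · (FFM/12)^0.75). Exponents 0.75 on
clearances and 1.0 on volumes are the standard allometric convention; the
"per 12 kg of FFM" units of the published volume estimates fix the linear
scaling.

Assumptions: linear (non-saturable) plasma PK, so cAUC = total dose / CL
exactly; no inter-occasion variability (clearance is treated as constant
across the 3–5 dosing days, consistent with the consistency of f-ara-a
clearance across a course); no IIV on Q or Vp (none is reported); the
intracellular (f-ara-ATP) compartment is out of scope.

## Parameters and their provenance

| parameter | value | units | note |
|---|---|---|---|
| CL_pop | **required** | L/h per 12 kg FFM | not in the published estimate set; no silent default |
| Vc | 11.5 | L per 12 kg FFM | published estimate |
| Q | 1.47 | L/h per 12 kg FFM | published estimate |
| Vp | 8.48 | L per 12 kg FFM | published estimate |
| θ (maturation) | 3.54 | 1/y | published estimate; warn below 5 months |
| CrCL_eff | 0.00186 | per mL/min/1.73 m² | published estimate |
| Ω | [[0.117, 0.141], [0.141, 0.303]] | log-scale var/cov | see below |
| σ | 0.36 | log-concentration SD | see below |
| CrCL cap | 150 | mL/min/1.73 m² | applied before model use |
| LLOQ | 2 | ng/mL | assay lower limit (range 2–800) |

**Ω reading.** The published table labels 0.117/0.303 "%CV" and 0.141
"correlation", but the magnitudes are only coherent as log-normal variances
(≈35% and ≈58% apparent CV) with 0.141 their covariance (correlation
≈0.75) — the conventional OMEGA-block reading, and the one consistent with
the spread of the published simulated exposure ranges. The alternative
correlation reading is available via `omega_cl_vc_is_correlation=True`.

**Residual scale.** An additive SD of 0.36 ng/mL is implausible against a
2–800 ng/mL assay; the default residual model is additive on the natural-log
concentration scale with σ = 0.36 (≈36% CV), switchable to
additive-in-concentration (σ then in mg/L).

**CL_pop fixture (3.0 L/h per 12 kg FFM).** All simulations and tests in
this package use CL_pop = 3.0, chosen once on plausibility grounds: it
implies ≈9.4 L/h for a 55-kg-FFM adult (within the range reported for
f-ara-a in adults) and makes conventional 40 mg/m²×4 dosing overshoot a
20 mg·h/L target (cAUC ≈ 29–33 in adults/adolescents), reproducing the
well-documented overshoot of traditional fludarabine dosing. Under
model-based dosing the choice provably cancels: the dose is
target·CL_typ/n_days and the attained cAUC is target·e^{−η_CL}, so
medians and target-attainment statistics are CL_pop-invariant (asserted in
tests). The variance comparison against fixed mg/m² dosing does depend on
CL_pop through the traditional arm's mean exposure, which is why a
realistic value matters there.

**Unit conventions.** Internal concentrations are mg/L; dataset DV is
ng/mL, converted by the exact factor 0.001. Dose amounts enter the model
directly; an optional molar conversion (fludarabine phosphate → f-ara-a,
≈0.781) is available as `molar_factor` and defaults to 1.0. Default
infusion duration is 1.0 h (configurable per event).

## Covariates

- FFM: Al-Sallami sex-specific sigmoid × adult FFM hyperbola, applied from
  3 to 18 y; below 3 y total body weight is used (no referenced infant FFM
  equation exists), at ≥18 y the plain adult formula. FFM is clamped to
  body weight. The age cutoffs are configurable.
- CrCL: bedside Schwartz (0.413·height/SCr) up to the 18th birthday
  (continuity with the pediatric cohort), BSA-indexed Cockcroft–Gault
  (×1.73/BSA, Mosteller) at ≥18 y, then capped at 150.
- BSA: Mosteller by default (ubiquitous in pediatric HCT), DuBois optional.
- The renal multiplier 1 + (CrCL−100)·eff is floored at 0.01: the published
  linear form is unguarded and would go non-positive near CrCL ≈ −438, or
  for large pathological effect sizes.

## MAP estimation

Objective: Σ r_j²/σ² + ηᵀΩ⁻¹η with residuals on the configured error scale
(log-concentration by default); posterior mode by Nelder–Mead from the
fixed start grid {0, ±0.5 per axis}, best objective wins with lexicographic
eta tie-break — deterministic with no random state. BLQ observations are
excluded from the objective (and counted in the output): the sparse design
draws only two samples and the study used only quantifiable concentrations.
With no usable observations the prior mode (η = 0) is returned. Approximate
posterior SEs come from the finite-difference curvature of the objective at
the mode (covariance 2H⁻¹, since the objective is −2·log-posterior up to a
constant).

Because the prior always shrinks the mode, "recovery of truth" is only
expected when the residual weight matches the data: the recovery tests fit
noise-free simulated profiles with σ = 0.05 (consistent with their
generating process), while sparse-data tests use the full σ = 0.36 and
assert rank-order recovery (ρ > 0.7) rather than pointwise accuracy.

Mid-course re-estimation (updating later doses from day-1 levels) is
possible by refitting with a truncated regimen but is not automated: target
exposures are attainable from the initial model-based estimate.

## Virtual trials

Each arm: generate a cohort (seeded), compute each subject's typical CL,
size 4 daily doses by the strategy (model-based to a 20 mg·h/L target, or
mg/m² / mg/kg rules), draw η from Ω, and predict cAUC = total dose /
(CL_typ·e^{η_CL}) in closed form. IIV is ON in the prediction by default —
the published simulated ranges (e.g. 17.1–32.0 around a 20.3 median) are
impossible for a purely typical prediction, which would be degenerate at
the target — while residual (assay) error is OFF: it describes measurement,
not exposure. Arms sharing a seed share patients and η draws, so strategy
comparisons are paired. Variance comparisons use Levene's test
(mean-centred; Brown–Forsythe optional).

## Synthetic cohorts

The generator emulates the study population: ages mixing 13%
infants/toddlers (0.4–2 y) with a Beta-distributed bulk over 2–22 y (median
≈8 y); piecewise-linear median height and BMI curves of age with a growing
sex offset and log-normal spread (median weight ≈24 kg at the median age);
age-typical serum creatinine with log-normal spread calibrated so median
CrCL ≈ 135–140 mL/min/1.73 m² (HCT conditioning patients typically
hyperfilter). Strata: `age_lt_2` (uniform 0.25–2 y) and `bmi_gt_30`
(adolescent/young-adult ages, BMI uniform 30.5–42). This parametric growth
model is an intentional stand-in for CDC LMS tables (keeping the package
download-free): it reproduces medians and plausible spread, not LMS
skewness, percentile crossings, or secular trends — so passing tests
demonstrate pipeline correctness under realistic heterogeneity, not
calibration to any real registry.

The sparse design draws one sample 0–2 h and one 2–24 h after the end of
the final infusion (sampling day configurable), jittered uniformly within
each window, corrupts them with the residual model, and flags DV < 2 ng/mL
as BLQ. Datasets are NONMEM-style CSVs
(ID,TIME,EVID,AMT,DUR,DV,MDV,BLQ,AGE,SEX,WT,HT,SCR; missing DV coded ".").

## Diagnostics

Percent error is the signed mean relative error, 100/n·Σ(pred−obs)/obs (an
absolute-value variant exists under a distinct name). The pcVPC pools
observations on a time-after-end-of-infusion axis (default bins 0–1, 1–2,
2–4, 4–8, 8–24 h, matching the sparse windows; samples drawn mid-infusion
map to 0), corrects by pcY = Y·median(PRED in bin)/PRED with PRED the
typical prediction, and compares observed 5th/50th/95th percentiles to
2.5–97.5% envelopes of the same statistics over seeded replicates simulated
with IIV and residual error.

## Numerical choices and problem sizes

- Closed form vs ODE agreement asserted at 1e-6 relative with a 1e-12 mg/L
  absolute floor (profile tails decay below float noise).
- Trapezoid cAUC: 0.02-h grid to end-of-dosing + 10 terminal half-lives
  (≤0.5% of the exact dose/CL identity).
- Repeated disposition eigenvalues (a measure-zero configuration) raise an
  explicit error rather than switching to the confluent form.
- Virtual trials use 1000 subjects per arm (the published simulation size);
  strategy-comparison tests use 200/arm and the pcVPC self-consistency
  check 53 subjects × 500 replicates, sizes at which every assertion holds
  with wide margin while the whole suite runs in well under a minute of
  compute per module.
- Dose amounts are not rounded by default (`round_mg=True` opts in).

## Limitations

- CL_pop must come from the user (or the documented fixture); absolute
  concentration predictions are only as good as that value.
- The maturation function is extrapolated below 5 months (warned).
- The FFM fallback below 3 y (total body weight) and the Schwartz cutoff at
  the 18th birthday are pragmatic decisions where no equation is specified.
- BLQ data are excluded, not modelled (M3-style likelihood not implemented).
- The generator's growth and creatinine curves are parametric
  approximations; real-data covariate joint structure (e.g. obesity-renal
  interactions) is not represented.
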