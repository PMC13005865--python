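# Methods

## Scope and shape

hepaflux is a library: the importable API plus the narrative scripts in
`examples/` are the interface. The pipeline is meant to be driven from
Python (or the two maintenance scripts in `scripts/`); no shell
command-line tool is provided because none of its operations are
one-shot shell tasks.

Time is measured in minutes from T0, the start of tracer ingestion.
Blood channels live on the grid T−60, T0, T10, T20, T30, T60, T90, T120,
T150, T180; glucagon on the subset T0, T10, T30, T60, T120, T180; the MR
channels (hepatic D-Glc voxel amplitudes, glycogen amplitudes) on a
10-min grid from 0 to 180 min. The MR grid extends to 180 min — beyond a
150-min acquisition window — so that the conventional 0–180 min
incremental AUC of the imaging channels is computable on the generated
data; this is a deliberate idealisation of the generator.

## Model structure

### Gastrointestinal absorption

A single liquid stomach compartment (the meal is a glucose drink, so no
solid-phase grinding compartment) empties with a glucose-mass-dependent
rate

k_empt(q) = k_min + (k_max−k_min)/2 · [tanh(α(q − b·D)) − tanh(β(q − c·D)) + 2],
α = 5/(2D(1−b)), β = 5/(2Dc),

into a gut compartment absorbing at k_abs; Ra = f_bio·k_abs·q_gut/BW.
Emptying starts near k_max, slows towards k_min once less than the
fraction b of the dose remains, and recovers below the fraction c. The
break-points default to b = 0.9, c = 0.5: a short initial fast phase, a
long slow mid-phase, late recovery. This shape (rather than the
fast–slow–fast symmetric default of the model family) is what lets a
single liquid compartment reproduce a late tracer appearance peak
together with an early total-glucose peak; generator and estimator share
it, and it is held fixed during fitting (only k_max, k_min, k_abs are
estimated). f_bio is fixed at 0.90.

### Oral minimal model

Equations as in the README. Conventions and fixing rules:

* GEZI_D — disposal glucose effectiveness at zero insulin, fixed to the
  population value 0.015 min⁻¹ (gives basal production EGP_b =
  GEZI_D·G_b·V ≈ 0.011 mmol kg⁻¹ min⁻¹ ≈ 2 mg kg⁻¹ min⁻¹ at G_b =
  5.2 mmol/l, the textbook fasting EGP). In type 1 diabetes it is scaled
  by 0.5; both numbers are config values (`gezi_disposal_healthy`,
  `gezi_t1d_scale`), not estimates.
* GE_P — production glucose effectiveness, expressed as fractional
  suppression per mmol/l so the type-1-diabetes rule "fix to zero" drops
  one term cleanly. The EGP form is the multiplicative-suppression
  variant EGP_b·max(0, 1 − GE_P·(G−G_b) − X_P); it is isolated in one
  place (`simulate_omm`) so alternates can be swapped.
* The glucose distribution volume V is fixed at 0.145 l/kg (config);
  estimating it per subject is possible in principle but not enabled.
* Basal flux balance EGP_b = GEZI_D·G_b·V is enforced by construction
  (EGP_b is a derived property, never a free parameter).
* Insulin input: linear interpolation between samples, constant
  extrapolation outside. Healthy subjects use the measured insulin
  directly; the diabetes arm uses the composite active profile
  reconstructed from the fitted subcutaneous model plus the active
  fraction of the basal analogue.
* EGP is floored at zero; trajectories record whether the floor was hit.
  With degenerate zero-effectiveness parameters (no basal flux) the
  over-basal ratios are defined as 1.

Derived metrics: EGP suppression over (t₀,t₁) is 1 minus the time
average of EGP/EGP_b (equivalently −iAUC/(t₁−t₀) with baseline 1);
disposal increase is the mirror image; T₅₀GR is the first 0.5-crossing
of gastric retention by linear interpolation on the dense (0.5 min)
solver grid, independent of the reporting grid; GE_Disposal is reported
as GEZI_D + SI_D·I_b (effectiveness at basal insulin — a derived
quantity, distinct from the GEZI that enters the dynamics).

### Subcutaneous insulin

Two-compartment depot with dual absorption routes (q₁ →[k_a1] plasma,
q₁ →[k_d] q₂ →[k_a2] plasma), linear elimination k_e, volume V_I,
bioavailability F; 1 U = 6000 pmol. The system is linear with constant
coefficients, so trajectories are evaluated exactly by per-bolus
matrix-exponential impulse responses — there is no integration error in
this channel. Only F/V_I is identifiable from concentrations, so F stays
fixed (0.8) and V_I is estimated along with the four rates. Weighting is
proportional (6% CV) by default, with a constant-error switch.

### Tracer partition

Ratio semantics are tracer/tracee molar ratio (the GC-MS M+2/M+0
readout), hence exo = total·r′/(1+r′); a mole-percent-excess convention
is available behind `mole_percent_excess`. The natural-abundance
baseline is the measured mean pre-dose (t ≤ 0) ratio rather than a
theoretical constant, so the correction uses each subject's own
background. Negative corrected ratios (assay noise before tracer
arrival) clip to zero with a logged warning.

### MRS quantification

Deuterium: per-deuteron normalisation (2 labelled positions per glucose,
1 per mono-deuterated water) is applied before ratioing, with both
counts explicit config values; the water reference is the pre-ingestion
scan only (no time-varying water correction); voxels are quantified
individually and then averaged. Concentrations mean "mmol tracer
glucose per selected volume" — hepatocytes plus sinusoids, with no
vascular/hepatocellular decomposition. Glycogen: amplitude ratio to a
phantom times the phantom concentration times the product of four
multiplicative corrections (distance, loading, T₁, NOE).

### Cohort statistics

Pooled-variance Student t by default (Welch via a flag), two-sided,
α = 0.05, means ± SD with the t-based 95% CI of the difference; SEM =
SD/√n. No multiple-testing correction is applied — every contrast is
reported at face value, deliberately. Incremental AUCs use the trapezoid
rule on the measured grid with interpolated window endpoints; baseline
is the value at T0 for 0-anchored windows and at T−60 for the
whole-visit insulin window; insulin exposure windows are reported as
plain (non-incremental) AUCs, glucagon windows as T0-baselined iAUCs.
Peak/nadir searches exclude the fasting T−60 draw and break ties toward
the earlier time. Subgroup discovery: z-score the per-subject plasma and
hepatic D-Glc iAUC₀₋₁₈₀, Euclidean distance, Ward linkage, cut at k = 2,
relabel so cluster 1 has the larger plasma iAUC; the linkage and
standardisation choices are assumptions, exposed as arguments so their
sensitivity can be probed.

## The synthetic cohort

Three documented profiles — healthy, diabetes subgroup 1 (fast
emptying, steep tracer rise, net glycogen accumulation) and subgroup 2
(slow emptying, blunted tracer rise, net glycogen depletion) — define
the generator's defaults. The glucose channels are produced by the same
`simulate_omm` core the estimator fits, the fast-insulin channel by the
same depot model, so a noise-free subject is an exact realisation of the
fitted model (this is what makes parameter-recovery testing meaningful).
Channels the fitted model never consumes are descriptive parametric
curves: a log-normal-shaped endogenous insulin excursion (healthy; basal
43.4, peak 366 pmol/l at 81 min), a decline-and-partial-return glucagon
curve, a smoothstep glycogen ramp (onset 30 min, width 120 min), and a
first-order liver/plasma tracer exchange (k_in, k_out) for the hepatic
D-Glc channel.

Profile defaults were calibrated once, by `scripts/calibrate.py`, so the
noise-free forward simulation pushed through the package's own summary
operations attains the reference postprandial phenotypes the profiles
represent: basal/peak total glucose 5.2/7.5 mmol/l, exogenous peak
5.2 mmol/l, endogenous nadir 1.2 mmol/l and 63% three-hour EGP
suppression in health; half-emptying times 65.3/110.7 min and first-hour
suppression 0.26/0.11 across the subgroups; hepatic tracer peaks
3.0/6.1/2.7 mmol/l; glycogen iAUC₀₋₁₈₀ +2.4/+2.5/−3.0 mol/l·min. The
solved constants are frozen in `profiles._CAL` and are inputs to the
analysis, not outputs. The diabetes profiles share the healthy calibrated
SI_D (insulin-dependent disposal is similar across arms); their SI_P,
emptying scale, insulin volume and hepatic uptake are solved per
subgroup.

Measurement noise is multiplicative Gaussian truncated at zero with
per-channel CVs (glucose and enrichment 2%, insulin 6%, glucagon 10%,
DMI amplitudes 8%, glycogen 10%) — typical assay/MRS precisions, all
configurable. Between-subject variability is unit-mean lognormal on a
documented parameter set (basal glucose 8%, sensitivities 20%, emptying
and exchange rates 15%, glycogen amplitude 25%, insulin excursion 30%,
body weight 12%); gastric k_max and k_min scale together so the emptying
shape is preserved.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: assay drift and non-multiplicative error,
within-channel correlated noise, irregular or missed sampling, model
misspecification (real subjects do not follow the oral minimal model
exactly), meal-to-meal variability of absorption, glucagon physiology
(the generated curve is cosmetic), and the vascular vs hepatocellular
composition of the liver tracer signal. On that last point: the lumped
first-order exchange reproduces printed peak *values* but necessarily
peaks later than plasma tracer, whereas measured hepatic signal peaks
earlier (its portal/vascular component leads plasma); the decomposition
is out of scope here as it is methodologically unresolved. Two further
honest mismatches at the defaults: the diabetes profiles' three-hour
suppression (0.18/0.07) sits below roughly half the healthy value
because the post-bolus composite insulin declines across the window, and
the subgroup-2 exogenous peak (~9.4 mmol/l) exceeds the reference
phenotype (6.7) because the fixed GEZI scale bounds how far tracer
clearance can fall.

## Estimation and numerics

* Integration: `scipy.solve_ivp` (LSODA), rtol = atol = 1e−8 by default,
  dense 0.5-min output grid, integrating in two legs so the ingestion
  discontinuity at t = 0 falls on a boundary. The subcutaneous insulin
  channel is closed-form (matrix exponentials).
* Weights: proportional error, σ = CV·max(|y|, 0.2 mmol/l); the floor
  keeps the zero-enrichment pre-dose samples from dominating.
* The glucose-model objective is non-convex: the exogenous channel alone
  leaves an (SI_D, p₂) ridge, the endogenous channel has a curved
  (SI_P, p₂P) valley plus a dead zone where the EGP floor saturates and
  the production parameters lose all gradient. The fitter therefore works
  on log₁₀-scaled positive parameters and cycles: (1) absorption+disposal
  against the exogenous channel, multi-started over emptying-rate
  decades; (2) production against the endogenous channel, basin located
  by a deterministic coarse log-grid scan before local refinement;
  (3) joint Levenberg–Marquardt — repeating the cycle until the joint
  objective stalls, then polishing at rtol 1e−10 (finite-difference
  gradients need integration error well below the residual scale) with
  restarts until converged. On noise-free default subjects this recovers
  every free parameter to better than 1e−5 relative from generic
  population starting values.
* k_min ≤ k_max is enforced by fitting the ratio k_min/k_max ∈ (0, 1].
* Estimates within 0.1% of a bound are reported with an explicit
  warning (e.g. GE_P freed on diabetes-arm data pins at zero);
  non-convergence is recorded in the fit result, never silent.
* Asymptotic parameter CVs come from the Levenberg–Marquardt covariance;
  for log-scale parameters CV ≈ ln10·SE(log₁₀ θ).
* Degenerate inputs: t50 is None (undefined), not an error, when
  retention never reaches one half on the grid; a zero dose disables the
  meal sub-model (null-tracer datasets); identical subjects make a k-way
  cut impossible and raise; a silhouette is undefined for k = 1.

## Problem sizes

Defaults used by the test-suite and the acceptance script: single
subjects on the 10-point blood grid and 19-point MR grid; cohorts of
10–20 virtual subjects; 20 subjects for parameter-recovery checks; 200
replicates for noise-bias checks. These sizes were chosen to estimate
each quantity comfortably at desk scale.

## Known limitations

Beyond the generator caveats above: point weighted-least-squares
estimates only (no Bayesian posterior); no double-tracer flux
estimation; the MR channels enter as already-fitted peak amplitudes (no
spectral fitting, phasing or voxel selection); glucagon is never used by
the fitted model; and the healthy insulin input is the measured series
interpolated, so its accuracy is bounded by the blood-sampling density.
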