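# hepaflux

Postprandial hepatic and systemic glucose-flux analysis after an oral
dose of [6,6′-²H₂]-glucose (D-Glc), for investigators combining stable-
isotope tracer kinetics with liver magnetic-resonance readouts: deuterium
metabolic imaging (DMI) of hepatic tracer glucose and natural-abundance
¹³C-MRS of glycogen. The package covers the full analysis chain for a
mixed cohort of healthy participants and participants with type 1
diabetes on subcutaneous insulin, and ships a mechanistic synthetic-
cohort generator so every stage is testable end to end without access to
subject-level data.

## What it computes

**Tracer partition.** GC-MS reports the tracer/tracee molar ratio *r*;
after subtracting the pre-dose natural-abundance background and dividing
by tracer purity (99%), plasma glucose splits as

    G_exo = G_total · r′/(1 + r′),   G_endo = G_total − G_exo.

**Oral minimal model (single tracer).** Exogenous and endogenous glucose
are modelled separately, with insulin acting through remote compartments
on disposal (X) and production (X_P):

    Ẋ   = −p₂ (X − SI_D·(I − I_b))
    Ẋ_P = −p₂P (X_P − SI_P·(I − I_b))
    Ġ_exo  = −(GEZI_D + X)·G_exo + Ra(t)/V
    EGP(t) = EGP_b · max(0, 1 − GE_P·(G − G_b) − X_P)
    Ġ_endo = −(GEZI_D + X)·G_endo + EGP(t)/V
    R_d    = (GEZI_D + X)·G·V,     EGP_b = GEZI_D·G_b·V

Ra comes from a gastrointestinal sub-model (stomach emptying with a
tanh-shaped, dose-dependent rate between k_max and k_min; first-order
intestinal absorption), yielding gastric retention GR(t) and the
half-emptying time T₅₀GR. GEZI_D (disposal glucose effectiveness at zero
insulin) is fixed to a population value for identifiability and scaled
down in type 1 diabetes; GE_P is fixed to zero in type 1 diabetes, where
the absent porto-systemic insulin gradient makes it unidentifiable.
Estimation is weighted least squares, jointly over both glucose channels,
with insulin as a known input.

**Insulin exposure.** For the diabetes arm, measured fast-acting insulin
is described by a two-compartment subcutaneous depot model (known bolus
timing and dose), and the free-active fraction of the basal analogue
(glargine 100%, detemir 25%, degludec 2.85%) is superimposed to form the
composite active insulin input.

**MRS quantification.** Hepatic D-Glc: per-voxel amplitudes are
normalised per deuteron, referenced to the pre-ingestion natural-abundance
water signal (8.94 mmol/l assumed hepatic HDO), then averaged over six
voxels. Glycogen: phantom-referenced with multiplicative corrections for
coil distance, loading, T₁ and nuclear Overhauser enhancement.

**Cohort analytics.** Incremental AUCs (trapezoid, stated baseline),
peaks/nadirs excluding the fasting draw, pooled-variance two-sample
t tests with 95% CIs, and Ward-linkage hierarchical clustering on the
z-scored plasma/hepatic D-Glc iAUCs for subgroup discovery.

## Worked example

```bash
python examples/04_fit_minimal_model.py
```

```
converged: True (weighted RSS 6.41e-13)
SI_disposal   = 1.152e-05 1/min per pmol/l (CV 0.0%)
SI_production = 2.749e-03 per pmol/l (CV 0.0%)
GE_disposal   = 0.0155 1/min (at basal insulin)
GE_production = 0.0050 per mmol/l

EGP suppression: 29% over the first hour, 63% over three hours
disposal rose 46% above basal (time-averaged, 0-180 min)
gastric half-emptying time: 130 min; 59% of the dose appeared in plasma by 180 min
```

This simulates a noise-free virtual healthy participant with the
documented default profile, fits the oral minimal model to the
partitioned glucose channels, and reports the estimated sensitivities and
model-derived fluxes: endogenous glucose production is 63% suppressed
over the 3 h window (the healthy hallmark the defaults are calibrated
to), while whole-body disposal rises about half above its basal rate.
The remaining examples cover simulation and file round trips (`01`),
tracer partitioning (`02`), subcutaneous insulin kinetics (`03`), MRS
quantification (`05`) and the cohort report with subgroup clustering
(`06`).

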