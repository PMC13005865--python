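"""Describe a diabetes subject's fast-acting insulin with the depot model.

The prandial bolus goes in subcutaneously about 45 min before the glucose
drink; a two-compartment depot with dual absorption routes is fitted to
the measured concentrations, and the free-active fraction of the basal
analogue (25% for detemir) is superimposed to give the composite active
insulin the glucose model uses as its known input.
"""

import hepaflux as hf

ds, truth = hf.generate_subject(hf.t1d_sub1_profile(), seed=0, noise=False)
config = hf.AnalysisConfig()

composite, exposure = hf.insulin_input_for(ds, config)
p = exposure.fast_params
print(f"bolus: {ds.bolus_events[0].dose_units:.1f} U at "
      f"t = {ds.bolus_events[0].time_min:.0f} min")
print(f"fitted kinetics: k_d={p.k_d:.4f}, k_a1={p.k_a1:.4f}, "
      f"k_a2={p.k_a2:.4f}, k_e={p.k_e:.4f} 1/min, V_I={p.V_I:.3f} l/kg")
print(f"elimination half-life: {p.elimination_half_life:.1f} min")
print(f"converged: {exposure.converged}, weighted RSS {exposure.rss:.2e}")

peak, peak_t, _, _ = hf.peak_nadir(composite, exclude_before=-60)
print(f"\ncomposite active insulin peaks at {peak:.0f} pmol/l "
      f"(t = {peak_t:.0f} min, i.e. {peak_t + 45:.0f} min after the bolus);")
print("the constant detemir contribution is "
      f"{0.25 * ds.basal_analogue_conc:.1f} pmol/l (25% of "
      f"{ds.basal_analogue_conc:.0f} pmol/l circulating)")
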