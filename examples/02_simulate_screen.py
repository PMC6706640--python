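"""Generate a small synthetic screening study.

Builds a 4-protein x 6-metabolite study with 15% binders and lists the
measurements the screen would acquire: one mix-alone (M) reference per mix,
one protein-alone (P) reference per enzyme, and one protein+mix (PM) sample
per combination, each as a short/long/short spin-lock triple.
"""

import t1screen as t

study = t.simulate_screen(
    n_proteins=4, n_metabolites=6, binder_fraction=0.15, n_mixes=2, seed=11
)

print(f"proteins    : {', '.join(study.proteins)}")
print(f"metabolites : {', '.join(study.metabolites)}")
print(f"mixes       : {', '.join(study.mixes())}")
print(f"true binders: {sorted(study.truth.binders())}")
print()
for meas in study.measurements:
    who = meas.protein_id or "-"
    mix = meas.mix_id or "-"
    print(f"  {meas.sample_id:<22} role={meas.role:<3} protein={who:<7} "
          f"mix={mix:<5} long delay={meas.long_delay_ms:g} ms")
print()
print(f"{len(study.measurements)} measurements, "
      f"{3 * len(study.measurements)} spectra in total; every spectrum has "
      "a DSS reference line at 0 ppm and Gaussian noise on top of the "
      "Lorentzian metabolite peaks.")
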