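"""Quantify relaxation factors on a noiseless study and compare with the
closed form.

With no noise, calibration offsets or degradation, the pipeline's ΔRF per
binder must equal exp(-r_free * dt) - exp(-r_obs * dt) exactly, with dt the
0.19 s long/short spin-lock difference and r_obs the fast-exchange average
rate.
"""

import t1screen as t
from t1screen.pipeline import design_from_assignment

study = t.simulate_screen(
    n_proteins=3, n_metabolites=4, binder_fraction=0.25,
    noise_sd=0.0, shift_offset_sd=0.0, seed=1,
)
design = design_from_assignment(study.mix_of, study.peak_lists)
windows, _ = t.compile_peak_windows(design, study.peak_lists)
matrix, quants = t.quantify_study(study.measurements, windows)

print("ΔRF matrix (NaN = no peak passed the QC filters):")
print(matrix.delta_rf.round(4))
print()
print(f"{'pair':<18} {'KD (uM)':>8} {'pipeline':>10} {'closed form':>12}")
for (prot, met), kd in sorted(study.truth.kd.items()):
    expected = t.expected_delta_rf(study.truth, kd)
    print(f"{prot}/{met:<11} {kd:>8.1f} {matrix.value(prot, met):>10.6f} "
          f"{expected:>12.6f}")
print()
print("Non-binding pairs carry no residual signal in the noiseless")
print("difference spectrum, so the S/N > 2 gate leaves them unquantified;")
print("every binder matches its closed form to machine precision.")
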