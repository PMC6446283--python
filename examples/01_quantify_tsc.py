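"""Quantify a tissue sodium concentration from a single ROI signal pair.

A brain-tissue ROI reads a mean sodium signal of 38.0 (arbitrary scanner
units) and the 0.6% NaCl reference tube reads 95.0 in the same image.
The relaxation-corrected calibration converts the ratio into an absolute
concentration in mmol/kg wet weight.
"""

from natsc import correction_factor, default_library, quantify_tsc

lib, acq = default_library()
brain = lib.spec("GM")
ref_spec, ref_conc = lib.reference

s_tissue, s_reference = 38.0, 95.0

cf = correction_factor(brain, ref_spec, acq)
tsc = quantify_tsc(s_tissue, s_reference, ref_conc, brain, ref_spec, acq)

print(f"acquisition: TR = {acq.tr_ms} ms, TE = {acq.te_ms} ms")
print(f"reference concentration: {ref_conc} mmol/L")
print(f"relaxation correction factor (brain vs reference): {cf:.4f}")
print(f"tissue sodium concentration: {tsc:.1f} mmol/kg wet weight")
print()
print(
    "The correction factor is close to 1 because at TR = 120 ms both "
    "compartments are nearly fully relaxed and TE = 0.2 ms allows little "
    "T2 decay; the concentration is essentially the signal ratio scaled "
    "by the reference concentration."
)
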