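# Default compartment constants and acquisition parameters for cerebral
# 23Na-MRI TSC quantification at 3 T.
#
# Sources of the relaxation times and compartment weights: published values
# for brain tissue (biexponential T2, alfa/beta = 0.6/0.4) and CSF
# (monoexponential, alfa/beta = 0.0/1.0).  The reference-phantom T1
# (t1_ms: 35.0) is an ASSUMPTION typical of aqueous/agarose NaCl phantoms
# at 3 T -- it is not a measured value; override it for a real phantom.
# The reference concentration 102.7 mmol/L is derived from 0.6 % NaCl
# (6 g/L / 58.44 g/mol).

acquisition:
  tr_ms: 120.0
  te_ms: 0.2
  voxel_mm: 3.6
  flip_deg: 87.0

reference:
  concentration_mmol_l: 102.7
  relaxation:
    t1_ms: 35.0          # assumption, see header
    t2_fast_ms: 7.15
    t2_slow_ms: 33.7
    weight_fast: 0.6
    weight_slow: 0.4

classes:
  brain:
    t1_ms: 29.0
    t2_fast_ms: 4.0
    t2_slow_ms: 29.0
    weight_fast: 0.6
    weight_slow: 0.4
  csf:
    t1_ms: 58.1
    t2_fast_ms: 55.0     # monoexponential: weight_fast = 0
    t2_slow_ms: 55.0
    weight_fast: 0.0
    weight_slow: 1.0

# Region ground-truth concentrations (mmol/kg wet weight) and
# between-subject SDs used by the synthetic cohort generator.
regions:
  GM:         {class: brain, concentration: 51.5,  between_subject_sd: 4.5}
  WM:         {class: brain, concentration: 40.9,  between_subject_sd: 3.8}
  HCN:        {class: brain, concentration: 60.9,  between_subject_sd: 8.1}
  pons:       {class: brain, concentration: 39.8,  between_subject_sd: 5.3}
  cerebellum: {class: brain, concentration: 40.1,  between_subject_sd: 4.9}
  CSF:        {class: csf,   concentration: 102.1, between_subject_sd: 21.6}
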