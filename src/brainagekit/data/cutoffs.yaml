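version: 1
# Amyloid/tau positivity cut-offs per cohort.  Abnormality is strictly past
# the cut-off: CSF abeta42 BELOW the cut-off is A+, Centiloid ABOVE is A+,
# p-tau ABOVE is T+; values exactly at the cut-off are normal.
cohorts:
  "ALFA+":
    abeta_modality: csf
    csf_abeta42: 1098.0
    csf_ptau: 24.0
  "EPAD":
    abeta_modality: csf
    csf_abeta42: 1098.0
    csf_ptau: 24.0
  "ADNI":
    abeta_modality: csf
    csf_abeta42: 880.0
    csf_ptau: 24.0
  "OASIS":
    abeta_modality: pet
    centiloid: 17.0
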