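"""Generate a synthetic NPC cohort and audit its planted signal.

The generator produces, per patient, three image channels (CT-like,
T1-like, T2-like), a 3D dose map and eight organ masks, plus a binary
adaptive-radiotherapy (ART) label at ~26% prevalence.  Outcome-linked
signal is planted on four channels (image texture, parotid dose, tumour
volume, tumour-to-cord distance) with standardised effect sizes
2.0 > 1.2 > 0.5 > 0.15, so radiomics should dominate downstream models.
"""

import numpy as np

from artomics import Modality, Role, SyntheticConfig, generate_cohort, signal_audit

config = SyntheticConfig(n_patients=135, seed=1)  # the study-scale cohort
records, cohort = generate_cohort(config)

print(f"cohort: {len(records)} patients, {cohort.labels.sum()} ART-positive")
rec = records[0]
dose = rec.images[Modality.DOSE]
high = rec.structures[Role.PTVN_HIGH]
print(f"patient {rec.patient_id}: grid {dose.shape}, spacing {dose.spacing} mm")
print(f"  mean dose in PTVn_high_dose: {dose.values[high.values].mean():.1f} Gy "
      "(prescription 70 Gy)")
print(f"  GTVnp volume: {rec.structures[Role.GTVNP].count() * 8 / 1000:.1f} cm^3")

print("\nplanted-signal audit (realised Cohen's d and implied Bayes AUC):")
print(signal_audit(records).round(3))
print("\nThe implied AUC Phi(d/sqrt(2)) is the ceiling any model reading that"
      "\nchannel alone can reach; the ordering should be texture > dose >"
      "\nmorph > contour, mirroring the planted effect sizes (up to sampling"
      "\nnoise of the effect-size estimate at n = 135).")
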