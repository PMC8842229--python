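"""Extract the four omics feature families for a few patients.

Radiomics (R): 93 intensity/texture features x 12 filter images x 10
modality-VOI pairs = 11,160 columns.  Morphology (M): 14 shape features x
4 VOIs = 56.  Dosiomics (D): 102 DVH scalars + 6 dose gradients + 93 dose
textures per VOI x 8 VOIs = 1,608.  Contouromics (C): 21 OVH distances +
12 POV angles per VOI pair x 4 pairs = 132.
"""

from artomics import SyntheticConfig
from artomics.pipeline import extract_all_families
from artomics.radiomics import ExtractionConfig
from artomics.synthetic import generate_cohort, resolve_laterality

records, _ = generate_cohort(SyntheticConfig(n_patients=10, seed=4))
records = [resolve_laterality(r) for r in records[:3]]
tables = extract_all_families(records, ExtractionConfig())

for family, table in tables.items():
    print(f"family {family}: {table.n_features:6d} features, "
          f"{len({c.voi for c in table.columns})} VOI sources")

R = tables["R"]
key = "R:CT-GTVnp:original_firstorder_Variance"
j = R.keys.index(key)
print(f"\nexample feature {key}:")
for pid, v in zip(R.patient_ids, R.matrix[:, j]):
    print(f"  {pid}: {v:8.1f}")
print("This first-order variance inside the primary tumour is the statistic"
      "\nthe texture signal is planted on - it separates ART from non-ART"
      "\npatients most strongly of all channels.")
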