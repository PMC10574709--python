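"""Simulate a three-class cohort and build the 200-variable bucket table.

The cohort mimics an authentication problem: cultivated/wild Lonicerae
japonicae flos (cLJF/wLJF) vs Lonicerae flos (LF).  Saponin methyl signals
(0.65-1.80 ppm) are high in LF, intermediate in wLJF, trace in cLJF.
"""

import numpy as np

from nmrpattern import assemble_table, default_species_design, simulate_cohort

design = default_species_design(seed=1)
spectra = simulate_cohort(design)
table = assemble_table(spectra)

print(f"cohort: {len(spectra)} spectra -> bucket table {table.values.shape}")
print(f"classes: { {lab: table.labels.count(lab) for lab in dict.fromkeys(table.labels)} }")

# mean TMS-normalized integral over the saponin methyl region per class
saponin = [i for i, (lo, hi) in enumerate(table.bucket_edges)
           if lo >= 0.65 and hi <= 1.80]
labels = np.asarray(table.labels)
for lab in ("cLJF", "wLJF", "LF"):
    mean = table.values[labels == lab][:, saponin].sum(axis=1).mean()
    print(f"saponin-region mass, {lab:5s}: {mean:.4f}")
print("-> LF > wLJF > cLJF ordering is the planted species signature;")
print("   values are integrals relative to the TMS bucket (=1.0 per sample).")
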