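"""The two-stage VIP screening and PLS-DA/OPLS-DA intersection cascade.

Stage 1 keeps variables with VIP > 1 under a PLS-DA of the full training
matrix; stage 2 rescreens the reduced matrix under both PLS-DA and OPLS-DA;
the characteristic variables are the intersection.
"""

import warnings

from nmrpattern import (DummyY, assemble_table, default_species_design,
                        intersect_cascade, scale_columns, simulate_cohort,
                        split_train_test)

table = assemble_table(simulate_cohort(default_species_design(seed=1)))
part = split_train_test(table, {"cLJF": 47, "wLJF": 6, "LF": 8}, seed=1)
train = table.subset_rows(part.train_indices)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    X, _ = scale_columns(train.values, "uv")
trace = intersect_cascade(X, DummyY.from_labels(train.labels), seed=1)

print(f"stage 1 (VIP>1, PLS-DA, full matrix): {trace.stage1_selected.size} variables")
print(f"stage 2 PLS-DA / OPLS-DA:             {trace.stage2_pls.size} / {trace.stage2_opls.size}")
print(f"characteristic (intersection):        {trace.characteristic.size}")
print("characteristic ppm windows:")
for i in trace.characteristic:
    lo, hi = train.bucket_edges[i]
    print(f"  {train.variable_names[i]:>5s}  [{lo:6.3f}, {hi:6.3f}] ppm")
print("-> selections concentrate in the planted marker windows")
print("   (0.65-1.80 saponins; 2.65-2.95 / 4.60-4.70 / 5.20-5.30 secoiridoids).")
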