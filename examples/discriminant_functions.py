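"""Stepwise LDA: variable entry by Wilks' lambda, Fisher classification
functions, LOOCV and test-set scoring — plus the published reference model.
"""

import warnings

import numpy as np

from nmrpattern import (DummyY, assemble_table, classify,
                        default_species_design, fit_lda, intersect_cascade,
                        loocv, predict_labels, reference_classification_functions,
                        scale_columns, simulate_cohort, split_train_test,
                        stepwise_select)

table = assemble_table(simulate_cohort(default_species_design(seed=1)))
part = split_train_test(table, {"cLJF": 47, "wLJF": 6, "LF": 8}, seed=1)
train, test = table.subset_rows(part.train_indices), table.subset_rows(part.test_indices)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    X, _ = scale_columns(train.values, "uv")
    trace = intersect_cascade(X, DummyY.from_labels(train.labels), seed=1)
    sel_local, record = stepwise_select(train.values[:, trace.characteristic],
                                        train.labels)
vars_orig = [int(trace.characteristic[j]) for j in sel_local]
names = [train.variable_names[i] for i in vars_orig]
print(f"stepwise-selected variables: {names}")

model = fit_lda(train.values[:, vars_orig], train.labels, selected_variables=vars_orig)
for k, lab in enumerate(model.class_order):
    terms = " + ".join(f"{c:.1f}*{v}" for c, v in zip(model.coefficients[k], names))
    print(f"  g_{lab}(x) = {terms} {model.intercepts[k]:+.1f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    acc_loo, _ = loocv(train.values[:, vars_orig], train.labels)
pred = predict_labels(model, test.values[:, vars_orig])
acc_test = np.mean([a == b for a, b in zip(pred, test.labels)])
print(f"LOOCV accuracy {acc_loo:.1%}   test-set accuracy {acc_test:.1%}")
print("-> each class has one linear classification function; a sample is")
print("   assigned to the class whose function scores highest.")

# the published reference functions ship with the package
ref = reference_classification_functions()
label, scores = classify(ref, np.zeros(7))
print(f"published model at the zero vector: scores {np.round(scores, 3)} -> {label}")
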