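"""Binary drying-mode analysis of cultivated material (hot-air vs sun).

The drying effect on the heat-labile secoiridoids is deliberately weak in
this design, so the supervised models fit the training batches well but
predict held-out batches much less reliably — the regime in which stepwise
LDA is the more useful classifier.
"""

import json

from nmrpattern import PipelineConfig, run_processing_analysis

cfg = PipelineConfig(seed=1, output_dir="scratch/processing_example",
                     n_permutations=100)
report = run_processing_analysis(cfg)

o = report["opls"]
print("OPLS-DA (1 predictive + 1 orthogonal component):")
print(f"  R2Y = {o['r2y_cum']:.3f}   Q2 = {o['q2_cum']:.3f}")
print(f"  train accuracy {o['train_accuracy']:.1%}   test accuracy {o['test_accuracy']:.1%}")
print(f"  permutation Q2 intercept {o['perm_q2_intercept']:+.3f}")
l = report["lda"]
print("stepwise LDA on the VIP>1 variables:")
print(f"  LOOCV {l['loocv_accuracy']:.1%}   test accuracy {l['test_accuracy']:.1%}")
print("-> high R2Y with much lower Q2: good fitness, poor predictive ability;")
print(json.dumps({"n_vip_selected": report["n_vip_selected"]}))
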