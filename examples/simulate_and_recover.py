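"""Cohort simulation and discrimination recovery.

Draws synthetic cohorts from the grade-conditional reduction-rate model
(G1 0.40 +/- 0.15 vs G2/G3 ~ 0.26 +/- 0.07, truncated at 1) and checks that
the ROC analysis recovers the built-in grade separation.
"""
import numpy as np

import hepquant as hq

model = hq.CohortModel(group_sizes={"G1": 100, "G2": 50, "G3": 50})

aucs = []
for seed in range(25):
    records, _ = hq.simulate_cohort(model, seed)
    rr = np.array([r.reduction_rate for r in records])
    labels = np.array([r.grade == "G1" for r in records])
    aucs.append(hq.roc_auc(rr, labels))

print(f"{len(aucs)} simulated cohorts of n=200 (100 G1 vs 100 G2/G3)")
print(f"AUC: median {np.median(aucs):.3f}, range [{min(aucs):.3f}, {max(aucs):.3f}]")
print(f"replicates with AUC > 0.75: {sum(a > 0.75 for a in aucs)}/{len(aucs)}")
# The generating distributions imply a theoretical AUC near 0.81; observed
# AUCs scatter around it, almost always clearing 0.75.
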