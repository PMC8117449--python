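"""The composite FET-DKI index classifier.

index = 4.7 * TBR_max + 39.2 * MK_C90, calling tumor progression when the
index exceeds 41.  Evaluated first at the two groups' published median
operating points, then on a simulated cohort.
"""

import numpy as np

from fetdki.cohort import CohortSimConfig, simulate_feature_cohort
from fetdki.stats import fet_dki_index, roc_analysis

for group, tbr, mk in (("TPR", 3.30, 0.78), ("TRC", 2.50, 0.61)):
    value, call = fet_dki_index(tbr, mk)
    print(f"{group} medians (TBR_max={tbr}, MK_C90={mk}) -> index {value:.3f} -> {call}")

cohort = simulate_feature_cohort(CohortSimConfig(n_trc=110, n_tpr=210, seed=5))
idx, calls = fet_dki_index(cohort["TBR_max"].to_numpy(),
                           cohort["MK_C90"].to_numpy())
acc = np.mean(calls == cohort["group"].to_numpy()) * 100
roc = roc_analysis(idx, cohort["group"].to_numpy())
print(f"\nsimulated cohort (n={len(cohort)}): accuracy at cutoff 41 = {acc:.1f}%, "
      f"AUC = {roc.auc:.3f}")

# The group-median operating points straddle the cutoff (46.1 vs 35.7
# around 41).  Cohort-level accuracy is lower than at the medians because
# individual patients scatter around them; the synthetic generator
# reproduces group medians/IQRs, not the original patients.
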