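"""Two-group cohort comparison of the total ultrastructure index.

Draws a synthetic 39-patient cohort (27 without atrial fibrillation, 12
with) from the generator's default group distributions, computes Me [Q1; Q3]
summaries, the Mann-Whitney test and the ROC AUC for each parameter, and
prints the report table.
"""

import pandas as pd

from mitomorph import CohortSpec, draw_cohort_parameters
from mitomorph.cohort_stats import compare_cohort

frame = draw_cohort_parameters(CohortSpec(seed=1))
comparisons = compare_cohort(frame)

for c in comparisons.values():
    print(f"{c.parameter:12s} {str(c.summary_g0):28s} vs {str(c.summary_g1):28s}"
          f" p={c.p_value:.3f}  AUC={c.auc:.3f} ({c.auc_direction})")

# Typical output: the total index separates the groups (p well below 0.05,
# AUC ~0.8 with the LOWER index predicting AF), while TAIM and OIMR
# individually overlap much more — the motivation for combining them.
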