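"""Compare DoR between two simulated cohorts of cells.

Simulates a control-like cohort (strongly radial microtubules) and a
patient-like cohort (weakly radial), measures per-cell DoR at relative
radial distance 2, and tests the group difference.
"""

import pandas as pd

from synapsekit import batch_report, dor_cohort

ctrl = dor_cohort(alpha=1.0, n_cells=20, seed=1)
case = dor_cohort(alpha=0.4, n_cells=20, seed=2)

rows = [{"cell_id": f"ctrl{i}", "group": "control", "metric": "dor", "value": v}
        for i, v in enumerate(ctrl)]
rows += [{"cell_id": f"case{i}", "group": "case", "metric": "dor", "value": v}
         for i, v in enumerate(case)]
table = batch_report(pd.DataFrame(rows), test="t_independent")
print(table.to_string(index=False))

print(
    "\nmean_a/mean_b are the group means of per-cell DoR; a p-value far"
    "\nbelow 0.05 says the radiality difference is detectable at this"
    "\ngroup size with the independent-samples t-test."
)
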