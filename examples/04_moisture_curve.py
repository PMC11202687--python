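"""Moisture content and moisture ratio from a weight series.

Converts a half-hourly weight record of one drying sample into dry-basis
moisture content M_t = (W_t - W_d)/W_d and moisture ratio MR = M_t/M_0,
and reports when the batch reaches the customary safe endpoint
(MR = 0.05 +/- 0.01).
"""

import numpy as np
import pandas as pd

from drytrack.moisture import drying_records

# a sample starting at 81% wet-basis moisture (dry matter 19%), 10.5 g
w_d = 2.0                       # bone-dry weight, g
m0 = 0.81 / 0.19                # initial dry-basis moisture content
mr_true = np.exp(-0.3 * np.arange(11))   # first-order drying, k=0.3 per step
weights = pd.DataFrame({"W_t": w_d * (1 + m0 * mr_true), "W_d": w_d})

records = drying_records(weights)
print(" t   W_t(g)    M_t     MR")
for r in records:
    flag = "  <- safe endpoint" if abs(r.MR - 0.05) <= 0.01 else ""
    print(f"{r.time_index:2d}  {r.W_t:7.3f}  {r.M_t:.3f}  {r.MR:.3f}{flag}")
# MR is exactly 1 at the baseline weighing and decays toward 0; the run
# crosses the 0.05 +/- 0.01 endpoint at the final half-hourly step.
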