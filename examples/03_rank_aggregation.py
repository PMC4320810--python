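"""Integrate fold-change rankings across datasets with robust rank aggregation.

A transcript consistently near the top of several datasets' fold-change
rankings gets a small rank score rho = min_k P(Binomial(n, r(k)) >= k) and a
small Bonferroni-adjusted p-value, even if no single dataset is decisive.
"""

import numpy as np
import pandas as pd

from lncprobe.expression import FoldChangeTable, call_regulated, rra_aggregate

rng = np.random.default_rng(4)
ids = [f"t{i:02d}" for i in range(40)]
tables = []
for d in range(8):
    fc = pd.Series(rng.normal(0, 0.5, size=40), index=ids)
    fc["t00"] += 2.0        # planted upregulated transcript
    fc["t01"] -= 2.0        # planted downregulated transcript
    tables.append(FoldChangeTable(f"D{d}", fc))

up = rra_aggregate(tables, "up")
down = rra_aggregate(tables, "down")
print("top of the upregulated ranking (rho, p, p_adj):")
for a in up[:3]:
    print(f"  {a.transcript_id}  rho={a.rho:.3g}  p={a.p:.3g}  p_adj={a.p_adj:.3g}")

called_up, called_down = call_regulated(up, down, alpha=0.05)
print(f"\ncalled up:   {[a.transcript_id for a in called_up]}")
print(f"called down: {[a.transcript_id for a in called_down]}")
print("\nOnly the planted transcripts clear the Bonferroni-0.05 cutoff; the 38")
print("null transcripts have near-uniform ranks and large adjusted p-values.")
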