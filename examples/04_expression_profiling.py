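"""Expression profiling: normalization, group tests and stage profiles.

Simulates negative-binomial counts for 20 element types across four tissues
(three replicates each, unequal library sizes), with one element planted at a
5x mean in heart.  The pipeline recovers the library-size factors, computes
NRC and NRC_rel, and runs the transform-then-test battery per element.
"""

import numpy as np
import pandas as pd

from retrocensus import normalize_counts, test_element
from retrocensus.simulate import CountSimSpec, simulate_counts

tissues = ["brain", "heart", "liver", "muscle"]
means = np.full((20, 4), 80.0)
means[0, 1] = 400.0  # element 0: 5x in heart
spec = CountSimSpec(
    means=means,
    groups=[0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3],
    size_factors=np.array([1.0, 1.1, 0.9, 1.3, 1.0, 0.8, 1.0, 1.2, 1.0, 0.7, 1.0, 1.1]),
    alpha=0.1,
    group_labels=tissues,
    element_names=[f"el{i}" for i in range(20)],
)
counts, meta = simulate_counts(spec, seed=3)
norm = normalize_counts(counts)
print("recovered size factors (planted 1.0, 1.1, 0.9, ...):")
print("  " + ", ".join(f"{v:.2f}" for v in norm.size_factors))

rows = []
for el in norm.nrc_rel.index[:5]:
    row = norm.nrc_rel.loc[el].to_numpy()
    groups = {t: row[3 * g:3 * g + 3] for g, t in enumerate(tissues)}
    r = test_element(groups, element=el)
    rows.append((el, r.boxcox_lambda, r.test_used, r.p_value))
print("\nelement  lambda  test            p-value")
for el, lam, used, p in rows:
    flag = "  <- planted tissue-specific" if el == "el0" and p < 0.05 else ""
    print(f"{el:8s} {lam:5.2f}  {used:14s} {p:8.4f}{flag}")

print("\nel0's 5x heart mean should test significant; the null elements "
      "should mostly not (about 1 in 20 will at alpha = 0.05).")
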