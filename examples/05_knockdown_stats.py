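"""Downstream expression statistics for a knockdown time course.

Controls are quantile-normalized, transcripts below log2(TPM+1) = 1.5 in the
controls are dropped, a transcript is downregulated when its log2 fold
change falls below -0.7, and downregulated sets are tested for enrichment in
pre-defined expression clusters (hypergeometric, Bonferroni over clusters).
"""

import numpy as np
import pandas as pd

import stemsplice as ss

rng = np.random.default_rng(3)
n = 400
base = rng.gamma(3.0, 1.0, size=n) + 1.0
expr = pd.DataFrame(
    {
        "kd_d20": base + rng.normal(0, 0.15, n),
        "ctl_d20": base + rng.normal(0, 0.15, n),
        "kd_d25": base + rng.normal(0, 0.15, n),
        "ctl_d25": base + rng.normal(0, 0.15, n),
    },
    index=[f"t{i}" for i in range(n)],
)
# plant downregulation concentrated in cluster 1
clusters = {f"t{i}": i % 6 + 1 for i in range(n)}
planted = [t for t, c in clusters.items() if c == 1][:40]
expr.loc[planted, ["kd_d20", "kd_d25"]] = (
    expr.loc[planted, ["ctl_d20", "ctl_d25"]].to_numpy() - 1.0
)

expr = ss.quantile_normalize(expr, ["ctl_d20", "ctl_d25"])
per_tp, union, expressed = ss.call_downregulated(
    expr, {"d20": ("kd_d20", "ctl_d20"), "d25": ("kd_d25", "ctl_d25")}
)
enrichment = ss.cluster_enrichment(union, clusters, expressed)

print(f"expressed transcripts: {len(expressed)}")
print(f"downregulated (union of d20, d25): {len(union)}")
print(enrichment.to_string())
print(
    "\ncluster 1 (where downregulation was planted) should show a tiny "
    "corrected p; the remaining clusters stay near 1."
)
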