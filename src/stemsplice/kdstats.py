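"""Downstream expression statistics for knockdown experiments.

Control samples are quantile-normalized; transcripts are filtered for
reliable detection (log2(TPM+1) > 1.5); a transcript counts as downregulated
at a timepoint when its log2 fold change versus the matched control falls
below -0.7 (strict inequality); and downregulated sets are tested for
enrichment in pre-defined expression clusters with a hypergeometric test,
Bonferroni-corrected over the clusters tested.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "quantile_normalize",
    "call_downregulated",
    "cluster_enrichment",
]


def quantile_normalize(
    matrix: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Quantile-normalize the selected columns (default: all).

    Each selected column's sorted values are replaced by the across-column
    means of the order statistics; tied values within a column receive the
    mean of the reference values at their tied ranks.  Unselected columns are
    returned untouched.
    """
    cols = list(columns) if columns is not None else list(matrix.columns)
    if not cols:
        raise ValueError("no columns selected for normalization")
    sub = matrix[cols].to_numpy(dtype=float)
    sorted_cols = np.sort(sub, axis=0)
    if np.array_equal(sorted_cols, np.tile(sorted_cols[:, :1], (1, len(cols)))):
        # already-normalized input: honour the fixed point exactly rather
        # than re-averaging identical order statistics (1-ulp drift)
        reference = sorted_cols[:, 0]
    else:
        reference = sorted_cols.mean(axis=1)
    out = matrix.copy()
    for j, col in enumerate(cols):
        v = sub[:, j]
        order = np.argsort(v, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties: average the assigned reference values within each tie group
        s = pd.Series(assigned)
        out[col] = s.groupby(pd.Series(v)).transform("mean").to_numpy()
    return out


def call_downregulated(
    matrix: pd.DataFrame,
    comparisons: Mapping[str, tuple[str, str]],
    *,
    fc_threshold: float = -0.7,
    expr_threshold: float = 1.5,
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Downregulated transcripts per timepoint and their union.

    ``matrix`` holds log2(TPM+1); ``comparisons`` maps a timepoint label to a
    (treated, control) column pair.  Only transcripts exceeding
    ``expr_threshold`` in every control column are eligible ("reliably
    detected").  A transcript is down at a timepoint iff
    treated - control < ``fc_threshold`` (strict).  Returns
    (per-timepoint sets, union, expressed background set).
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    controls = [c for _, c in comparisons.values()]
    for col in controls + [t for t, _ in comparisons.values()]:
        if col not in matrix.columns:
            raise ValueError(f"column {col!r} missing from the expression matrix")
    expressed_mask = (matrix[controls] > expr_threshold).all(axis=1)
    expressed = set(matrix.index[expressed_mask])
    per_timepoint: dict[str, set[str]] = {}
    for label, (treated, control) in comparisons.items():
        fc = matrix[treated] - matrix[control]
        down = set(matrix.index[expressed_mask & (fc < fc_threshold)])
        per_timepoint[label] = down
    union: set[str] = set().union(*per_timepoint.values())
    return per_timepoint, union, expressed


def cluster_enrichment(
    down: set[str],
    clusters: Mapping[str, str | int],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of the downregulated set in each cluster.

    For cluster c with K background members, N background transcripts and n
    downregulated ones of which k fall in c, p = P(X >= k) for
    X ~ Hypergeom(N, K, n).  Bonferroni corrects over the clusters with
    nonzero background overlap.
    """
    if not down <= background:
        raise ValueError("downregulated set must be a subset of the background")
    N = len(background)
    n = len(down)
    members: dict[str, set[str]] = {}
    for transcript, label in clusters.items():
        members.setdefault(str(label), set()).add(transcript)
    rows = []
    for label in sorted(members):
        in_bg = members[label] & background
        K = len(in_bg)
        if K == 0:
            continue
        k = len(in_bg & down)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"cluster": label, "K": K, "k": k, "p_raw": p})
    if not rows:
        raise ValueError("no cluster overlaps the background")
    out = pd.DataFrame(rows).set_index("cluster")
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(out))
    return out
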