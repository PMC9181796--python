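"""FPKM quantification and replicate-correlation QC.

FPKM[g, s] = counts[g, s] / ((length_bp[g] / 1e3) * (total_counts[s] / 1e6)),
with per-sample totals taken as the column sums of the supplied count
matrix — the only mapped-fragment total available once upstream alignment
is out of the picture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CountMatrix

#: pseudocount applied before the log10 transform used in correlation QC
LOG_PSEUDOCOUNT = 1.0


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {', '.join(zero)}")
    lengths_kb = cm.gene_lengths.loc[cm.counts.index] / 1e3
    fpkm = cm.counts.div(totals / 1e6, axis=1).div(lengths_kb, axis=0)
    return fpkm


def replicate_correlation(
    expr: pd.DataFrame, group_of: pd.Series
) -> dict[str, pd.DataFrame]:
    """Within-group pairwise Pearson r on log10(expr + 1).

    Returns one symmetric, unit-diagonal replicate x replicate matrix per
    group. A constant replicate vector has undefined correlation and is
    reported as NaN rather than raising.
    """
    logx = np.log10(expr + LOG_PSEUDOCOUNT)
    out: dict[str, pd.DataFrame] = {}
    for group in pd.unique(group_of):
        cols = group_of.index[group_of == group]
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 replicates")
        corr = logx[list(cols)].corr(method="pearson")
        # pandas leaves the diagonal of an all-constant column NaN; keep the
        # unit-diagonal contract for defined columns only
        out[group] = corr
    return out


def correlation_summary(per_group: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Min / median / max off-diagonal within-group correlation."""
    vals: list[float] = []
    for mat in per_group.values():
        a = mat.to_numpy()
        iu = np.triu_indices_from(a, k=1)
        vals.extend(a[iu][~np.isnan(a[iu])])
    if not vals:
        return {"min": float("nan"), "median": float("nan"), "max": float("nan")}
    arr = np.asarray(vals)
    return {
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
    }
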