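"""Nucleocyclic-vs-other group contrasts.

One-tailed Wilcoxon rank-sum comparisons of a per-TSS parameter between
Group 1 (nucleocyclic) and Groups 2+3, with a pre-specified direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import RankSumResult, ranksum_one_tailed


@dataclass
class GroupComparison:
    parameter: str
    direction: str  # "greater" | "less" (Group 1 relative to the rest)
    p_value: float
    statistic: float
    method: str
    n_group1: int
    n_rest: int
    median_group1: float
    median_rest: float


def compare_groups(
    values,
    labels,
    direction: str,
    parameter: str = "",
    group: int = 1,
) -> GroupComparison:
    """Compare ``values`` of TSSs in ``group`` against all other groups.

    ``direction`` is the pre-specified one-tailed alternative for the focal
    group ("greater" or "less"); it is never inferred from the data.  NaN
    values and label-0 (missing-group) TSSs are excluded.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values) & (labels > 0)
    g1 = values[ok & (labels == group)]
    rest = values[ok & (labels != group)]
    res: RankSumResult = ranksum_one_tailed(g1, rest, alternative=direction)
    return GroupComparison(
        parameter=parameter,
        direction=direction,
        p_value=res.p_value,
        statistic=res.statistic,
        method=res.method,
        n_group1=len(g1),
        n_rest=len(rest),
        median_group1=float(np.median(g1)),
        median_rest=float(np.median(rest)),
    )
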