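"""Nonparametric group comparison (Mann-Whitney U / Wilcoxon rank-sum)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "mannwhitney"]


@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney comparison of two independent groups."""

    U: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def mannwhitney(values_a, values_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used for small samples (min group size
    <= 8) without ties; otherwise the normal approximation with tie
    correction.  ``U`` is the statistic of the first group.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
        method=method,
    )
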