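"""Replicate aggregation and the two-group comparison of permeability means.

Dispersion is reported as RSD% (relative standard deviation, 100·SD/mean),
the currency of plate-assay variability.  Group comparison uses Welch's
unequal-variance two-sample t-test: replicate groups from the two
formulations show grossly different spreads, so pooling variances is not
assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _st

__all__ = ["GroupSummary", "ComparisonResult", "summarize", "compare_groups"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n−1), RSD% and count of one replicate group.

    ``sd`` and ``rsd_pct`` are NaN for a single value; ``rsd_pct`` is NaN
    (flagged undefined) when the mean is zero.
    """

    mean: float
    sd: float
    rsd_pct: float
    n: int


class ComparisonResult(NamedTuple):
    p_value: float
    significant: bool


def summarize(values: Sequence[float]) -> GroupSummary:
    """Aggregate replicate measurements into mean / SD / RSD%."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one value")
    mean = float(x.mean())
    if x.size == 1:
        return GroupSummary(mean=mean, sd=math.nan, rsd_pct=math.nan, n=1)
    sd = float(x.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else math.nan
    return GroupSummary(mean=mean, sd=sd, rsd_pct=rsd, n=int(x.size))


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Welch's two-sided t-test between two replicate groups.

    Returns the p-value and whether the difference is significant at
    ``alpha``.  Both groups need at least two values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = _st.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return ComparisonResult(p_value=p, significant=p < alpha)
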