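"""Peak-height comparisons and partnership-dependence categorization.

Peak heights (FPKM) of peaks with adjacent FBEs are compared to all
peaks, and to each other split by Y479A partnership dependence, with an
unpaired two-sided t-test assuming equal variance (pooled variance,
df = n_a + n_b - 2).  Categories (lower/higher/unchanged occupancy in
the Y479A mutant track) are consumed from the input table when present;
a fold-change rule stands in for synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupComparison:
    group_a_label: str
    group_b_label: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    quartiles_a: tuple[float, float, float]
    quartiles_b: tuple[float, float, float]

    def format_p(self) -> str:
        """p-value in scientific notation at 2 significant figures."""
        return f"{self.p_value:.1e}"


def mean_height(heights: Sequence[float]) -> float:
    """Arithmetic mean peak height; rejects empty input."""
    arr = np.asarray(heights, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_height requires at least one height")
    return float(arr.mean())


def _quartiles(arr: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def pooled_t_test(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Unpaired two-sided t-test assuming equal variance.

    Degenerate case: if the pooled variance is zero and means are equal
    the test is a no-op (t = 0, p = 1); zero pooled variance with unequal
    means is rejected as ill-posed.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs >= 2 values")
    pooled_var = (
        (xa.size - 1) * xa.var(ddof=1) + (xb.size - 1) * xb.var(ddof=1)
    ) / (xa.size + xb.size - 2)
    if pooled_var == 0.0:
        if xa.mean() == xb.mean():
            t_stat, p_val = 0.0, 1.0
        else:
            raise ValueError(
                "zero pooled variance with unequal means: t undefined"
            )
    else:
        res = stats.ttest_ind(xa, xb, equal_var=True)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label_a,
        label_b,
        float(xa.mean()),
        float(xb.mean()),
        int(xa.size),
        int(xb.size),
        t_stat,
        p_val,
        _quartiles(xa),
        _quartiles(xb),
    )


def categorize_y479(
    height_wt: float,
    height_mut: float,
    fold_threshold: float = 1.5,
) -> str:
    """Classify a peak's Y479A partnership dependence by fold change.

    ``lower``  — occupancy drops in the mutant (mut * threshold <= wt);
    ``higher`` — occupancy rises (wt * threshold <= mut);
    ``unchanged`` otherwise (including both heights zero).

    Deposited category labels, when present in the input table, take
    precedence over this rule; it exists for synthetic data.
    """
    if height_wt < 0 or height_mut < 0:
        raise ValueError("heights must be nonnegative")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if height_wt == 0 and height_mut == 0:
        return "unchanged"
    if height_mut * fold_threshold <= height_wt:
        return "lower"
    if height_wt * fold_threshold <= height_mut:
        return "higher"
    return "unchanged"
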