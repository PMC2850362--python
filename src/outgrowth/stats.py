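"""Replicate-group summaries and comparisons against a reference group.

Grouping collapses replicate wells (biological or technical) to a
center (mean or median) with a sample standard deviation.  Comparisons
versus an experiment-matched reference group are reported as percent
change, log2 ratio, and a two-sample Welch t-test (unequal variances,
two-sided p).  No multiple-testing correction is applied; apply your
own across strains if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = [
    "GroupSummary",
    "summarize_group",
    "pct_change",
    "log2_ratio",
    "t_test_vs_ref",
    "compare_groups",
]


def summarize_group(
    values: Sequence[float], mode: str = "average"
) -> tuple[float, float]:
    """Center and spread of one replicate group.

    ``mode`` selects the center: ``"average"`` (arithmetic mean) or
    ``"median"``.  Spread is always the sample standard deviation
    (n − 1 denominator), 0.0 for a single replicate.
    """
    if len(values) == 0:
        raise ValueError("empty replicate group")
    if mode not in ("average", "median"):
        raise ValueError(f"unknown grouping mode {mode!r}")
    arr = np.asarray(values, dtype=float)
    center = float(np.mean(arr)) if mode == "average" else float(np.median(arr))
    spread = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return center, spread


def pct_change(group_center: float, ref_center: float) -> float:
    """Percent change of a group's value versus the reference's."""
    if ref_center == 0:
        raise ValueError("percent change undefined for a zero reference value")
    return 100.0 * (group_center - ref_center) / ref_center


def log2_ratio(group_center: float, ref_center: float) -> float:
    """log2 of the group/reference ratio; both values must be positive."""
    if group_center <= 0 or ref_center <= 0:
        raise ValueError(
            f"log2 ratio requires positive values, got {group_center} vs {ref_center}"
        )
    return math.log2(group_center / ref_center)


def t_test_vs_ref(
    group_values: Sequence[float], ref_values: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test of a group versus the reference group.

    Unequal variances are assumed (Welch–Satterthwaite degrees of
    freedom); the p-value is two-sided.  Both groups need at least two
    replicates.
    """
    if len(group_values) < 2 or len(ref_values) < 2:
        raise ValueError("t-test requires ≥2 replicates in each group")
    res = _scipy_stats.ttest_ind(
        np.asarray(group_values, dtype=float),
        np.asarray(ref_values, dtype=float),
        equal_var=False,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group statistics, optionally compared to a reference group."""

    group: str
    n: int
    center: float
    spread: float
    pct_change_vs_ref: Optional[float] = None
    log2_ratio_vs_ref: Optional[float] = None
    t_stat: Optional[float] = None
    p_value: Optional[float] = None


def compare_groups(
    values_by_group: dict[str, Sequence[float]],
    mode: str = "average",
    reference: str | None = None,
) -> list[GroupSummary]:
    """Summarize every group and, if a reference is named, compare to it.

    The reference group appears in the output with comparison fields
    set to their identity values (0% change, log2 ratio 0); when its
    own values cannot support a comparison (non-positive centers, fewer
    than 2 replicates for the t-test) the affected fields are ``None``.
    """
    if reference is not None and reference not in values_by_group:
        raise ValueError(
            f"reference group {reference!r} not among groups "
            f"{sorted(values_by_group)}"
        )
    ref_vals = list(values_by_group[reference]) if reference is not None else None
    ref_center = summarize_group(ref_vals, mode)[0] if ref_vals else None

    out: list[GroupSummary] = []
    for group, vals in values_by_group.items():
        vals = list(vals)
        center, spread = summarize_group(vals, mode)
        pct = l2r = t = pval = None
        if ref_center is not None:
            if ref_center != 0:
                pct = pct_change(center, ref_center)
            if center > 0 and ref_center > 0:
                l2r = log2_ratio(center, ref_center)
            if len(vals) >= 2 and len(ref_vals) >= 2:
                t, pval = t_test_vs_ref(vals, ref_vals)
        out.append(
            GroupSummary(
                group=group,
                n=len(vals),
                center=center,
                spread=spread,
                pct_change_vs_ref=pct,
                log2_ratio_vs_ref=l2r,
                t_stat=t,
                p_value=pval,
            )
        )
    return out
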