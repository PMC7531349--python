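"""Nonparametric statistics for per-sequence composition tables.

Kendall tau-b rank correlation, two-sided Wilcoxon rank-sum (Mann-Whitney)
tests and step-down Holm adjustment — the toolkit applied to GC-percent /
dyad-density tables.  Exact null distributions are used whenever the sample
sizes permit (tau: n ≤ 8 without ties; rank-sum: both groups ≤ 25 without
ties), otherwise the tie-corrected normal approximations (with continuity
correction for the rank-sum test).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dyad_analysis import SequenceStats

__all__ = [
    "CorrelationMethod",
    "TestMethod",
    "CorrelationResult",
    "GroupComparison",
    "kendall_tau",
    "wilcoxon_rank_sum",
    "holm_adjust",
    "compare_groups",
]

EXACT_TAU_MAX_N = 8
EXACT_RANKSUM_MAX_N = 25


class CorrelationMethod(str, enum.Enum):
    EXACT_ENUMERATION = "exact_enumeration"
    NORMAL_APPROX = "normal_approx"


class TestMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX_CC = "normal_approx_cc"


@dataclass
class CorrelationResult:
    tau: float
    n: int
    p_value: float
    method: CorrelationMethod


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group_a
    p_raw: float
    method: TestMethod
    q_holm: float | None = None


def _has_ties(values: Sequence[float]) -> bool:
    return len(set(values)) < len(values)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall tau-b with a two-sided p-value.

    tau-b = (C − D) / sqrt((n0 − n_tx)(n0 − n_ty)) with n0 = n(n−1)/2 and the
    usual tie terms.  The p-value comes from exact enumeration of the
    permutation null when n ≤ 8 and neither vector has ties, else from the
    tie-corrected normal approximation on C − D.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("correlation undefined for a constant vector")
    exact = n <= EXACT_TAU_MAX_N and not _has_ties(x) and not _has_ties(y)
    res = sps.kendalltau(
        x, y, variant="b", method="exact" if exact else "asymptotic"
    )
    return CorrelationResult(
        tau=float(res.statistic),
        n=n,
        p_value=float(res.pvalue),
        method=(
            CorrelationMethod.EXACT_ENUMERATION
            if exact
            else CorrelationMethod.NORMAL_APPROX
        ),
    )


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test (``q_holm`` left unset).

    Exact null distribution when both groups have ≤ 25 observations and the
    pooled sample has no ties; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    exact = max(len(a), len(b)) <= EXACT_RANKSUM_MAX_N and not _has_ties(a + b)
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        method=TestMethod.EXACT if exact else TestMethod.NORMAL_APPROX_CC,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in input order.

    q_(i) = max_{j ≤ i} min(1, (m − j + 1)·p_(j)) over the ascending sort.
    """
    p = list(p_values)
    if not p:
        return []
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(arr, method="holm")[1]]


def compare_groups(
    stats_table: Sequence[SequenceStats],
    grouping: Mapping[str, str],
    value: str = "gc_percent",
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[GroupComparison]:
    """Pairwise rank-sum tests across groups with Holm adjustment over the family.

    ``grouping`` maps sequence ids to group labels; rows without a mapping are
    ignored.  ``pairs`` selects the tested family (default: all group pairs in
    sorted label order).  The Holm family size is the number of tested pairs.
    """
    if value not in ("gc_percent", "dyad_density"):
        raise ValueError(f"unknown value field {value!r}")
    groups: dict[str, list[float]] = {}
    for row in stats_table:
        label = grouping.get(row.id)
        if label is None:
            continue
        groups.setdefault(label, []).append(getattr(row, value))
    if pairs is None:
        labels = sorted(groups)
        if len(labels) < 2:
            raise ValueError("need at least 2 groups to compare")
        pairs = list(itertools.combinations(labels, 2))
    comparisons = []
    for ga, gb in pairs:
        for label in (ga, gb):
            if label not in groups:
                raise ValueError(f"unknown group label {label!r}")
        comparisons.append(
            wilcoxon_rank_sum(groups[ga], groups[gb], group_a=ga, group_b=gb)
        )
    qs = holm_adjust([c.p_raw for c in comparisons])
    for comp, q in zip(comparisons, qs):
        comp.q_holm = q
    return comparisons
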