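"""One-way ANOVA from sufficient statistics, Tukey-Kramer post hocs,
percent differences, and the +/- k SD outlier audit.

The central trick is that a one-way ANOVA needs only each group's
(n, mean, sd): ``ss_between = sum n_i (mean_i - grand)^2`` and
``ss_within = sum (n_i - 1) sd_i^2``.  This supports singleton groups —
template heads enter the omnibus comparison as n = 1 groups contributing
zero within-group variance and zero within degrees of freedom, which is
how a 195-subject cohort plus two templates yields df = (2, 194).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairwiseComparison",
    "anova_from_summaries",
    "anova_from_raw",
    "tukey_kramer",
    "percent_difference",
    "outliers_beyond_k_sd",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) for one group.

    ``sd`` is ignored for singleton groups (n = 1), which carry no
    within-group information.
    """

    label: str
    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.n >= 2 and self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} has no observations")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA: F, degrees of freedom, p, partial eta squared, and
    the sums of squares they derive from."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    eta_p2: float
    ss_between: float
    ss_within: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class PairwiseComparison:
    """One Tukey-Kramer pair: mean difference (a - b), studentized-range
    statistic, adjusted p, and the significance flag at alpha."""

    group_a: str
    group_b: str
    diff: float
    q_stat: float
    p_adj: float
    significant: bool


def anova_from_summaries(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA computed from group sufficient statistics.

    Singleton groups contribute 0 to ss_within and 0 to df_within.  Raises
    if fewer than two groups are supplied or every group is a singleton
    (within-group variance undefined).
    """
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd if g.n > 1 else 0.0 for g in groups], dtype=float)
    df_within = int((n - 1).sum())
    if df_within < 1:
        raise ValueError("all groups are singletons: within-group variance undefined")
    grand = float((n * m).sum() / n.sum())
    ss_between = float((n * (m - grand) ** 2).sum())
    ss_within = float(((n - 1) * sd**2).sum())
    df_between = len(groups) - 1
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = math.inf if ss_between > 0 else 0.0
    else:
        f_stat = ms_between / ms_within
    p_value = float(stats.f.sf(f_stat, df_between, df_within))
    denom = ss_between + ss_within
    eta_p2 = ss_between / denom if denom > 0 else 0.0
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        eta_p2=float(eta_p2),
        ss_between=ss_between,
        ss_within=ss_within,
    )


def anova_from_raw(values_by_group: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA from raw per-group observations.

    Computed by direct sums-of-squares decomposition (not by delegating to
    :func:`anova_from_summaries`), so the two routes cross-check each other.
    """
    if len(values_by_group) < 2:
        raise ValueError(f"need >= 2 groups, got {len(values_by_group)}")
    arrays = {}
    for label, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} has no observations")
        arrays[label] = arr
    all_values = np.concatenate(list(arrays.values()))
    total_n = all_values.size
    if total_n <= len(arrays):
        raise ValueError("need at least one group with n >= 2")
    grand = all_values.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))
    df_between = len(arrays) - 1
    df_within = total_n - len(arrays)
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = math.inf if ss_between > 0 else 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
    p_value = float(stats.f.sf(f_stat, df_between, df_within))
    denom = ss_between + ss_within
    eta_p2 = ss_between / denom if denom > 0 else 0.0
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        eta_p2=float(eta_p2),
        ss_between=ss_between,
        ss_within=ss_within,
    )


def tukey_kramer(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """All-pairs Tukey-Kramer comparisons from group sufficient statistics.

    For each pair, ``q = |mean_a - mean_b| / sqrt((MSw/2)(1/n_a + 1/n_b))``
    with MSw the pooled within-group mean square; the adjusted p comes from
    the studentized-range distribution with k groups and the pooled df.
    Singleton groups (e.g. template heads) are rejected: exclude them and
    run post hocs on the multi-subject factor only.  With k = 2 the
    procedure reduces to the pooled two-sample t-test.
    """
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups for post hoc comparisons, got {len(groups)}")
    singletons = [g.label for g in groups if g.n < 2]
    if singletons:
        raise ValueError(
            f"singleton groups {singletons} have no within-group variance; "
            "exclude template (n = 1) groups from post hoc comparisons"
        )
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    k = len(groups)
    df_within = sum(g.n - 1 for g in groups)
    ms_within = sum((g.n - 1) * g.sd**2 for g in groups) / df_within
    if ms_within == 0:
        raise ValueError("zero pooled within-group variance; comparisons undefined")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = math.sqrt(ms_within / 2.0 * (1.0 / a.n + 1.0 / b.n))
            diff = a.mean - b.mean
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
            out.append(
                PairwiseComparison(
                    group_a=a.label,
                    group_b=b.label,
                    diff=float(diff),
                    q_stat=float(q),
                    p_adj=p_adj,
                    significant=bool(p_adj < alpha),
                )
            )
    return out


def percent_difference(template_value: float, group_mean: float) -> float:
    """Percent by which a template-head value falls below the group mean.

    ``(group_mean - template_value) / group_mean * 100``; positive when the
    template under-estimates the group.
    """
    if group_mean <= 0:
        raise ValueError(f"group mean must be positive, got {group_mean}")
    return (group_mean - template_value) / group_mean * 100.0


def outliers_beyond_k_sd(
    values: Sequence[float],
    k: float = 2.0,
    labels: Sequence[str] | None = None,
) -> tuple[int, list[str]]:
    """Count values falling more than k sample SD from the sample mean.

    Mean and SD are computed from the same values.  Returns the count and
    the labels (indices as strings when no labels are given) of the
    flagged values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values, got {arr.size}")
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    flags = np.abs(arr - mean) > k * sd
    if labels is None:
        labels = [str(i) for i in range(arr.size)]
    flagged = [labels[i] for i in np.flatnonzero(flags)]
    return int(flags.sum()), flagged
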