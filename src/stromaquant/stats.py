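"""Group comparison: one-way ANOVA with Tukey HSD post-hoc tests.

The ANOVA is computed from first principles (between/within sums of
squares); pairwise comparisons use the studentized-range distribution with
the Tukey–Kramer correction for unequal group sizes.  Significance is
flagged at the conventional 0.05 (*) and 0.01 (**) levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class PairResult:
    group_1: str
    group_2: str
    mean_diff: float
    p_adjusted: float
    significant_05: bool
    significant_01: bool


@dataclass
class ComparisonResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairs: list[PairResult]

    def pair(self, g1: str, g2: str) -> PairResult:
        for p in self.pairs:
            if {p.group_1, p.group_2} == {g1, g2}:
                return p
        raise KeyError(f"no pair ({g1}, {g2})")


def anova_tukey(groups: dict[str, list | np.ndarray]) -> ComparisonResult:
    """One-way fixed-effects ANOVA plus all-pairs Tukey HSD.

    ``groups`` maps a label to its replicate measurements; at least two
    groups with at least two values each.  When every value in every group
    is identical there is nothing to test: F = 0, p = 1, no significant
    pair.  When groups differ but the within-group variance is exactly
    zero, F is infinite and all differing pairs are maximally significant.
    """
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=np.float64) for k in labels]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    for k, d in zip(labels, data):
        if d.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")

    ns = np.array([d.size for d in data])
    means = np.array([d.mean() for d in data])
    n_total = int(ns.sum())
    k = len(data)
    grand = float(np.concatenate(data).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((d - m) ** 2).sum() for d, m in zip(data, means)))
    df_b, df_w = k - 1, n_total - k

    if ss_within == 0 and ss_between == 0:
        f_stat, p_val = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_val = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_val = float(sps.f.sf(f_stat, df_b, df_w))

    ms_within = ss_within / df_w
    pairs: list[PairResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            if ms_within == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                # Tukey–Kramer standard error for unequal n
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q_obs = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q_obs, k, df_w))
            p_adj = min(max(p_adj, 0.0), 1.0)
            pairs.append(PairResult(
                group_1=labels[i], group_2=labels[j], mean_diff=diff,
                p_adjusted=p_adj,
                significant_05=p_adj < 0.05,
                significant_01=p_adj < 0.01,
            ))
    return ComparisonResult(
        f_statistic=f_stat, p_value=p_val,
        df_between=df_b, df_within=df_w, pairs=pairs,
    )
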