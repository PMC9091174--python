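"""Cohort statistics: one-way ANOVA, studentized-range post hoc tests, t-test.

The decompositions are written out explicitly (between/within sums of
squares; pooled-variance t) so the operations can be checked against
independent library implementations.  Post hoc comparisons use the
studentized-range distribution: Tukey(-Kramer) applies a single critical
value for all pairs, Student–Newman–Keuls (SNK) applies stepwise critical
values over the span of ordered means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedSamples",
    "one_way_anova",
    "posthoc",
    "ttest_unpaired",
    "significance_stars",
]


@dataclass
class GroupedSamples:
    """Labelled numeric observations, one array per group."""

    groups: dict[str, np.ndarray]

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.size < 2:
                raise ValueError(f"group {k!r} needs n >= 2")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


def _anova_decomposition(groups: GroupedSamples):
    data = list(groups.groups.values())
    all_vals = np.concatenate(data)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_between = len(data) - 1
    df_within = all_vals.size - len(data)
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups: GroupedSamples) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA; returns (F, df_between, df_within, p)."""
    ss_b, ss_w, df_b, df_w = _anova_decomposition(groups)
    if ss_w == 0:
        raise ValueError("zero within-group variance; F undefined")
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def _pairwise_q(groups: GroupedSamples):
    """Studentized-range statistics q_ij = |mean_i−mean_j| / sqrt(MSW/2·(1/ni+1/nj))."""
    _, ss_w, _, df_w = _anova_decomposition(groups)
    if ss_w == 0:
        raise ValueError("zero within-group variance")
    msw = ss_w / df_w
    means = {k: v.mean() for k, v in groups.groups.items()}
    ns = {k: v.size for k, v in groups.groups.items()}
    return means, ns, msw, df_w


def posthoc(groups: GroupedSamples, method: str = "tukey",
            alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise post hoc comparisons after ANOVA.

    ``method='tukey'``: Tukey(-Kramer) HSD — one critical value
    q(alpha, k, df) for all pairs, with adjusted p-values from the
    studentized-range distribution.  ``method='snk'``: Student–Newman–Keuls —
    means are ordered and each pair is tested at q(alpha, span, df) where
    span is the number of ordered means it encloses, with the usual stepwise
    protection (a pair inside a non-significant range is not declared
    significant).  Returns one row per pair: ``group_a, group_b, diff, q,
    p_adj, significant, stars``.
    """
    if method not in ("tukey", "snk"):
        raise ValueError("method must be 'tukey' or 'snk'")
    means, ns, msw, df_w = _pairwise_q(groups)
    k = len(means)
    labels = list(means)

    def qstat(a: str, b: str) -> float:
        se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        return abs(means[a] - means[b]) / se

    rows = []
    if method == "tukey":
        for a, b in itertools.combinations(labels, 2):
            q = qstat(a, b)
            p = float(sps.studentized_range.sf(q, k, df_w))
            rows.append((a, b, means[b] - means[a], q, p, p < alpha))
    else:
        order = sorted(labels, key=lambda g: means[g])
        rank = {g: i for i, g in enumerate(order)}
        # stepwise: test ranges from widest span inward; an inner pair is
        # blocked if any enclosing range was non-significant
        sig: dict[tuple[str, str], tuple[float, float, bool]] = {}
        blocked: set[tuple[int, int]] = set()
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                a, b = order[i], order[j]
                q = qstat(a, b)
                p = float(sps.studentized_range.sf(q, span, df_w))
                is_sig = p < alpha and (i, j) not in blocked
                if not is_sig:
                    for ii in range(i, j + 1):
                        for jj in range(ii + 1, j + 1):
                            blocked.add((ii, jj))
                sig[(a, b)] = (q, p, is_sig)
        for a, b in itertools.combinations(labels, 2):
            key = (a, b) if rank[a] < rank[b] else (b, a)
            q, p, is_sig = sig[key]
            rows.append((a, b, means[b] - means[a], q, p, is_sig))

    df = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "q",
                                     "p_adj", "significant"])
    df["stars"] = df["p_adj"].map(significance_stars)
    return df


def ttest_unpaired(a, b) -> tuple[float, int, float]:
    """Two-tailed pooled-variance (Student's) unpaired t-test: (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per sample")
    df = a.size + b.size - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance; t undefined")
    se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    t = (a.mean() - b.mean()) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), int(df), p


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
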