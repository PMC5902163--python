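"""Group comparisons with the standard tests used for this kind of data.

Two groups: Student's t-test or the Mann-Whitney U test (exact null
distribution for small samples without ties). Three or more groups:
one-way ANOVA followed by pairwise post-hoc comparisons with Holm-Sidak
adjustment. Summaries are reported as mean +/- SEM per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["GroupComparison", "PosthocPair", "compare"]

_EXACT_MAX_N = 20


@dataclass(frozen=True)
class PosthocPair:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class GroupComparison:
    metric: str
    group_labels: list[str]
    n: list[int]
    means: list[float]
    sems: list[float]
    test: str
    statistic: float
    p_value: float
    posthoc: list[PosthocPair] = field(default_factory=list)


def _mann_whitney(a: np.ndarray, b: np.ndarray):
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare(
    groups: Mapping[str, Sequence[float]],
    test: str = "mann_whitney",
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare labelled value lists with the named test.

    ``test`` is one of "t_test", "mann_whitney" (two groups) or
    "anova_holm_sidak" (three or more groups; pairwise post-hoc t-tests
    with Holm-Sidak adjusted p-values).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if a.size == 0:
            raise ValidationError(f"group {k!r} is empty")
        if a.size < 2:
            raise ValidationError(f"group {k!r} needs n >= 2")
    n = [int(a.size) for a in arrays]
    means = [float(a.mean()) for a in arrays]
    sems = [float(sps.sem(a)) for a in arrays]
    posthoc: list[PosthocPair] = []

    if test in ("t_test", "mann_whitney"):
        if len(arrays) != 2:
            raise ValidationError(f"{test} requires exactly 2 groups, got {len(arrays)}")
        if test == "t_test":
            res = sps.ttest_ind(arrays[0], arrays[1])
            statistic, p = float(res.statistic), float(res.pvalue)
        else:
            statistic, p = _mann_whitney(arrays[0], arrays[1])
    elif test == "anova_holm_sidak":
        if len(arrays) < 3:
            raise ValidationError("anova_holm_sidak requires >= 3 groups")
        res = sps.f_oneway(*arrays)
        statistic, p = float(res.statistic), float(res.pvalue)
        pairs, raw_p, stats_ = [], [], []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                r = sps.ttest_ind(arrays[i], arrays[j])
                pairs.append((labels[i], labels[j]))
                raw_p.append(float(r.pvalue))
                stats_.append(float(r.statistic))
        reject, p_adj, _, _ = multipletests(raw_p, alpha=alpha, method="holm-sidak")
        posthoc = [
            PosthocPair(pair=pr, statistic=s, p_adjusted=float(pa), significant=bool(rj))
            for pr, s, pa, rj in zip(pairs, stats_, p_adj, reject)
        ]
    else:
        raise ValidationError(
            f"unknown test {test!r}; use t_test, mann_whitney or anova_holm_sidak"
        )
    return GroupComparison(
        metric=metric,
        group_labels=labels,
        n=n,
        means=means,
        sems=sems,
        test=test,
        statistic=statistic,
        p_value=p,
        posthoc=posthoc,
    )
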