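"""Two-group nonparametric comparison with Bonferroni correction.

"Wilcoxon test" for two independent groups is implemented as the rank-sum
(Mann–Whitney U) variant — the signed-rank form is inapplicable to unpaired
samples.  Tests are two-sided throughout; exact enumeration is used for
small tie-free samples (combined n <= 12), a tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "ranksum_test", "bonferroni", "compare_measures"]


def ranksum_test(values_group1, values_group2) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic, p).

    All-identical samples across both groups give p = 1 by convention.
    """
    x = np.asarray(values_group1, dtype=float)
    y = np.asarray(values_group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-corrected p-values and significance flags.

    The family size is the length of ``p_values``; ``p_corr = min(1, m*p)``
    and a comparison is significant when ``p_corr < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("empty p-value family")
    p_corr = np.minimum(1.0, p.size * p)
    return p_corr, p_corr < alpha


@dataclass
class GroupComparison:
    measure: str
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    statistic: float
    p: float
    p_corrected: float
    family_size: int
    significant: bool


def compare_measures(
    group1: dict[str, np.ndarray],
    group2: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare every named measure between groups, correcting over the family.

    ``group1`` and ``group2`` map measure ids (e.g. ``total_weight:TfO``)
    to per-subject value vectors; the correction family is the full set of
    shared measure ids, recorded in the output.
    """
    measures = [m for m in group1 if m in group2]
    if not measures:
        raise ValueError("no shared measures between the two groups")
    rows = []
    for m in measures:
        x, y = np.asarray(group1[m], float), np.asarray(group2[m], float)
        stat, p = ranksum_test(x, y)
        rows.append((m, x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1), stat, p))
    p_corr, sig = bonferroni([r[-1] for r in rows], alpha=alpha)
    records = [
        GroupComparison(
            measure=r[0], mean1=r[1], sd1=r[2], mean2=r[3], sd2=r[4],
            statistic=r[5], p=r[6], p_corrected=float(pc),
            family_size=len(rows), significant=bool(s),
        )
        for r, pc, s in zip(rows, p_corr, sig)
    ]
    return pd.DataFrame([vars(r) for r in records])
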