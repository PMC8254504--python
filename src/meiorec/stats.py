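"""Normality-gated two-group comparison.

Continuous measurements (foci counts, spot counts, distances, ...) are
compared between two groups by an unpaired two-tailed Student t test
when both samples are compatible with a Gaussian (D'Agostino-Pearson
omnibus K2 test at ``alpha``), and by an unpaired two-tailed
Mann-Whitney U test otherwise.  K2 needs a minimum sample size to be
defined, so groups smaller than 8 default to Mann-Whitney.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "compare_groups"]

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"
_K2_MIN_N = 8


@dataclass
class GroupComparison:
    test_used: str  # "t_test" or "mann_whitney"
    statistic: float
    p_value: float
    normality_p_a: float | None
    normality_p_b: float | None
    n_a: int
    n_b: int


def compare_groups(a, b, alpha_normality: float = 0.05) -> GroupComparison:
    """Compare two samples with the test selected by K2 normality screening.

    Both samples pass K2 at ``alpha_normality`` and have n >= 8: Student
    t test (equal variances, two-tailed).  Otherwise: Mann-Whitney U
    (two-tailed; exact for small tie-free samples, normal approximation
    with tie correction otherwise, scipy's default policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    p_norm_a = p_norm_b = None
    use_t = False
    if a.size >= _K2_MIN_N and b.size >= _K2_MIN_N:
        p_norm_a = float(stats.normaltest(a).pvalue)
        p_norm_b = float(stats.normaltest(b).pvalue)
        use_t = p_norm_a > alpha_normality and p_norm_b > alpha_normality
    if use_t:
        res = stats.ttest_ind(a, b, equal_var=True, alternative="two-sided")
        test = T_TEST
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        test = MANN_WHITNEY
    return GroupComparison(
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p_a=p_norm_a,
        normality_p_b=p_norm_b,
        n_a=int(a.size),
        n_b=int(b.size),
    )
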