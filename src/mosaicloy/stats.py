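"""Rank-based group comparisons and correlation analyses.

Pairwise comparisons of per-patient (or per-cell) %LOY use the unpaired
two-sided Wilcoxon rank-sum test with Bonferroni adjustment over all
pairs in one comparison family.  The exact null distribution is used for
small tie-free samples and the tie-corrected normal approximation with
continuity correction otherwise, mirroring the behaviour of the
conventional R default.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .io import ValidationError

logger = logging.getLogger("mosaicloy")

#: Largest min(n_a, n_b) for which the exact rank-sum null is enumerated.
EXACT_MAX_N = 25


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided unpaired rank-sum (Mann-Whitney) test.

    Returns the Mann-Whitney U statistic of the first sample and the
    two-sided p-value.  Exact when both samples are small
    (min(n) <= 25) and the pooled data has no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, p * family_size)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    family_size = p.size if family_size is None else int(family_size)
    if family_size < p.size:
        raise ValidationError("family_size must be at least the number of p-values")
    return np.minimum(1.0, p * family_size)


def pairwise_compare(groups: dict) -> pd.DataFrame:
    """All unordered pairwise rank-sum tests within one comparison family.

    ``groups`` maps a label to its sample of values.  The Bonferroni
    family is the number of pairs; rows are ordered lexicographically by
    the pair labels.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValidationError("pairwise comparison needs at least two groups")
    for lab in labels:
        if len(np.atleast_1d(groups[lab])) == 0:
            raise ValidationError(f"group {lab!r} is empty")
    pairs = list(itertools.combinations(labels, 2))
    family = len(pairs)
    rows = []
    for ga, gb in pairs:
        a = np.asarray(groups[ga], dtype=float)
        b = np.asarray(groups[gb], dtype=float)
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {"group_a": ga, "group_b": gb, "n_a": a.size, "n_b": b.size,
             "statistic": stat, "p_raw": p}
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = bonferroni_adjust(table["p_raw"].to_numpy(), family)
    table["family_size"] = family
    logger.info("pairwise comparison: %d groups, %d pairs", len(labels), family)
    return table


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with the t-based two-sided p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples must have equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
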