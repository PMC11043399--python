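"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force (enumeration,
per-cell loops) rather than calling the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def enumerate_rank_sum_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Assumes no ties in the pooled sample.  p = min(1, 2 * min(P(U <= u),
    P(U >= u))) under the permutation null.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    m = len(a)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in a) - m * (m + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), m):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - m * (m + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def pearson_from_definition(x, y) -> float:
    """Product-moment r straight from the defining sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den


def brute_force_module_score(
    X: pd.DataFrame, module_genes, n_bins: int, n_ctrl: int,
    exclude_module_from_ctrl: bool, seed: int,
) -> np.ndarray:
    """Loop-based reimplementation of the documented module-score contract.

    (1) per-gene mean over cells; (2) genes ordered by (mean, symbol) and
    split into n_bins bins with numpy.array_split; (3) per retained module
    gene, in sorted-symbol order, draw n_ctrl controls with replacement
    from the symbol-sorted bin candidates via
    default_rng(seed).choice(len(candidates), n_ctrl); (4) per-cell score
    = mean over module genes - mean over pooled draw.
    """
    module = sorted({g.upper() for g in module_genes} & set(X.columns))
    means = {g: sum(X[g]) / len(X) for g in X.columns}
    order = sorted(X.columns, key=lambda g: (means[g], g))
    bins = [list(chunk) for chunk in np.array_split(np.array(order, dtype=object), n_bins)]
    rng = np.random.default_rng(seed)
    pooled = []
    for gene in module:
        bin_members = next(sorted(b) for b in bins if gene in b)
        candidates = [g for g in bin_members if g not in module] \
            if exclude_module_from_ctrl else bin_members
        if not candidates:
            candidates = bin_members
        idx = rng.choice(len(candidates), size=n_ctrl, replace=True)
        pooled.extend(candidates[i] for i in idx)
    scores = []
    for _, row in X.iterrows():
        module_mean = sum(row[g] for g in module) / len(module)
        ctrl_mean = sum(row[g] for g in pooled) / len(pooled)
        scores.append(module_mean - ctrl_mean)
    return np.array(scores)


def random_expression_frame(rng: np.random.Generator, n_genes: int, n_cells: int) -> pd.DataFrame:
    """Small random normalized-expression frame with distinct gene symbols."""
    genes = [f"G{i:03d}" for i in range(n_genes)]
    values = rng.gamma(shape=1.0, scale=1.0, size=(n_cells, n_genes))
    return pd.DataFrame(values, columns=genes,
                        index=[f"c{i}" for i in range(n_cells)])
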