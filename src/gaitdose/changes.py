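"""Percent-normalized-change scores and montage comparison.

Pre/post intervention effects are expressed as the bounded change score

    change = (POST - PRE) * 100 / (POST + PRE)

and the two stimulation montages are compared per gait parameter with a
two-sided Wilcoxon rank-sum test.  For small untied samples the p-value is
exact — computed from the full null distribution of the rank sum — which
is the regime the typical 10-subjects-per-montage crossover lands in; ties
or larger samples fall back to the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

from .indices import InvalidInputError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 20  # combined size up to which the untied exact test is used


class UndefinedChangeError(ValueError):
    """PRE + POST = 0: the normalized change score has no value."""


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of group A (midranks)
    p_value: float
    n_a: int
    n_b: int
    method: str  # exact | normal_approximation

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def percent_normalized_change(pre: float, post: float) -> float:
    """Bounded pre→post change: ``(post - pre) * 100 / (post + pre)``.

    Antisymmetric under swapping pre and post, invariant under common
    rescaling, and confined to (−100, 100) whenever both values are
    positive.
    """
    denom = pre + post
    if denom == 0:
        raise UndefinedChangeError("pre + post is zero; change undefined")
    return (post - pre) * 100.0 / denom


def build_change_table(
    pre: pd.DataFrame,
    post: pd.DataFrame,
) -> pd.DataFrame:
    """Elementwise change table from aligned pre/post parameter tables.

    Rows are subject × montage observations, columns gait parameters.
    Cells where the score is undefined (or either input missing) are NaN.
    """
    post = post.reindex(index=pre.index, columns=pre.columns)
    denom = pre + post
    with np.errstate(divide="ignore", invalid="ignore"):
        table = (post - pre) * 100.0 / denom
    return table.mask(denom == 0)


@lru_cache(maxsize=None)
def _ranksum_null_counts(n_a: int, n_b: int) -> tuple[np.ndarray, int]:
    """Null distribution of the rank sum of group A over untied ranks 1..N.

    Returns ``(counts, min_sum)``: ``counts[w - min_sum]`` is the number of
    the C(N, n_a) equally likely rank assignments with rank sum ``w``.
    Computed by dynamic programming over ranks.
    """
    n = n_a + n_b
    min_sum = n_a * (n_a + 1) // 2
    max_sum = n_a * (n_a + 2 * n_b + 1) // 2
    # table[k][s]: number of k-subsets of processed ranks with sum s
    table = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            table[k, rank:] += table[k - 1, :-rank]
    counts = table[n_a, min_sum:max_sum + 1].copy()
    return counts, min_sum


def ranksum_test(group_a, group_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    The statistic is the rank sum of ``group_a`` using midranks for ties.
    With combined size ≤ 20 and no ties, the two-sided p-value is exact:
    twice the smaller tail of the enumerated null distribution, capped at
    1.  Otherwise the normal approximation with tie correction and a 0.5
    continuity correction is used; the method applied is recorded.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    # midranks: average rank within each tied block
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    w = float(ranks[:n_a].sum())
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_MAX_N and not has_ties:
        counts, min_sum = _ranksum_null_counts(n_a, n_b)
        total = counts.sum()
        idx = int(round(w)) - min_sum
        lower = counts[: idx + 1].sum() / total
        upper = counts[idx:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankSumResult(w, p, n_a, n_b, "exact")

    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return RankSumResult(w, 1.0, n_a, n_b, "normal_approximation")
    z = max(0.0, abs(w - mean) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return RankSumResult(w, p, n_a, n_b, "normal_approximation")


def compare_montages(
    changes: pd.DataFrame,
    montage_a: str = "dentate",
    montage_b: str = "leg",
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Rank-sum comparison of the two montages' change scores per parameter.

    ``changes`` carries a (subject, montage) row MultiIndex and one column
    per gait parameter.  One two-sided test per parameter; parameters with
    an empty group are skipped with a warning.  By default no multiplicity
    correction is applied across parameters; ``correction='bh'`` adds
    Benjamini–Hochberg adjusted p-values and flags on those instead.
    """
    if "montage" not in (changes.index.names or []):
        raise InvalidInputError("changes index must include a 'montage' level")
    montages = set(changes.index.get_level_values("montage"))
    for m in (montage_a, montage_b):
        if m not in montages:
            raise InvalidInputError(f"montage {m!r} absent from change table")

    rows = []
    for param in changes.columns:
        col = changes[param]
        a = col.xs(montage_a, level="montage").dropna().to_numpy()
        b = col.xs(montage_b, level="montage").dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            logger.warning("parameter %s lacks data in one montage; skipped", param)
            continue
        res = ranksum_test(a, b)
        rows.append({
            "parameter": param,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "n_a": res.n_a,
            "n_b": res.n_b,
            "method": res.method,
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    if correction == "bh":
        p = result["p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        result["p_adjusted"] = adj
        result["significant"] = result["p_adjusted"] < alpha
    elif correction is None:
        result["significant"] = result["p_value"] < alpha
    else:
        raise InvalidInputError(f"unknown correction {correction!r}")
    return result
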