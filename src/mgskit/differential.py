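"""Two-group differential abundance: Wilcoxon rank-sum + Benjamini-Hochberg.

The rank-sum test runs in exact mode (full enumeration of the null
distribution of the rank sum over all group assignments, average ranks
for ties) for small samples, and otherwise uses the normal approximation
with tie and continuity correction.  Significance is called at a
configurable q threshold (default q < 0.001).
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceMatrix, CohortLabels

__all__ = ["rank_sum_test", "bh_adjust", "differential_features"]

logger = logging.getLogger(__name__)

TIE = "tie"

#: largest min(n, m) for which exact enumeration is attempted automatically
EXACT_MAX = 8


def _exact_rank_sum_p(pooled_ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p for the group-A rank sum by full enumeration.

    Enumerates all C(N, n_a) assignments of the pooled (average) ranks
    to group A; p is the fraction with |S - E[S]| >= |S_obs - E[S]|.
    Works with ties because the ranks themselves are permuted.
    """
    from itertools import combinations

    n = len(pooled_ranks)
    mu = n_a * (n + 1) / 2.0  # sum of average ranks is always N(N+1)/2
    s_obs = pooled_ranks[:n_a].sum()
    dev = abs(s_obs - mu) - 1e-12
    hits = sum(
        1
        for idx in combinations(range(n), n_a)
        if abs(pooled_ranks[list(idx)].sum() - mu) >= dev
    )
    return hits / comb(n, n_a)


def rank_sum_test(
    values_a, values_b, method: str = "auto"
) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(p, direction)`` where direction is ``"a"``/``"b"`` for the
    group with the higher mean rank, or ``"tie"``.  ``method`` is
    ``"auto"`` (exact when min(n, m) <= 8 and the pooled data are
    tie-free, else asymptotic), ``"exact"`` (enumeration, ties allowed)
    or ``"asymptotic"``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mean_rank_a = ranks[: a.size].mean()
    mean_rank_b = ranks[a.size :].mean()
    if mean_rank_a > mean_rank_b:
        direction = "a"
    elif mean_rank_b > mean_rank_a:
        direction = "b"
    else:
        direction = TIE

    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (min(a.size, b.size) <= EXACT_MAX and not has_ties) else "asymptotic"
    if method == "exact":
        p = _exact_rank_sum_p(ranks, a.size)
    elif method == "asymptotic":
        if np.unique(pooled).size == 1:
            return 1.0, TIE
        p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(p, 1.0)), direction


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over ascending p, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_features(
    abund: AbundanceMatrix,
    labels: CohortLabels,
    q_threshold: float = 0.001,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-feature rank-sum test with BH correction and direction calls.

    Features that are zero in every sample are untestable and dropped
    before the correction denominator is counted (the drop is logged).
    Returns a DataFrame indexed by feature with columns ``p_value``,
    ``q_value``, ``direction`` (group label with higher mean rank, or
    ``"tie"``) and ``significant`` (q < ``q_threshold``).
    """
    g_a, g_b = labels.two_groups()
    missing = set(abund.sample_ids) - set(labels.labels.index)
    if missing:
        raise ValueError(f"sample(s) without cohort label: {sorted(missing)[:5]}")
    mat = abund.values
    cols_a = [s for s in mat.columns if labels.labels[s] == g_a]
    cols_b = [s for s in mat.columns if labels.labels[s] == g_b]
    x_a = mat[cols_a].to_numpy(dtype=float)
    x_b = mat[cols_b].to_numpy(dtype=float)

    nonzero = (x_a.sum(axis=1) + x_b.sum(axis=1)) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero feature(s) before testing", n_dropped)
    x_a, x_b = x_a[nonzero], x_b[nonzero]
    features = mat.index[nonzero]
    if len(features) == 0:
        raise ValueError("no testable (non-zero) features")

    n_a, n_b = x_a.shape[1], x_b.shape[1]
    pooled = np.hstack([x_a, x_b])
    ranks = stats.rankdata(pooled, axis=1)
    mean_a = ranks[:, :n_a].mean(axis=1)
    mean_b = ranks[:, n_a:].mean(axis=1)
    direction = np.where(mean_a > mean_b, g_a, np.where(mean_b > mean_a, g_b, TIE))

    constant = np.ptp(pooled, axis=1) == 0
    if method == "asymptotic" or (method == "auto" and min(n_a, n_b) > EXACT_MAX):
        # vectorised normal-approximation path (tie + continuity corrected)
        p = np.ones(len(features))
        if np.any(~constant):
            p[~constant] = stats.mannwhitneyu(
                x_a[~constant],
                x_b[~constant],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
                axis=1,
            ).pvalue
    else:
        p = np.empty(len(features))
        for i in range(len(features)):
            p[i], _ = rank_sum_test(x_a[i], x_b[i], method=method)
    p = np.minimum(p, 1.0)

    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": q < q_threshold,
        },
        index=pd.Index(features, name="feature_id"),
    )
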