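"""Permutation tests for group comparisons and Kendall rank correlation.

Group comparisons operate on collections of pairwise dissimilarity values
(e.g. beta_J per site pair, grouped by vent system).  Because pairwise
values within a system share sites they are not independent observations;
the permutation machinery is still well defined, but p-values should be
read as descriptive of the exchangeability hypothesis on the pooled values
rather than as strict tests on independent replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PermutationTestResult",
    "perm_anova",
    "perm_t_test",
    "kendall_tau",
]


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    group_labels: tuple[str, ...]
    statistic_name: str = ""


def _f_statistic(values: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for s, k in zip(starts, sizes):
        g = values[s : s + k]
        m = g.mean()
        ss_between += k * (m - grand) ** 2
        ss_within += ((g - m) ** 2).sum()
    df_b = sizes.size - 1
    df_w = values.size - sizes.size
    if ss_within == 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def perm_anova(
    groups: Sequence[Sequence[float]],
    n_perm: int = 9999,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> PermutationTestResult:
    """One-way permutation ANOVA on the F statistic.

    The null distribution comes from randomly reassigning the pooled values
    to groups of the original sizes; ``p = (1 + #{F_null >= F_obs}) /
    (1 + n_perm)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        raise ValueError("every group needs at least 2 values")
    if seed is None:
        raise ValueError("a seed is required for reproducible inference")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    f_obs = _f_statistic(values, starts, sizes)
    # canonical order makes the null stream invariant to input value order
    values = np.sort(values)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if _f_statistic(perm, starts, sizes) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    labels = tuple(labels) if labels else tuple(f"g{i}" for i in range(len(groups)))
    return PermutationTestResult(float(f_obs), p, n_perm, seed, labels, "F")


def perm_t_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> PermutationTestResult:
    """Two-sample, two-sided permutation t-test (pooled-variance t).

    Labels are permuted between the samples; the null counts replicates with
    ``|t_null| >= |t_obs|``.  Two zero-variance samples with equal means give
    t = 0 and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if seed is None:
        raise ValueError("a seed is required for reproducible inference")

    def t_stat(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = a.size, b.size
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
        if sp2 == 0:
            return 0.0 if a.mean() == b.mean() else math.inf
        return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))

    t_obs = t_stat(x, y)
    pooled = np.sort(np.concatenate([x, y]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(t_stat(perm[: x.size], perm[x.size :])) >= abs(t_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermutationTestResult(float(t_obs), p, n_perm, seed, tuple(labels), "t")


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with a two-sided p-value.

    The p-value uses exact enumeration for n <= 9 without ties, otherwise
    the normal approximation on the concordance score S with tie-corrected
    variance and a continuity correction (the convention of R's
    ``cor.test(..., method="kendall", continuity=TRUE)``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("tau undefined for a constant vector")

    tau = float(stats.kendalltau(x, y).statistic)

    has_ties = np.unique(x).size < n or np.unique(y).size < n
    if n <= 9 and not has_ties:
        # exact null: S = C - D = n(n-1)/2 - 2*inversions, inversion counts
        # from the Mahonian generating function prod_i (1 + q + ... + q^(i-1))
        s_obs = _concordance_score(x, y)
        counts = np.array([1], dtype=object)
        for i in range(2, n + 1):
            counts = np.convolve(counts, np.ones(i, dtype=object))
        m = n * (n - 1) // 2
        s_values = m - 2 * np.arange(counts.size)
        mask = np.abs(s_values) >= abs(s_obs) - 1e-9
        total = math.factorial(n)
        return tau, float(sum(counts[mask]) / total)

    s_obs = _concordance_score(x, y)
    var_s = _tie_corrected_var(x, y)
    if var_s <= 0:
        return tau, 1.0
    z = (abs(s_obs) - 1.0) / math.sqrt(var_s) if abs(s_obs) > 1 else 0.0
    p = 2 * stats.norm.sf(z)
    return tau, min(1.0, float(p))


def _concordance_score(x: np.ndarray, y: np.ndarray) -> float:
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    return float((sx * sy)[np.triu_indices(len(x), k=1)].sum())


def _tie_corrected_var(x: np.ndarray, y: np.ndarray) -> float:
    """Variance of S under the null with tie corrections (tau-b)."""
    n = len(x)

    def tie_terms(v: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(v, return_counts=True)
        t = counts[counts > 1].astype(float)
        return (
            float((t * (t - 1) * (2 * t + 5)).sum()),
            float((t * (t - 1) * (t - 2)).sum()),
            float((t * (t - 1)).sum()),
        )

    x1, x2, x3 = tie_terms(x)
    y1, y2, y3 = tie_terms(y)
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - x1 - y1) / 18.0
    var += x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
    var += x3 * y3 / (2.0 * n * (n - 1))
    return var
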