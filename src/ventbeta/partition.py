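"""Pairwise partitioning of incidence-based beta diversity.

For a pair of sites with ``a`` shared species, ``b`` unique to the first and
``c`` unique to the second (``n = a + b + c``), the Jaccard-family pairwise
pattern components are

* overlap          ``O = a / n``
* replacement      ``R = 2 * min(b, c) / n``
* richness diff.   ``D = |b - c| / n``

which sum to 1 and locate the pair on a ternary (simplex) plot.  Beta
diversity is ``beta = 1 - O = R + D`` and nestedness ``N = O + D`` (0 when
the pair shares nothing).  Beta diversity further splits into the
intersection with nestedness, ``I`` (equal to D when a > 0, else 0), and its
relative complement ``RC = beta - I``; ``beta_ratio = I / beta`` tells
whether richness difference (> 0.5) or replacement (< 0.5) dominates the
dissimilarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .incidence import IncidenceMatrix

__all__ = [
    "PairwiseDecomposition",
    "decompose_pair",
    "decompose_counts",
    "decompose_all",
    "summarize_decomposition",
    "whittaker_ratio",
    "whittaker_from_alpha",
    "ternary_coordinates",
    "beta_j_matrix",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class PairwiseDecomposition:
    """All relativized components for one unordered site pair."""

    site_i: str
    site_j: str
    a: int
    b: int
    c: int
    o_j: float
    r_j: float
    d_j: float
    beta_j: float
    n_j: float
    i_j: float
    rc_j: float
    beta_ratio: float  # NaN when beta_j == 0 (identical sites)


def decompose_counts(site_i: str, site_j: str, a: int, b: int, c: int) -> PairwiseDecomposition:
    """Components from the raw (a, b, c) counts of a site pair."""
    if min(a, b, c) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c
    if n == 0:
        raise ValueError(f"pair ({site_i!r}, {site_j!r}): both sites empty")
    o = a / n
    r = 2 * min(b, c) / n
    d = abs(b - c) / n
    beta = (b + c) / n
    if a > 0:
        n_j = (a + abs(b - c)) / n
        i_j = d
    else:
        n_j = 0.0
        i_j = 0.0
    rc = beta - i_j
    ratio = i_j / beta if beta > 0 else math.nan
    return PairwiseDecomposition(
        site_i, site_j, a, b, c, o, r, d, beta, n_j, i_j, rc, ratio
    )


def decompose_pair(
    x: Iterable[str], y: Iterable[str], site_i: str = "i", site_j: str = "j"
) -> PairwiseDecomposition:
    """Components for two explicit species sets."""
    xs, ys = set(x), set(y)
    return decompose_counts(
        site_i, site_j, len(xs & ys), len(xs - ys), len(ys - xs)
    )


def decompose_all(matrix: IncidenceMatrix) -> list[PairwiseDecomposition]:
    """All n(n-1)/2 pairwise decompositions, in lexicographic site order."""
    if matrix.n_sites < 2:
        raise ValueError("pairwise decomposition needs at least 2 sites")
    occ = matrix.occupancy
    shared = (occ.astype(np.int64) @ occ.T.astype(np.int64))
    alpha = occ.sum(axis=1)
    out = []
    for i, j in combinations(range(matrix.n_sites), 2):
        a = int(shared[i, j])
        out.append(
            decompose_counts(
                matrix.site_ids[i],
                matrix.site_ids[j],
                a,
                int(alpha[i]) - a,
                int(alpha[j]) - a,
            )
        )
    return out


def summarize_decomposition(
    pairs: Sequence[PairwiseDecomposition],
) -> pd.DataFrame:
    """Mean/median/min/max of each component over the pairs.

    ``beta_ratio`` statistics are over defined (non-NaN) values only.
    Returns a DataFrame indexed by component.
    """
    if not pairs:
        raise ValueError("no pairs to summarize")
    rows = {}
    for comp in ("o_j", "r_j", "d_j", "beta_j", "n_j", "i_j", "rc_j", "beta_ratio"):
        vals = np.array([getattr(p, comp) for p in pairs], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size:
            rows[comp] = {
                "mean": vals.mean(),
                "median": float(np.median(vals)),
                "min": vals.min(),
                "max": vals.max(),
                "n": vals.size,
            }
        else:
            rows[comp] = {
                "mean": math.nan, "median": math.nan,
                "min": math.nan, "max": math.nan, "n": 0,
            }
    return pd.DataFrame(rows).T


def whittaker_ratio(matrix: IncidenceMatrix) -> float:
    """Whittaker's multiplicative beta: gamma / mean(alpha)."""
    alpha = matrix.site_richness()
    if alpha.sum() == 0:
        raise ValueError("all sites empty; Whittaker ratio undefined")
    return matrix.gamma() / alpha.mean()


def whittaker_from_alpha(alpha: Iterable[float], gamma: float) -> float:
    """Whittaker ratio from published per-site richness and gamma."""
    alpha = np.asarray(list(alpha), dtype=float)
    if alpha.size == 0 or alpha.mean() == 0:
        raise ValueError("need at least one non-empty site")
    return float(gamma / alpha.mean())


# 2-D vertices of the simplex triangle used for plotting: O at the
# lower-right vertex, R at the lower-left, D at the apex.
_V_O = np.array([1.0, 0.0])
_V_R = np.array([0.0, 0.0])
_V_D = np.array([0.5, math.sqrt(3) / 2])


def ternary_coordinates(
    pairs: Sequence[PairwiseDecomposition],
) -> pd.DataFrame:
    """Barycentric (O, R, D) triples and their 2-D simplex projection."""
    rows = []
    for p in pairs:
        xy = p.o_j * _V_O + p.r_j * _V_R + p.d_j * _V_D
        rows.append(
            {
                "site_i": p.site_i,
                "site_j": p.site_j,
                "o_j": p.o_j,
                "r_j": p.r_j,
                "d_j": p.d_j,
                "x": xy[0],
                "y": xy[1],
            }
        )
    return pd.DataFrame(
        rows, columns=["site_i", "site_j", "o_j", "r_j", "d_j", "x", "y"]
    )


def beta_j_matrix(matrix: IncidenceMatrix) -> pd.DataFrame:
    """Square symmetric Jaccard dissimilarity (beta_J) matrix."""
    n = matrix.n_sites
    D = np.zeros((n, n))
    for p in decompose_all(matrix):
        i = matrix.site_ids.index(p.site_i)
        j = matrix.site_ids.index(p.site_j)
        D[i, j] = D[j, i] = p.beta_j
    return pd.DataFrame(D, index=matrix.site_ids, columns=matrix.site_ids)


def pairs_to_frame(pairs: Sequence[PairwiseDecomposition]) -> pd.DataFrame:
    """Tabulate decompositions (one row per pair) for CSV export."""
    return pd.DataFrame([p.__dict__ for p in pairs])
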