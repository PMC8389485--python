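"""Minimum-set site coverage and group-structured pair bookkeeping.

The minimum set is the smallest combination of sites whose pooled species
list equals the system's gamma diversity — the classic (unweighted) reserve
selection question.  All minimal solutions are enumerated so planners can
weigh alternatives.  ``group_overlap`` and ``subset_pairs`` support
combined-region analyses where sites carry system labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .incidence import IncidenceMatrix

__all__ = ["MinSetResult", "minimum_set", "greedy_cover", "group_overlap", "subset_pairs"]

EXACT_SITE_LIMIT = 25


@dataclass(frozen=True)
class MinSetResult:
    min_size: int
    solutions: tuple[tuple[str, ...], ...]  # all minimal covering site sets
    coverage_fraction: float  # min_size / n_sites
    exact: bool = True


def _bit_columns(matrix: IncidenceMatrix) -> tuple[list[int], int]:
    """Per-site species bitmask and the full-coverage target mask.

    Species occupying no site are excluded (with a warning) since no site
    set can cover them.
    """
    freq = matrix.species_frequency()
    empty = int((freq == 0).sum())
    if empty:
        warnings.warn(
            f"{empty} species occupy no site and are excluded from coverage",
            stacklevel=3,
        )
    cols = np.flatnonzero(freq > 0)
    masks = []
    for row in matrix.occupancy:
        m = 0
        for k, j in enumerate(cols):
            if row[j]:
                m |= 1 << k
        masks.append(m)
    return masks, (1 << len(cols)) - 1


def minimum_set(matrix: IncidenceMatrix) -> MinSetResult:
    """Exact minimum cover by exhaustive search over subset sizes ascending.

    All minimal solutions are reported.  Beyond ``EXACT_SITE_LIMIT`` sites
    the exact search is refused; use :func:`greedy_cover`.
    """
    if matrix.gamma() < 1:
        raise ValueError("no species to cover")
    if matrix.n_sites > EXACT_SITE_LIMIT:
        raise ValueError(
            f"{matrix.n_sites} sites exceeds the exact-search bound "
            f"({EXACT_SITE_LIMIT}); use greedy_cover"
        )
    masks, target = _bit_columns(matrix)
    n = matrix.n_sites
    for size in range(1, n + 1):
        sols = [
            tuple(matrix.site_ids[i] for i in combo)
            for combo in combinations(range(n), size)
            if _union(masks, combo) == target
        ]
        if sols:
            return MinSetResult(size, tuple(sols), size / n, exact=True)
    raise AssertionError("unreachable: all sites together always cover")


def _union(masks: list[int], combo: tuple[int, ...]) -> int:
    m = 0
    for i in combo:
        m |= masks[i]
    return m


def greedy_cover(matrix: IncidenceMatrix) -> MinSetResult:
    """Greedy set-cover heuristic (largest marginal gain, lowest index first).

    Returns a single solution flagged ``exact=False``; its size is an upper
    bound on the true minimum.
    """
    if matrix.gamma() < 1:
        raise ValueError("no species to cover")
    masks, target = _bit_columns(matrix)
    chosen: list[int] = []
    covered = 0
    while covered != target:
        best = max(
            range(len(masks)),
            key=lambda i: (bin(covered | masks[i]).count("1"), -i),
        )
        chosen.append(best)
        covered |= masks[best]
    sites = tuple(matrix.site_ids[i] for i in sorted(chosen))
    return MinSetResult(
        len(sites), (sites,), len(sites) / matrix.n_sites, exact=False
    )


def group_overlap(
    matrix: IncidenceMatrix, groups: Mapping[str, str]
) -> dict:
    """Species sharing between exactly two site groups.

    Returns per-group gamma, the shared species list and count, and the
    shared fraction of the combined gamma.
    """
    missing = [s for s in matrix.site_ids if s not in groups]
    if missing:
        raise ValueError(f"sites without group label: {missing}")
    labels = sorted(set(groups[s] for s in matrix.site_ids))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    pools: dict[str, set[str]] = {g: set() for g in labels}
    for site in matrix.site_ids:
        pools[groups[site]] |= matrix.species_at(site)
    g1, g2 = labels
    shared = sorted(pools[g1] & pools[g2])
    combined = len(pools[g1] | pools[g2])
    return {
        "groups": (g1, g2),
        "gamma": {g1: len(pools[g1]), g2: len(pools[g2])},
        "shared_species": shared,
        "n_shared": len(shared),
        "combined_gamma": combined,
        "shared_fraction": len(shared) / combined if combined else float("nan"),
    }


def subset_pairs(
    pairs: Sequence, groups: Mapping[str, str], mode: str = "between"
) -> list:
    """Filter pairwise records (anything with site_i/site_j) by group labels.

    ``between`` keeps pairs whose sites carry different labels, ``within``
    keeps same-label pairs; together they partition the input.
    """
    if mode not in ("within", "between"):
        raise ValueError(f"mode must be 'within' or 'between', got {mode!r}")
    out = []
    for p in pairs:
        for s in (p.site_i, p.site_j):
            if s not in groups:
                raise ValueError(f"site without group label: {s!r}")
        same = groups[p.site_i] == groups[p.site_j]
        if (mode == "within") == same:
            out.append(p)
    return out
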