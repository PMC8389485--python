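"""Richness estimation from abundance samples: Chao1 and rarefaction.

Chao1 extrapolates total richness from the counts of singletons (F1) and
doubletons (F2); individual-based rarefaction gives the expected number of
species in a random subsample of n individuals under the hypergeometric
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["AbundanceVector", "chao1", "rarefied_richness", "read_abundance"]


@dataclass(frozen=True)
class AbundanceVector:
    """Species abundance counts from one sampling unit."""

    species_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size != len(self.species_ids):
            raise ValueError("counts must align with species_ids")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "counts", counts)

    @property
    def s_obs(self) -> int:
        return int((self.counts > 0).sum())

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())

    def f_count(self, k: int) -> int:
        """Number of species observed exactly k times."""
        return int((self.counts == k).sum())


def chao1(abund: AbundanceVector, bias_corrected: bool | None = None) -> float:
    """Chao1 lower-bound estimate of total species richness.

    Classic form ``S_obs + F1**2 / (2 * F2)``; bias-corrected form
    ``S_obs + F1 * (F1 - 1) / (2 * (F2 + 1))``.  With ``bias_corrected=None``
    (auto) the classic form is used unless F2 = 0, where it is undefined.
    """
    if abund.n_individuals == 0:
        raise ValueError("empty abundance vector")
    s_obs = abund.s_obs
    f1, f2 = abund.f_count(1), abund.f_count(2)
    if bias_corrected is None:
        bias_corrected = f2 == 0
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined with no doubletons (F2 = 0)")
    return s_obs + f1 * f1 / (2 * f2)


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(k + 1) - gammaln(np.asarray(n) - k + 1)


def rarefied_richness(abund: AbundanceVector, n: int) -> float:
    """Expected species count in a random subsample of ``n`` individuals.

    ``E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n)`` computed through
    log-gamma to stay stable for large N.
    """
    N = abund.n_individuals
    if not 0 <= n <= N:
        raise ValueError(f"subsample size {n} outside [0, {N}]")
    if n == 0:
        return 0.0
    counts = abund.counts[abund.counts > 0]
    log_cN = _log_comb(N, n)
    rest = N - counts
    p_missing = np.zeros(counts.size)
    ok = rest >= n
    p_missing[ok] = np.exp(_log_comb(rest[ok], n) - log_cN)
    return float(np.sum(1.0 - p_missing))


def read_abundance(path: str | Path) -> AbundanceVector:
    """Read a species,count CSV into an :class:`AbundanceVector`."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "species" not in cols or "count" not in cols:
        raise ValueError(f"{path}: abundance CSV needs species,count columns")
    sp = df[df.columns[cols.index("species")]].astype(str)
    ct = df[df.columns[cols.index("count")]]
    return AbundanceVector(tuple(sp), ct.to_numpy())
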