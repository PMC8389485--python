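"""Presence/absence community matrices: the data model every analysis consumes.

An :class:`IncidenceMatrix` is a sites x species boolean occupancy grid with
ordered, unique labels on both axes.  CSV I/O supports two layouts:

* ``wide`` — first column ``site``, one 0/1 column per species;
* ``long`` — one ``site,species`` record per occurrence.

Site metadata (:class:`SiteMeta`) carries the environmental variables used in
screening analyses, plus coordinates for the field-merging rule: vent fields
closer than a threshold distance (default 3 km) are treated as a single site
because they likely tap one heat source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceMatrix",
    "SiteMeta",
    "IncidenceFormatError",
    "read_incidence",
    "write_incidence",
    "read_site_meta",
    "merge_nearby_fields",
    "occupancy_summary",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0


class IncidenceFormatError(ValueError):
    """Raised when an input file cannot be parsed as an incidence matrix."""


@dataclass(frozen=True)
class IncidenceMatrix:
    """Sites x species boolean occupancy with ordered labels.

    Parameters
    ----------
    site_ids : sequence of str
        Row labels, unique, in analysis order.
    species_ids : sequence of str
        Column labels, unique, in analysis order.
    occupancy : ndarray of bool, shape (n_sites, n_species)
        ``occupancy[i, j]`` is True when species ``j`` occurs at site ``i``.
    """

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        sites = tuple(str(s) for s in self.site_ids)
        species = tuple(str(s) for s in self.species_ids)
        occ = np.asarray(self.occupancy)
        if occ.dtype != bool:
            uniq = np.unique(occ)
            if not np.isin(uniq, [0, 1]).all():
                raise IncidenceFormatError(
                    f"occupancy cells must be 0/1; found {uniq[:5]!r}"
                )
            occ = occ.astype(bool)
        occ = np.ascontiguousarray(occ)
        if occ.ndim != 2 or occ.shape != (len(sites), len(species)):
            raise IncidenceFormatError(
                f"occupancy shape {occ.shape} does not match "
                f"{len(sites)} sites x {len(species)} species"
            )
        if len(set(sites)) != len(sites):
            raise IncidenceFormatError("duplicate site labels")
        if len(set(species)) != len(species):
            raise IncidenceFormatError("duplicate species labels")
        if len(sites) < 1 or len(species) < 1:
            raise IncidenceFormatError("need at least one site and one species")
        occ.setflags(write=False)
        object.__setattr__(self, "site_ids", sites)
        object.__setattr__(self, "species_ids", species)
        object.__setattr__(self, "occupancy", occ)

    # -- basic views ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        """Wide 0/1 DataFrame indexed by site."""
        return pd.DataFrame(
            self.occupancy.astype(int),
            index=pd.Index(self.site_ids, name="site"),
            columns=list(self.species_ids),
        )

    def species_at(self, site: str) -> frozenset[str]:
        i = self.site_ids.index(site)
        row = self.occupancy[i]
        return frozenset(sp for sp, v in zip(self.species_ids, row) if v)

    def site_richness(self) -> np.ndarray:
        """Per-site alpha diversity (row sums)."""
        return self.occupancy.sum(axis=1)

    def species_frequency(self) -> np.ndarray:
        """Per-species occupancy frequency (column sums)."""
        return self.occupancy.sum(axis=0)

    def gamma(self) -> int:
        """Regional richness: species present at >= 1 site."""
        return int((self.species_frequency() > 0).sum())

    def subset_sites(self, sites: Sequence[str]) -> "IncidenceMatrix":
        """Row subset in the given order; all-zero species columns are kept."""
        idx = [self.site_ids.index(s) for s in sites]
        return IncidenceMatrix(tuple(sites), self.species_ids, self.occupancy[idx])

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]]
    ) -> "IncidenceMatrix":
        """Build from (site, species) occurrence records.

        Duplicates are collapsed; site and species orders follow first
        appearance.
        """
        sites: dict[str, int] = {}
        species: dict[str, int] = {}
        cells: set[tuple[int, int]] = set()
        for site, sp in records:
            i = sites.setdefault(str(site), len(sites))
            j = species.setdefault(str(sp), len(species))
            cells.add((i, j))
        if not sites:
            raise IncidenceFormatError("no occurrence records")
        occ = np.zeros((len(sites), len(species)), dtype=bool)
        for i, j in cells:
            occ[i, j] = True
        return cls(tuple(sites), tuple(species), occ)


@dataclass(frozen=True)
class SiteMeta:
    """Environmental descriptors for one vent site."""

    site_id: str
    abbr: str = ""
    latitude: float = math.nan
    longitude: float = math.nan
    depth_m: float = math.nan
    arc_distance_km: float = math.nan
    neighbor_distance_km: float = math.nan
    max_temperature_c: float = math.nan
    venting_area_m2: float = math.nan

    def __post_init__(self) -> None:
        if not math.isnan(self.latitude) and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} out of [-90, 90]")
        if not math.isnan(self.longitude) and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude {self.longitude} out of [-180, 180]")
        for name in ("arc_distance_km", "neighbor_distance_km", "venting_area_m2"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


# -- I/O -------------------------------------------------------------------


def read_incidence(path: str | Path, layout: str = "wide") -> IncidenceMatrix:
    """Read a presence/absence matrix from CSV.

    ``wide``: first column holds site labels, remaining columns are species
    with 0/1 cells.  ``long``: columns ``site,species``; duplicate records are
    collapsed and orders follow first appearance.
    """
    path = Path(path)
    if layout == "wide":
        try:
            df = pd.read_csv(path, index_col=0)
        except pd.errors.EmptyDataError as exc:
            raise IncidenceFormatError(f"{path}: empty file") from exc
        if df.shape[1] == 0:
            raise IncidenceFormatError(f"{path}: no species columns")
        values = df.to_numpy()
        bad = ~np.isin(values, [0, 1])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise IncidenceFormatError(
                f"{path}: non-binary cell {values[i, j]!r} at "
                f"site {df.index[i]!r}, species {df.columns[j]!r}"
            )
        return IncidenceMatrix(
            tuple(str(s) for s in df.index),
            tuple(str(s) for s in df.columns),
            values.astype(bool),
        )
    if layout == "long":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise IncidenceFormatError(f"{path}: empty file") from exc
        cols = [c.lower() for c in df.columns]
        if "site" not in cols or "species" not in cols:
            raise IncidenceFormatError(f"{path}: long layout needs site,species columns")
        site_col = df.columns[cols.index("site")]
        sp_col = df.columns[cols.index("species")]
        return IncidenceMatrix.from_records(
            zip(df[site_col].astype(str), df[sp_col].astype(str))
        )
    raise ValueError(f"unknown layout {layout!r}")


def write_incidence(
    matrix: IncidenceMatrix, path: str | Path, layout: str = "wide"
) -> Path:
    """Write a matrix to CSV; ``read_incidence`` round-trips it exactly.

    Note the long layout cannot represent all-empty species columns or
    all-empty sites; the wide layout is lossless.
    """
    path = Path(path)
    if layout == "wide":
        matrix.to_frame().to_csv(path)
    elif layout == "long":
        rows = [
            {"site": site, "species": sp}
            for site, row in zip(matrix.site_ids, matrix.occupancy)
            for sp, v in zip(matrix.species_ids, row)
            if v
        ]
        pd.DataFrame(rows, columns=["site", "species"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return path


def read_site_meta(path: str | Path) -> list[SiteMeta]:
    """Read site metadata CSV (columns named after :class:`SiteMeta` fields)."""
    df = pd.read_csv(path)
    metas = []
    for _, row in df.iterrows():
        kwargs = {"site_id": str(row["site_id"])}
        for fld in (
            "abbr",
            "latitude",
            "longitude",
            "depth_m",
            "arc_distance_km",
            "neighbor_distance_km",
            "max_temperature_c",
            "venting_area_m2",
        ):
            if fld in df.columns and not pd.isna(row[fld]):
                kwargs[fld] = row[fld] if fld == "abbr" else float(row[fld])
        metas.append(SiteMeta(**kwargs))
    return metas


# -- field merging ---------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a spherical Earth (R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def merge_nearby_fields(
    matrix: IncidenceMatrix,
    meta: Sequence[SiteMeta] | Mapping[str, SiteMeta],
    threshold_km: float = 3.0,
    joiner: str = "/",
) -> IncidenceMatrix:
    """Combine vent fields closer than ``threshold_km`` into single sites.

    The merge is the transitive closure of the "< threshold" relation: a
    chain of fields each within threshold of the next collapses into one
    site.  Merged occupancy is the union; the merged label concatenates the
    member labels in input order.  Every site must have coordinates.
    """
    if not isinstance(meta, Mapping):
        meta = {m.site_id: m for m in meta}
    coords = []
    for s in matrix.site_ids:
        m = meta.get(s)
        if m is None or math.isnan(m.latitude) or math.isnan(m.longitude):
            raise ValueError(f"missing coordinates for site {s!r}")
        coords.append((m.latitude, m.longitude))

    n = matrix.n_sites
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if haversine_km(*coords[i], *coords[j]) < threshold_km:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: g[0])

    site_ids = tuple(
        joiner.join(matrix.site_ids[i] for i in g) for g in ordered
    )
    occ = np.stack([matrix.occupancy[g].any(axis=0) for g in ordered])
    return IncidenceMatrix(site_ids, matrix.species_ids, occ)


# -- summaries -------------------------------------------------------------


def occupancy_summary(matrix: IncidenceMatrix) -> dict:
    """Per-site alpha, regional gamma, and occupancy-frequency breakdown.

    Returns a dict with keys ``alpha`` (site -> richness), ``gamma``,
    ``mean_alpha``, ``sd_alpha`` (ddof=1, NaN for a single site),
    ``species_frequency`` (species -> number of sites occupied),
    ``n_ubiquitous`` / ``prop_ubiquitous`` (species at every site) and
    ``n_singletons`` / ``prop_singletons`` (species at exactly one site);
    proportions are relative to gamma.
    """
    alpha = matrix.site_richness()
    freq = matrix.species_frequency()
    gamma = int((freq > 0).sum())
    n_ubiq = int((freq == matrix.n_sites).sum())
    n_single = int((freq == 1).sum())
    return {
        "alpha": dict(zip(matrix.site_ids, (int(a) for a in alpha))),
        "gamma": gamma,
        "mean_alpha": float(alpha.mean()),
        "sd_alpha": float(alpha.std(ddof=1)) if matrix.n_sites > 1 else math.nan,
        "species_frequency": dict(zip(matrix.species_ids, (int(f) for f in freq))),
        "n_ubiquitous": n_ubiq,
        "prop_ubiquitous": n_ubiq / gamma if gamma else math.nan,
        "n_singletons": n_single,
        "prop_singletons": n_single / gamma if gamma else math.nan,
    }
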