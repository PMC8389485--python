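"""Published vent-survey summaries bundled as ready-made fixtures.

Three North Pacific hydrothermal systems are covered: the Mariana back-arc
spreading centre (8 sites), the Mariana volcanic arc (8 seamount sites) and
the Juan de Fuca/Explorer mid-ocean ridge (7 sites).  What ships here is the
printed summary data — per-site species richness (alpha) and system richness
(gamma), environmental variables for the back-arc sites, and the 28-species
macrofaunal checklist from the four northern back-arc sites — not the full
site-by-species matrices, which belong to the source study's supplementary
material.  Full-matrix analyses are exercised on synthetic communities from
:mod:`ventbeta.synthetic`.
"""

from __future__ import annotations

from .incidence import IncidenceMatrix, SiteMeta

__all__ = [
    "backarc_site_metadata",
    "backarc_checklist",
    "system_alpha",
    "system_gamma",
]

# Environmental variables for the eight Mariana back-arc vent sites.
# Coordinates in decimal degrees; max temperature is the highest measured at
# any visit; venting area estimated from dive imagery.
_BACKARC_META = [
    # site, abbr, lat, lon, depth_m, arc_km, next_south_km, tmax_C, area_m2
    ("Alice Springs/Illium", "AI", 18.21183, 144.70750, 3597, 109, 3.5, 287, 2270),
    ("Burke", "Bk", 18.18250, 144.71983, 3630, 108, 136.7, 50, 2625),
    ("Hafa Adai", "HA", 16.96133, 144.86917, 3279, 101, 169.2, 345, 5165),
    ("Perseverance", "Pv", 15.48000, 144.50767, 3910, 97, 239.9, 264, 510),
    ("Forecast", "Fc", 13.40000, 143.91667, 1470, 23, 59.1, 210, 2510),
    ("Snail", "Sn", 12.95333, 143.62000, 2850, 11, 2.7, 248, 1183),
    ("Archaean", "Ar", 12.93333, 143.63333, 2990, 8, 2.3, 345, 1840),
    ("Urashima/Pika", "UP", 12.91833, 143.64833, 2956, 6, float("nan"), 330, 1995),
]

# Macrofauna recorded at the four northern back-arc sites (Alice Springs/
# Illium, Burke, Hafa Adai, Perseverance), 28 species.
_BACKARC_CHECKLIST = [
    "Marianactis bythios",
    "Epizoanthus aff. sp. nov.",
    "Helicoradomenia sp. nov.",
    "Bathymodiolus septemdierum",
    "Alviniconcha hessleri",
    "Provanna nassariaeformis",
    "Desbruyeresia marianaensis",
    "Desbruyeresia chamorrensis",
    "Lepetodrilus aff. schrolli MT",
    "Pseudorimula marianae",
    "Bathyacmaea sp.",
    "Shinkailepas sp. nov.",
    "Symmetromphalus regularis",
    "Phymorhynchus wareni",
    "Neoverruca brachylepadoformis",
    "Vulcanolepas verenae",
    "Rimicaris vandoverae",
    "Rimicaris cf. variabilis",
    "Rimicaris falkorae",
    "Austinograea williamsi",
    "Sericosura cochleifovea",
    "Levensteiniella raisae",
    "Lepidonotopodium minutum",
    "Branchinotogluma marianus",
    "Sirsoe hessleri",
    "Laonice sp. nov.",
    "Paralvinella hessleri",
    "Amphisamytha sp. nov.",
]

# Per-site alpha diversity (species richness) and system gamma for the three
# study systems, keyed by site abbreviation.
_ALPHA = {
    "backarc": {
        "AI": 29, "Bk": 23, "HA": 25, "Pv": 13,
        "Fc": 20, "Sn": 21, "Ar": 13, "UP": 15,
    },
    "arc": {
        "Nk": 12, "K2": 12, "NWE": 21, "Dk": 14,
        "Ch": 5, "ED": 16, "NWR": 9, "SX": 14,
    },
    "jdf": {
        "Ex": 29, "MV": 46, "En": 45, "CA": 27,
        "Ax": 40, "NC": 28, "SC": 16,
    },
}

_GAMMA = {"backarc": 39, "arc": 45, "jdf": 71}


def backarc_site_metadata() -> list[SiteMeta]:
    """Environmental metadata for the eight Mariana back-arc sites."""
    return [
        SiteMeta(
            site_id=s,
            abbr=a,
            latitude=lat,
            longitude=lon,
            depth_m=d,
            arc_distance_km=arc,
            neighbor_distance_km=nxt,
            max_temperature_c=t,
            venting_area_m2=area,
        )
        for s, a, lat, lon, d, arc, nxt, t, area in _BACKARC_META
    ]


def backarc_checklist(as_matrix: bool = False) -> list[str] | IncidenceMatrix:
    """The 28-species macrofaunal checklist of the northern back-arc sites.

    The published checklist pools the four northern sites, so ``as_matrix``
    returns a one-site incidence matrix labelled ``"northern back-arc"``.
    """
    if not as_matrix:
        return list(_BACKARC_CHECKLIST)
    return IncidenceMatrix.from_records(
        ("northern back-arc", sp) for sp in _BACKARC_CHECKLIST
    )


def system_alpha(system: str) -> dict[str, int]:
    """Per-site alpha richness for ``backarc``, ``arc`` or ``jdf``."""
    try:
        return dict(_ALPHA[system])
    except KeyError:
        raise KeyError(f"unknown system {system!r}; choose from {sorted(_ALPHA)}")


def system_gamma(system: str) -> int:
    """System-level gamma richness for ``backarc``, ``arc`` or ``jdf``."""
    try:
        return _GAMMA[system]
    except KeyError:
        raise KeyError(f"unknown system {system!r}; choose from {sorted(_GAMMA)}")
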