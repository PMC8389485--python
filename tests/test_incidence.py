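import math

import numpy as np
import pytest

from ventbeta import (
    IncidenceFormatError,
    IncidenceMatrix,
    SiteMeta,
    merge_nearby_fields,
    occupancy_summary,
    read_incidence,
    write_incidence,
)
from ventbeta.incidence import haversine_km

from conftest import random_matrix

# 1 degree of latitude spans R * pi/180 km on the sphere, so a pure
# latitude offset gives an exact closed-form great-circle distance.
KM_PER_DEG_LAT = 6371.0 * math.pi / 180.0


class TestConstruction:
    def test_from_long_records(self):
        m = IncidenceMatrix.from_records([("A", "x"), ("A", "y"), ("B", "x")])
        assert m.site_ids == ("A", "B")
        assert m.species_ids == ("x", "y")
        assert m.occupancy.tolist() == [[True, True], [True, False]]

    def test_duplicate_records_collapse(self):
        once = IncidenceMatrix.from_records([("A", "x"), ("B", "x")])
        twice = IncidenceMatrix.from_records([("A", "x"), ("A", "x"), ("B", "x")])
        assert np.array_equal(once.occupancy, twice.occupancy)

    @pytest.mark.parametrize(
        "sites,species",
        [(("A", "A"), ("x", "y")), (("A", "B"), ("x", "x"))],
    )
    def test_duplicate_labels_rejected(self, sites, species):
        with pytest.raises(IncidenceFormatError):
            IncidenceMatrix(sites, species, np.ones((2, 2), dtype=bool))

    def test_non_binary_cells_rejected(self):
        with pytest.raises(IncidenceFormatError):
            IncidenceMatrix(("A",), ("x", "y"), np.array([[1, 2]]))


class TestRoundTrip:
    def test_wide_round_trip_identity(self, tmp_path, rng):
        m = random_matrix(rng)
        path = tmp_path / "m_wide.csv"
        write_incidence(m, path, "wide")
        back = read_incidence(path, "wide")
        assert back.site_ids == m.site_ids
        assert back.species_ids == m.species_ids
        assert np.array_equal(back.occupancy, m.occupancy)

    def test_long_round_trip_identity_when_representable(self, tmp_path, rng):
        # the long layout recovers orders exactly when the first site holds
        # every species (first-appearance order = column order)
        occ = random_matrix(rng).occupancy.copy()
        occ[0, :] = True
        m = IncidenceMatrix(
            tuple(f"s{i}" for i in range(occ.shape[0])),
            tuple(f"sp{j}" for j in range(occ.shape[1])),
            occ,
        )
        path = tmp_path / "m_long.csv"
        write_incidence(m, path, "long")
        back = read_incidence(path, "long")
        assert back.site_ids == m.site_ids
        assert back.species_ids == m.species_ids
        assert np.array_equal(back.occupancy, m.occupancy)

    def test_long_round_trip_preserves_occurrences(self, tmp_path, rng):
        # arbitrary matrices: same site order and same site -> species sets
        m = random_matrix(rng)
        path = tmp_path / "m_long.csv"
        write_incidence(m, path, "long")
        back = read_incidence(path, "long")
        assert back.site_ids == m.site_ids
        for s in m.site_ids:
            assert back.species_at(s) == m.species_at(s)

    def test_wide_long_wide_equivalence(self, tmp_path, tiny_matrix):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_incidence(tiny_matrix, p1, "long")
        write_incidence(read_incidence(p1, "long"), p2, "wide")
        assert np.array_equal(read_incidence(p2, "wide").occupancy, tiny_matrix.occupancy)

    def test_empty_species_column_preserved_in_wide(self, tmp_path):
        m = IncidenceMatrix(("A", "B"), ("x", "gone"), np.array([[1, 0], [1, 0]]))
        path = tmp_path / "m.csv"
        write_incidence(m, path, "wide")
        back = read_incidence(path, "wide")
        assert back.species_ids == ("x", "gone")
        assert back.species_frequency().tolist() == [2, 0]

    def test_non_binary_wide_cell_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site,x,y\nA,1,2\n")
        with pytest.raises(IncidenceFormatError, match="non-binary"):
            read_incidence(path, "wide")

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(IncidenceFormatError):
            read_incidence(path, "wide")


class TestMergeNearbyFields:
    def _meta(self, *latlon):
        return [
            SiteMeta(site_id=f"F{i}", latitude=lat, longitude=lon)
            for i, (lat, lon) in enumerate(latlon)
        ]

    def _two_fields(self):
        return IncidenceMatrix(
            ("F0", "F1"), ("x", "y"), np.array([[1, 0], [0, 1]])
        )

    def test_fields_below_threshold_merge_with_union(self):
        m = self._two_fields()
        meta = self._meta((0.0, 0.0), (2.9 / KM_PER_DEG_LAT, 0.0))
        merged = merge_nearby_fields(m, meta, threshold_km=3.0)
        assert merged.site_ids == ("F0/F1",)
        assert merged.occupancy.tolist() == [[True, True]]

    def test_fields_above_threshold_unchanged(self):
        m = self._two_fields()
        meta = self._meta((0.0, 0.0), (3.1 / KM_PER_DEG_LAT, 0.0))
        merged = merge_nearby_fields(m, meta, threshold_km=3.0)
        assert merged.site_ids == ("F0", "F1")

    def test_identical_coordinates_merge(self):
        m = self._two_fields()
        meta = self._meta((10.0, 20.0), (10.0, 20.0))
        assert merge_nearby_fields(m, meta).n_sites == 1

    def test_transitive_chain_merges(self):
        # F0-F1 and F1-F2 each 2 km apart; F0-F2 is 4 km yet all merge
        step = 2.0 / KM_PER_DEG_LAT
        m = IncidenceMatrix(
            ("F0", "F1", "F2"), ("x",), np.ones((3, 1), dtype=bool)
        )
        meta = self._meta((0.0, 0.0), (step, 0.0), (2 * step, 0.0))
        merged = merge_nearby_fields(m, meta)
        assert merged.site_ids == ("F0/F1/F2",)

    def test_idempotent(self, rng):
        m = random_matrix(rng, n_sites=4)
        lat = [0.0, 0.01, 5.0, 5.005]
        meta = [
            SiteMeta(site_id=s, latitude=lat[i], longitude=0.0)
            for i, s in enumerate(m.site_ids)
        ]
        once = merge_nearby_fields(m, meta)
        meta2 = [
            SiteMeta(site_id=s, latitude=0.0 if i == 0 else 5.0, longitude=0.0)
            for i, s in enumerate(once.site_ids)
        ]
        again = merge_nearby_fields(once, meta2)
        assert again.site_ids == once.site_ids
        assert np.array_equal(again.occupancy, once.occupancy)

    def test_missing_coordinates_raise(self):
        m = self._two_fields()
        meta = [SiteMeta(site_id="F0", latitude=0, longitude=0), SiteMeta(site_id="F1")]
        with pytest.raises(ValueError, match="coordinates"):
            merge_nearby_fields(m, meta)

    def test_haversine_quarter_circumference(self):
        # pole to equator is a quarter of the great circle
        assert haversine_km(90, 0, 0, 0) == pytest.approx(6371.0 * math.pi / 2)


class TestOccupancySummary:
    def test_identity_matrix(self):
        m = IncidenceMatrix(("A", "B", "C"), ("x", "y", "z"), np.eye(3, dtype=bool))
        s = occupancy_summary(m)
        assert list(s["alpha"].values()) == [1, 1, 1]
        assert s["gamma"] == 3
        assert s["n_singletons"] == 3
        assert s["n_ubiquitous"] == 0

    def test_gamma_matches_column_scan(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_sites=5, n_species=20, p=0.2)
            brute = sum(1 for j in range(m.n_species) if m.occupancy[:, j].any())
            assert occupancy_summary(m)["gamma"] == brute

    def test_alpha_sums_to_total_occupancy(self, rng):
        m = random_matrix(rng)
        s = occupancy_summary(m)
        assert sum(s["alpha"].values()) == int(m.occupancy.sum())

    def test_site_meta_validation(self):
        with pytest.raises(ValueError):
            SiteMeta(site_id="bad", latitude=123.0, longitude=0.0)
        with pytest.raises(ValueError):
            SiteMeta(site_id="bad", venting_area_m2=-5.0)
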