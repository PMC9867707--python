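"""Great-circle geometry, day classification, winter-area estimation,
stage segmentation, strategy assignment and habitat reduction."""

import numpy as np
import pandas as pd
import pytest

import fullcycle as fc
from fullcycle.annual_cycle import (
    EARTH_RADIUS_KM, assign_strategy, classify_day, daily_displacement,
    great_circle_km, remap_habitat, segment_stages, winter_core_area,
)


def law_of_cosines_km(p1, p2):
    """Independent spherical-law-of-cosines oracle."""
    phi1, phi2 = np.radians(p1[0]), np.radians(p2[0])
    dlam = np.radians(p2[1] - p1[1])
    c = np.sin(phi1) * np.sin(phi2) + np.cos(phi1) * np.cos(phi2) * np.cos(dlam)
    return EARTH_RADIUS_KM * np.arccos(np.clip(c, -1, 1))


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_km((52.0, 4.0), (52.0, 4.0)) == 0.0

    def test_one_degree_meridian_arc(self):
        expected = EARTH_RADIUS_KM * np.pi / 180  # 111.195 km
        assert great_circle_km((52.0, 4.0), (53.0, 4.0)) == pytest.approx(expected, rel=1e-9)

    def test_symmetry_and_oracle_agreement(self):
        rng = np.random.default_rng(42)
        lats = rng.uniform(-80, 80, (1000, 2))
        lons = rng.uniform(-180, 180, (1000, 2))
        for i in range(0, 1000, 7):
            p1, p2 = (lats[i, 0], lons[i, 0]), (lats[i, 1], lons[i, 1])
            d = great_circle_km(p1, p2)
            assert great_circle_km(p2, p1) == pytest.approx(d, rel=1e-12)
            assert abs(d - law_of_cosines_km(p1, p2)) < 1e-3  # < 1 m

    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            great_circle_km((95.0, 0.0), (0.0, 0.0))


class TestClassifyDay:
    @pytest.mark.parametrize("disp,expected", [
        (71.0, "relocation"), (70.0, "stationary"), (0.0, "stationary"),
    ])
    def test_threshold_is_strict(self, disp, expected):
        assert classify_day(disp) == expected

    def test_missing_propagates(self):
        assert classify_day(float("nan")) == "missing"


class TestDailyDisplacement:
    def test_winter_days_are_stationary(self, wa_year):
        daily = daily_displacement(wa_year)
        t = wa_year.truth
        winter = daily.iloc[t["winter_start"] + 1: t["spring_start"] - 1]
        assert winter["displacement_km"].max() < 5.0

    def test_migration_day_moves_far(self):
        # constructed track moving 3 degrees south in one day
        t = pd.date_range("2018-06-01", periods=96, freq="30min")
        lat = np.concatenate([np.full(48, 52.0), np.linspace(52, 49, 48)])
        df = pd.DataFrame({
            "t": t, "lat": lat, "lon": 4.0, "mode": "flap", "floating": False,
            "dba": 1.0, "t_air": 15.0, "wind": 1.0, "solar": 0.0, "simulated": False,
        })
        by = fc.BirdYear(df, (52.0, 4.0), "2018-06-01")
        daily = daily_displacement(by)
        assert daily["displacement_km"].iloc[1] > 300

    def test_gap_day_is_missing(self, wa_year):
        gapped = fc.inject_gaps(wa_year, [("2019-01-05", "2019-01-14")])
        daily = daily_displacement(gapped)
        mid_gap = daily[daily["date"] == "2019-01-10"]
        assert np.isnan(mid_gap["displacement_km"].iloc[0])


class TestWinterCoreArea:
    def test_single_cluster_mass(self):
        rng = np.random.default_rng(1)
        lat = 15.0 + rng.normal(0, 0.3, 400)
        lon = -17.0 + rng.normal(0, 0.3, 400)
        area = winter_core_area(lat, lon)
        assert area.n_components == 1
        assert area.mass == pytest.approx(0.95, abs=0.02)
        assert area.centroid[0] == pytest.approx(15.0, abs=0.3)
        assert area.contains(15.0, -17.0)

    def test_southernmost_of_two_clusters_selected(self):
        rng = np.random.default_rng(2)
        lat = np.concatenate([45 + rng.normal(0, 0.3, 200), 15 + rng.normal(0, 0.3, 200)])
        lon = np.concatenate([2 + rng.normal(0, 0.3, 200), -17 + rng.normal(0, 0.3, 200)])
        area = winter_core_area(lat, lon)
        assert area.centroid[0] == pytest.approx(15.0, abs=0.5)
        assert not area.contains(45.0, 2.0)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            winter_core_area(np.full(10, 15.0), np.full(10, -17.0))

    def test_geojson_roundtrip_structure(self):
        rng = np.random.default_rng(3)
        area = winter_core_area(15 + rng.normal(0, 0.3, 200),
                                -17 + rng.normal(0, 0.3, 200))
        gj = area.to_geojson()
        assert gj["geometry"]["type"] == "MultiPolygon"
        assert len(gj["geometry"]["coordinates"]) >= 1


class TestSegmentation:
    def test_stages_partition_the_year(self, wa_processed):
        days = wa_processed.segmentation.days
        assert days["stage"].notna().all()
        from itertools import groupby

        runs = [k for k, _ in groupby(days["stage"])]
        assert runs == ["breeding", "autumn_migration", "wintering",
                        "spring_migration", "breeding"]

    def test_boundaries_match_generator_truth(self, wa_processed, wa_year):
        b = wa_processed.segmentation.boundaries
        t = wa_year.truth
        day0 = wa_year.start
        assert abs((b["departure"] - day0).days + 1 - t["departure_autumn"]) <= 2
        assert abs((b["winter_start"] - day0).days - t["winter_start"]) <= 2
        assert abs((b["winter_end"] - day0).days + 1 - t["spring_start"]) <= 2
        assert abs((b["arrival"] - day0).days - t["arrival_spring"]) <= 2

    def test_migration_days_imply_relocation(self, wa_processed):
        days = wa_processed.segmentation.days
        mig = days[days["day_subtype"] == "migration_day"]
        assert (mig["day_type"] == "relocation").all()

    def test_sedentary_year_rejected(self):
        t = pd.date_range("2018-06-01", "2019-05-31 23:00", freq="60min")
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "t": t, "lat": 52.0 + rng.normal(0, 0.01, len(t)),
            "lon": 4.0 + rng.normal(0, 0.01, len(t)),
            "mode": "stationary", "floating": False, "dba": 0.01,
            "t_air": 15.0, "wind": 1.0, "solar": 0.0, "simulated": False,
        })
        by = fc.BirdYear(df, (52.0, 4.0), "2018-06-01")
        with pytest.raises(ValueError):
            segment_stages(by)


class TestAssignStrategy:
    @pytest.mark.parametrize("centroid,expected", [
        ((14.7, -17.0), "WestAfrica"),
        ((31.0, -8.0), "NorthAfrica"),
        ((40.0, -4.0), "Iberia"),
        ((51.3, 0.0), "FRUK"),
    ])
    def test_default_regions(self, centroid, expected):
        assert assign_strategy(centroid) == expected

    def test_unassigned_warns(self):
        with pytest.warns(UserWarning):
            assert assign_strategy((0.0, 120.0)) == "unassigned"


class TestRemapHabitat:
    @pytest.mark.parametrize("raw,within,expected", [
        ("cropland", False, "agricultural"),
        ("shrubland", False, "terrestrial_open"),
        ("built-up", True, "terrestrial_open"),
        ("sea", False, "marine"),
        ("herbaceous_wetland", False, "inland_wet"),
        ("forest_mixed", False, "forest"),
    ])
    def test_reduction(self, raw, within, expected):
        assert remap_habitat(raw, within) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            remap_habitat("lava_field")
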