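"""The synthetic generator: determinism, track structure, bursts, weather
and gap injection."""

import numpy as np
import pandas as pd
import pytest

import fullcycle as fc
from fullcycle.accelerometry import compute_dba, remove_baseline
from fullcycle.annual_cycle import classify_day, daily_displacement, great_circle_km
from fullcycle.synthetic_tracks import (
    TEMPLATES, build_schedule, generate_acc_burst, generate_bird_year,
    inject_gaps, synth_weather,
)


class TestGenerateBirdYear:
    def test_winter_positions_near_centroid(self):
        by = generate_bird_year("WestAfrica", 20, seed=1)
        t = by.truth
        winter = by.fixes[
            (by.fixes["t"] >= by.start + pd.Timedelta(days=t["winter_start"]))
            & (by.fixes["t"] < by.start + pd.Timedelta(days=t["spring_start"]))
        ]
        d_lat = np.abs(winter["lat"] - TEMPLATES["WestAfrica"].winter_centroid[0])
        d_lon = np.abs(winter["lon"] - TEMPLATES["WestAfrica"].winter_centroid[1])
        assert d_lat.max() < 2.0 and d_lon.max() < 2.0

    def test_fruk_relocation_days_bounded(self):
        by = generate_bird_year("FRUK", 60, seed=7)
        daily = daily_displacement(by)
        n_reloc = (classify_day(daily["displacement_km"].to_numpy()) == "relocation").sum()
        assert n_reloc <= 20

    def test_seed_determinism_byte_identical(self):
        a = generate_bird_year("Iberia", 30, seed=3)
        b = generate_bird_year("Iberia", 30, seed=3)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        assert a.fixes.to_csv() == b.fixes.to_csv()

    def test_different_seeds_differ(self):
        a = generate_bird_year("Iberia", 60, seed=1)
        b = generate_bird_year("Iberia", 60, seed=2)
        assert not a.fixes["dba"].equals(b.fixes["dba"])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_bird_year("FRUK", 1.0, seed=0)
        with pytest.raises(ValueError):
            generate_bird_year("FRUK", 120.0, seed=0)

    def test_year_coverage_complete(self, wa_year):
        dates = wa_year.fixes["t"].dt.normalize().nunique()
        assert dates == wa_year.n_days

    def test_schedule_day_counts_match_template(self):
        for name, tpl in TEMPLATES.items():
            sched = build_schedule(tpl, 365, np.random.default_rng(0))
            counts = sched["day_kind"].value_counts()
            assert counts["migration_leg"] == (
                tpl.n_migration_days_autumn + tpl.n_migration_days_spring
            ), name
            assert (sched["stage"] == "wintering").sum() == (
                (tpl.arrival_spring - tpl.spring_days)
                - (tpl.departure_autumn + tpl.autumn_days)
            ), name

    def test_flight_bouts_within_template_range(self, wa_year):
        fh = wa_year.truth["flight_hours"]
        tpl = TEMPLATES["WestAfrica"]
        assert all(tpl.flight_hours_min <= h <= tpl.flight_hours_max for h in fh)


class TestGenerateAccBurst:
    def test_sit_stand_near_zero_dba(self):
        for seed in range(5):
            b = generate_acc_burst("sit/stand", seed=seed)
            assert compute_dba(remove_baseline(b)) < 0.05

    def test_amplitude_ranking(self):
        def dba(mode, seed=2):
            return compute_dba(remove_baseline(generate_acc_burst(mode, seed)))
        assert dba("flap") > dba("walk") > dba("soar") > dba("stationary")

    def test_twenty_samples(self):
        assert generate_acc_burst("walk", seed=5).n_samples == 20

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            generate_acc_burst("swimming", seed=0)


class TestSynthWeather:
    def test_tropical_january_noon_warm(self):
        for seed in range(20):
            assert synth_weather(15.0, 15, 12, seed).t_air > 10.0

    def test_temperate_january_night_can_freeze(self):
        draws = [synth_weather(52.0, 15, 3, s).t_air for s in range(100)]
        assert min(draws) < 10.0

    def test_solar_zero_at_local_midnight(self):
        for lat in (15.0, 35.0, 52.0):
            for doy in (15, 180, 300):
                assert synth_weather(lat, doy, 0, seed=1).solar == 0.0

    def test_deterministic_per_key(self):
        a = synth_weather(40.0, 100, 10, seed=9)
        b = synth_weather(40.0, 100, 10, seed=9)
        assert a == b

    def test_nonnegative_wind_and_solar(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = synth_weather(float(rng.uniform(10, 60)), int(rng.integers(1, 366)),
                              float(rng.uniform(0, 24) % 24), seed=int(rng.integers(1e6)))
            assert w.wind >= 0 and w.solar >= 0

    def test_winter_warmth_increases_with_migration_distance(self):
        """Winter air temperature rises from the FRUK to the WestAfrica
        wintering latitude."""
        lats = [TEMPLATES[n].winter_centroid[0]
                for n in ("FRUK", "Iberia", "NorthAfrica", "WestAfrica")]
        temps = [np.mean([synth_weather(lat, 15, h, seed=4).t_air
                          for h in (0, 6, 12, 18)]) for lat in lats]
        assert np.all(np.diff(temps) > 0)


class TestInjectGaps:
    def test_window_removes_fixes(self, wa_year):
        gapped = inject_gaps(wa_year, [("2019-01-05", "2019-01-14")])
        dates = gapped.fixes["t"].dt.normalize()
        assert not ((dates >= "2019-01-05") & (dates <= "2019-01-14")).any()
        assert gapped.truth["gap_fraction_removed"] == pytest.approx(10 / 365, rel=0.05)

    def test_large_gaps_fail_coverage(self, wa_year):
        windows = [("2018-11-01", "2018-12-31"), ("2019-01-05", "2019-02-10")]
        gapped = inject_gaps(wa_year, windows)
        cov = fc.coverage(gapped)
        assert not cov.passes

    def test_empty_list_is_identity(self, wa_year):
        out = inject_gaps(wa_year, [])
        pd.testing.assert_frame_equal(out.fixes, wa_year.fixes)

    def test_overlapping_windows_merged(self, wa_year):
        out = inject_gaps(wa_year, [("2019-01-01", "2019-01-10"),
                                    ("2019-01-08", "2019-01-20")])
        assert len(out.gaps) == 1

    def test_window_outside_year_rejected(self, wa_year):
        with pytest.raises(ValueError):
            inject_gaps(wa_year, [("2020-01-01", "2020-01-05")])


def test_csv_yaml_roundtrip(tmp_path, fruk_year):
    path = tmp_path / "fruk.csv"
    fruk_year.to_csv(path)
    back = fc.BirdYear.from_csv(path)
    assert back.colony == fruk_year.colony
    assert back.strategy == "FRUK"
    pd.testing.assert_frame_equal(
        back.fixes, fruk_year.fixes, check_exact=False, rtol=1e-9
    )
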