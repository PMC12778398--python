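"""Range centres, movement quantiles, zone and habitat distributions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import box

from conftest import make_dataset
from prickle.records import AUTUMN, NIGHT1, NIGHT2, SPRING
from prickle.spatial import (
    YearlyCentre,
    habitat_distribution,
    interyear_movements,
    yearly_centres,
    zone_distribution,
)
from prickle.zones import ZoneMap, synthetic_park


def centre(ind, year, x, y, zone="z"):
    return YearlyCentre(ind, year, x, y, zone, 1)


class TestZoneMap:
    def test_synthetic_park_area_and_zones(self, park):
        assert park.total_area_ha() == pytest.approx(166.0)
        assert len(park.names) == 7
        park.validate()

    def test_overlapping_zones_rejected(self):
        zm = ZoneMap({"a": box(0, 0, 10, 10), "b": box(5, 5, 15, 15)})
        with pytest.raises(ValueError, match="overlap"):
            zm.validate()

    def test_boundary_ties_break_lexicographically(self):
        zm = ZoneMap({"beta": box(0, 0, 10, 10), "alpha": box(10, 0, 20, 10)})
        # the shared edge x=10 touches both; 'alpha' sorts first
        assert zm.assign(10.0, 5.0) == "alpha"
        assert zm.assign(3.0, 3.0) == "beta"
        assert zm.assign(50.0, 50.0) == "outside"

    def test_geojson_round_trip(self, park, tmp_path):
        path = tmp_path / "zones.geojson"
        park.to_geojson(path)
        loaded = ZoneMap.from_geojson(path)
        assert loaded.names == park.names
        assert loaded.total_area_ha() == pytest.approx(park.total_area_ha())


class TestYearlyCentres:
    def test_single_point_identity_and_mean(self, park):
        e0, n0 = 530100.0, 182100.0
        ds = make_dataset(
            [
                ("A", SPRING, 2015, NIGHT1, "male", 900.0, True, e0, n0),
                ("B", SPRING, 2015, NIGHT1, "male", 900.0, True, e0, n0),
                ("B", AUTUMN, 2015, NIGHT1, "male", 900.0, False, e0 + 10, n0 + 20),
            ]
        )
        cs = {c.individual_id: c for c in yearly_centres(ds, park)}
        assert (cs["A"].easting_m, cs["A"].northing_m) == (e0, n0)
        assert (cs["B"].easting_m, cs["B"].northing_m) == (e0 + 5, n0 + 10)
        assert cs["B"].n_points == 2
        assert cs["A"].zone == "zone1"

    def test_events_without_coords_skipped(self, park):
        ds = make_dataset(
            [
                ("A", SPRING, 2015, NIGHT1, "male", 900.0, True, 530100.0, 182100.0),
                ("A", SPRING, 2015, NIGHT2, "male", 900.0, False, None, None),
            ]
        )
        (c,) = yearly_centres(ds, park)
        assert c.n_points == 1


class TestMovements:
    def test_quartile_rule_hand_case(self):
        centres = []
        for i, d in enumerate([10.0, 20.0, 30.0, 40.0]):
            centres += [centre(f"I{i}", 2015, 0.0, 0.0), centre(f"I{i}", 2016, d, 0.0)]
        res = interyear_movements(centres)
        assert res.upper_quartile_m == pytest.approx(37.5)
        assert res.median_m == pytest.approx(25.0)
        long = [m.distance_m for m in res.movements if m.long_mover]
        assert long == [40.0]

    def test_single_pair_is_not_long_mover(self):
        res = interyear_movements(
            [centre("A", 2015, 0, 0), centre("A", 2016, 50, 0)]
        )
        assert res.median_m == pytest.approx(50.0)
        assert res.n_long_movers == 0  # Q3 = 50, strict inequality

    def test_no_pairs(self):
        res = interyear_movements([centre("A", 2015, 0, 0), centre("B", 2017, 1, 1)])
        assert res.movements == [] and res.median_m is None

    def test_nonconsecutive_years_skipped(self):
        res = interyear_movements(
            [centre("A", 2015, 0, 0), centre("A", 2017, 100, 0)]
        )
        assert res.movements == []

    @given(
        st.floats(-1e5, 1e5),
        st.floats(-1e5, 1e5),
    )
    def test_translation_invariance(self, dx, dy):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, size=(12, 2, 2))
        base, shifted = [], []
        for i, pair in enumerate(pts):
            for j, year in enumerate((2015, 2016)):
                base.append(centre(f"I{i}", year, *pair[j]))
                shifted.append(centre(f"I{i}", year, pair[j][0] + dx, pair[j][1] + dy))
        r0, r1 = interyear_movements(base), interyear_movements(shifted)
        assert r1.median_m == pytest.approx(r0.median_m, rel=1e-9, abs=1e-6)
        assert r1.upper_quartile_m == pytest.approx(r0.upper_quartile_m, rel=1e-9, abs=1e-6)
        assert [m.long_mover for m in r1.movements] == [
            m.long_mover for m in r0.movements
        ]

    def test_long_mover_fraction_bound(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 60))
            centres = []
            for i in range(n):
                x0, y0 = rng.uniform(0, 1000, 2)
                x1, y1 = rng.uniform(0, 1000, 2)
                centres += [centre(f"I{i}", 2015, x0, y0), centre(f"I{i}", 2016, x1, y1)]
            res = interyear_movements(centres)
            assert res.n_long_movers / res.n <= 0.25 + 1.0 / res.n + 1e-12


class TestDistributions:
    def test_zone_percentages(self):
        centres = [centre(f"A{i}", 2015, 0, 0, zone="zoneA") for i in range(3)]
        centres.append(centre("B", 2015, 0, 0, zone="zoneB"))
        df = zone_distribution(centres)
        assert dict(zip(df.zone, df.pct)) == {"zoneA": 75.0, "zoneB": 25.0}

    def test_zone_rows_sum_to_100_per_year(self, rng):
        centres = [
            centre(f"I{i}", int(year), 0, 0, zone=f"z{int(rng.integers(5))}")
            for i, year in enumerate(rng.integers(2014, 2020, size=200))
        ]
        df = zone_distribution(centres)
        sums = df.groupby("year")["pct"].sum()
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_relocation_shifts_distribution(self):
        before = [centre(f"I{i}", 2015, 0, 0, zone="zone1") for i in range(5)]
        after = [centre(f"I{i}", 2016, 0, 0, zone="zone3") for i in range(5)]
        df = zone_distribution(before + after)
        assert df[(df.year == 2015) & (df.zone == "zone1")].pct.iloc[0] == 100.0
        assert df[(df.year == 2016) & (df.zone == "zone3")].pct.iloc[0] == 100.0

    def test_habitat_percentages_and_fixed_categories(self):
        rows = [
            ("A", SPRING, 2015, NIGHT1, "male", 900.0, True, None, None,
             "short grass")
        ] * 0 + [
            (f"A{i}", SPRING, 2015, NIGHT1, "male", 900.0, True, None, None,
             "short grass" if i < 6 else "scrub")
            for i in range(10)
        ]
        df = habitat_distribution(make_dataset(rows))
        pooled = df[df.period == "pooled"].set_index("habitat")
        assert len(pooled) == 11
        assert pooled.loc["short grass", "pct"] == pytest.approx(60.0)
        assert pooled.loc["scrub", "pct"] == pytest.approx(40.0)
        assert pooled.loc["hedgerow", "pct"] == 0.0

    def test_all_habitat_missing(self):
        ds = make_dataset([("A", SPRING, 2015, NIGHT1)])
        df = habitat_distribution(ds)
        assert (df.pct == 0).all()

    def test_simulated_mix_recovered(self):
        from prickle.simulate import SimConfig, simulate

        ds, _ = simulate(SimConfig(n_years=8, per_night_capture_prob=1.0), seed=13)
        df = habitat_distribution(ds)
        pooled = df[df.period == "pooled"].set_index("habitat")
        n = pooled["n"].sum()
        for habitat, p in [("short grass", 0.59), ("tall grass", 0.16)]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(pooled.loc[habitat, "pct"] / 100.0 - p) < 3 * se
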