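"""Age rule, recruitment, losses, life tables, weights, mortality."""

import datetime as dt

import numpy as np
import pytest

from conftest import history_from_statuses, make_dataset, make_occasions
from prickle.demography import (
    ADULT,
    JUVENILE,
    AgeRule,
    classify_age,
    interval_losses,
    life_table,
    life_table_from_counts,
    loss_summary,
    mortality_tabulation,
    recruitment_per_female,
    unmarked_adult_fraction,
    weight_summary,
)
from prickle.records import (
    AUTUMN,
    BOTH_NIGHTS,
    NIGHT1,
    NIGHT2,
    NOT_DETECTED,
    SPRING,
    DeathRecord,
    build_histories,
)
from prickle.simulate import SimConfig, simulate


def autumn_first_history(occasions, weight, individual_id="J1", sex="female",
                         statuses=None):
    if statuses is None:
        # first occasion must be an autumn
        statuses = [
            BOTH_NIGHTS if occ.season == AUTUMN and i == 1 else NOT_DETECTED
            for i, occ in enumerate(occasions)
        ]
    return history_from_statuses(
        statuses, occasions, individual_id=individual_id, sex=sex,
        first_weight=weight,
    )


class TestClassifyAge:
    def test_light_autumn_first_capture_is_juvenile_then_adult(self):
        occasions = make_occasions(4)  # s2014 a2014 s2015 a2015
        h = autumn_first_history(occasions, 540.0, statuses=[
            NOT_DETECTED, BOTH_NIGHTS, BOTH_NIGHTS, BOTH_NIGHTS,
        ])
        assert classify_age(h, occasions[1]) == JUVENILE
        assert classify_age(h, occasions[2]) == ADULT  # next spring: aged up
        assert classify_age(h, occasions[3]) == ADULT  # second autumn

    def test_exact_cutoff_is_adult(self):
        occasions = make_occasions(2)
        h = autumn_first_history(occasions, 700.0)
        assert classify_age(h, occasions[1]) == ADULT

    def test_spring_first_capture_is_adult(self):
        occasions = make_occasions(2)
        h = history_from_statuses(
            [BOTH_NIGHTS, NOT_DETECTED], occasions, first_weight=500.0
        )
        assert classify_age(h, occasions[0]) == ADULT

    def test_missing_autumn_weight_conservatively_adult(self):
        occasions = make_occasions(2)
        h = autumn_first_history(occasions, None)
        assert classify_age(h, occasions[1]) == ADULT

    def test_class_sequence_never_reverts(self):
        ds, _ = simulate(SimConfig(n_years=6), seed=4)
        for h in build_histories(ds):
            classes = [classify_age(h, occ) for occ in h.occasions]
            if JUVENILE in classes:
                first_adult = classes.index(JUVENILE) + 1
                assert all(c == ADULT for c in classes[first_adult:])


class TestRecruitment:
    def test_ratio(self):
        occasions = make_occasions(2)
        hs = [
            autumn_first_history(occasions, 500.0, individual_id=f"J{i}")
            for i in range(7)
        ] + [
            autumn_first_history(occasions, 900.0, individual_id=f"F{i}",
                                 sex="female")
            for i in range(3)
        ]
        (pt,) = recruitment_per_female(hs)
        assert pt.n_juveniles == 7 and pt.n_adult_females == 3
        assert pt.juveniles_per_female == pytest.approx(7 / 3)

    def test_no_females_is_undefined(self):
        occasions = make_occasions(2)
        hs = [
            autumn_first_history(occasions, 500.0, individual_id=f"J{i}")
            for i in range(2)
        ]
        (pt,) = recruitment_per_female(hs)
        assert not pt.defined


class TestUnmarkedAdults:
    def test_first_occasion_all_unmarked(self):
        ds = make_dataset(
            [(f"A{i}", SPRING, 2015, NIGHT1, "male", 900.0, True) for i in range(4)]
        )
        (pt,) = unmarked_adult_fraction(ds)
        assert pt.pct_unmarked == pytest.approx(100.0)

    def test_fraction(self):
        rows = [
            (f"A{i}", SPRING, 2015, NIGHT1, "male", 900.0, True) for i in range(8)
        ] + [
            (f"A{i}", AUTUMN, 2015, NIGHT1, "male", 900.0, False) for i in range(6)
        ] + [
            (f"B{i}", AUTUMN, 2015, NIGHT1, "male", 900.0, True) for i in range(2)
        ]
        ds = make_dataset(rows)
        pts = unmarked_adult_fraction(ds)
        assert pts[1].n_adults == 8 and pts[1].n_unmarked_adults == 2
        assert pts[1].pct_unmarked == pytest.approx(25.0)

    def test_all_recaptures_zero(self):
        rows = [
            (f"A{i}", SPRING, 2015, NIGHT1, "male", 900.0, True) for i in range(3)
        ] + [
            (f"A{i}", AUTUMN, 2015, NIGHT1, "male", 900.0, False) for i in range(3)
        ]
        pts = unmarked_adult_fraction(make_dataset(rows))
        assert pts[1].pct_unmarked == 0.0


class TestIntervalLosses:
    def test_thirty_percent_overwinter(self):
        occasions = make_occasions(3)  # s2014 a2014 s2015
        hs = []
        for i in range(7):  # survive: seen again in spring
            hs.append(
                history_from_statuses(
                    [NOT_DETECTED, BOTH_NIGHTS, BOTH_NIGHTS], occasions,
                    individual_id=f"S{i}", first_weight=900.0,
                )
            )
        for i in range(3):  # lost after autumn
            hs.append(
                history_from_statuses(
                    [NOT_DETECTED, BOTH_NIGHTS, NOT_DETECTED], occasions,
                    individual_id=f"L{i}", first_weight=900.0,
                )
            )
        losses = interval_losses(hs)
        winter = [l for l in losses if l.kind == "overwinter" and not l.censored]
        assert len(winter) == 1
        assert winter[0].start["adult"] == 10 and winter[0].lost["adult"] == 3
        assert winter[0].pct_lost("adult") == pytest.approx(30.0)

    def test_survivor_lost_only_in_censored_final_interval(self):
        occasions = make_occasions(3)
        h = history_from_statuses(
            [BOTH_NIGHTS, BOTH_NIGHTS, BOTH_NIGHTS], occasions
        )
        losses = interval_losses([h])
        assert [l.lost["adult"] for l in losses] == [0, 0, 1]
        assert [l.censored for l in losses] == [False, False, True]

    def test_gap_interval_is_irregular(self):
        occasions = make_occasions(4, start_year=2019, skip=((SPRING, 2020),))
        # a2019 follows s2019; next is a2020
        h = history_from_statuses(
            [BOTH_NIGHTS, BOTH_NIGHTS, BOTH_NIGHTS, BOTH_NIGHTS], occasions
        )
        kinds = [l.kind for l in interval_losses([h])]
        assert kinds[:3] == ["oversummer", "irregular", "overwinter"]

    def test_matches_true_deaths_at_full_detection(self):
        cfg = SimConfig(n_years=5, per_night_capture_prob=1.0)
        ds, truth = simulate(cfg, seed=8)
        losses = interval_losses(build_histories(ds))
        for l in losses:
            if l.censored or l.to_occasion is None:
                continue
            t0 = l.from_occasion.year + (0.0 if l.from_occasion.season == SPRING else 0.5)
            t1 = l.to_occasion.year + (0.0 if l.to_occasion.season == SPRING else 0.5)
            total_lost = l.lost["adult"] + l.lost["juvenile"]
            assert total_lost == truth.true_losses_between(t0, t1)

    def test_loss_summary_year_window(self):
        occasions = make_occasions(5)
        h = history_from_statuses([BOTH_NIGHTS] * 5, occasions)
        df = loss_summary(interval_losses([h]), 2014, 2015)
        assert set(df["kind"]) == {"overwinter", "oversummer"}
        assert (df["n_intervals"] > 0).any()


class TestLifeTable:
    def test_hand_columns(self):
        rows = life_table_from_counts([10, 4, 1, 0])
        assert [r.Lx for r in rows[:3]] == [7.0, 2.5, 0.5]
        assert rows[0].Tx == pytest.approx(10.0)
        assert rows[0].ex == pytest.approx(1.0)
        assert rows[1].ex == pytest.approx(3.0 / 4.0)
        assert [r.dx for r in rows[:3]] == [6, 3, 1]

    def test_singleton_cohort(self):
        rows = life_table_from_counts([1])
        assert rows[0].ex == pytest.approx(0.5)

    def test_monotone_and_conserving(self):
        rows = life_table_from_counts([12, 7, 7, 2, 0])
        lx = [r.lx for r in rows]
        assert lx == sorted(lx, reverse=True)
        assert sum(r.dx for r in rows) == 12
        tx = [r.Tx for r in rows]
        assert tx == sorted(tx, reverse=True)

    def test_decreasing_counts_required(self):
        with pytest.raises(ValueError):
            life_table_from_counts([3, 5])

    def test_from_histories_ages_on_autumn_anniversaries(self):
        occasions = make_occasions(6)  # s14 a14 s15 a15 s16 a16
        # juvenile caught autumn 2014; seen to spring 2016 (age 1, not 2)
        h1 = history_from_statuses(
            [NOT_DETECTED, BOTH_NIGHTS, NOT_DETECTED, BOTH_NIGHTS, BOTH_NIGHTS,
             NOT_DETECTED],
            occasions, individual_id="A", first_weight=500.0,
        )
        # juvenile caught autumn 2014, never again (age 0)
        h2 = history_from_statuses(
            [NOT_DETECTED, BOTH_NIGHTS] + [NOT_DETECTED] * 4,
            occasions, individual_id="B", first_weight=450.0,
        )
        rows = life_table([h1, h2], cohort_years=[2014])
        assert [r.lx for r in rows] == [2, 1, 0]

    def test_recovers_true_survivors_at_full_detection(self):
        cfg = SimConfig(n_years=6, per_night_capture_prob=1.0)
        ds, truth = simulate(cfg, seed=3)
        cohort_years = range(2014, 2018)
        rows = life_table(build_histories(ds), cohort_years=cohort_years)
        last_time = 2019.5
        members = [
            f for f in truth.individuals
            if f.entry == "autumn_born" and f.born_year in cohort_years
        ]
        for r in rows:
            if r.lx == 0:
                continue
            true_lx = sum(
                1 for f in members
                if f.born_year + r.x + 0.5 <= last_time
                and f.alive_at(f.born_year + r.x + 0.5)
            )
            assert r.lx == true_lx


class TestWeights:
    def test_within_survey_mean_and_group_stats(self):
        rows = [
            ("A", AUTUMN, 2015, NIGHT1, "male", 800.0),
            ("A", AUTUMN, 2015, NIGHT2, "male", 900.0),
            ("B", AUTUMN, 2015, NIGHT1, "female", 1000.0),
        ]
        df = weight_summary(make_dataset(rows))
        autumn_all = df[(df.sex == "all") & (df.season == AUTUMN)].iloc[0]
        assert autumn_all["n"] == 2
        assert autumn_all["mean_g"] == pytest.approx(925.0)  # (850 + 1000)/2
        assert autumn_all["sd_g"] == pytest.approx(np.std([850, 1000], ddof=1))

    def test_juveniles_excluded(self):
        rows = [
            ("A", AUTUMN, 2015, NIGHT1, "male", 500.0, True),  # juvenile
            ("B", AUTUMN, 2015, NIGHT1, "male", 900.0, True),
        ]
        df = weight_summary(make_dataset(rows))
        autumn_all = df[(df.sex == "all") & (df.season == AUTUMN)].iloc[0]
        assert autumn_all["n"] == 1

    def test_recovers_generating_means(self):
        cfg = SimConfig(n_years=8, per_night_capture_prob=1.0)
        ds, _ = simulate(cfg, seed=6)
        df = weight_summary(ds)
        row = df[(df.sex == "all") & (df.season == AUTUMN)].iloc[0]
        se = row["sd_g"] / np.sqrt(row["n"])
        assert abs(row["mean_g"] - 952.0) < 3 * se


class TestMortality:
    def test_all_predation_related_juveniles(self):
        deaths = [
            DeathRecord("A", dt.date(2016, 7, 1), "juvenile", "predation"),
            DeathRecord("B", dt.date(2016, 8, 1), "juvenile", "leg_injury"),
        ]
        summary = mortality_tabulation(deaths)
        assert summary.pct_predation_related["juvenile"] == pytest.approx(100.0)

    def test_empty(self):
        summary = mortality_tabulation([])
        assert summary.n_deaths == 0
        assert summary.by_cause.values.sum() == 0
        assert summary.pct_marked is None

    def test_marked_percentage(self):
        deaths = [
            DeathRecord(f"M{i}", dt.date(2017, 5, 1), "adult", "road", marked=True)
            for i in range(13)
        ] + [
            DeathRecord(None, dt.date(2017, 6, 1), "adult", "road", marked=False)
            for i in range(9)
        ]
        summary = mortality_tabulation(deaths)
        assert round(summary.pct_marked) == 59  # 13 of 22
        assert summary.by_month.loc[5, "adult"] == 13
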