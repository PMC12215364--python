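import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothtraj import (OccurrenceTable, TrajectoryConfig, aggregate_to_periods,
                      filter_trajectories, load_occurrence, run_campaign,
                      weekly_periods)
from mothtraj.occurrence import complete, load_sites, period_containing

from conftest import occ_table, uniform_field


class TestPeriods:
    def test_weekly_bins_with_truncated_tail(self):
        ps = weekly_periods("2022-04-03", "2022-06-29")
        assert ps[0].period_id == "04/03-04/09"
        assert ps[6].period_id == "05/15-05/21"
        assert ps[-1].period_id == "06/26-06/29"       # truncated final bin
        assert len(ps) == 13

    def test_membership_inclusive_on_both_ends(self):
        ps = weekly_periods("2022-04-03", "2022-04-16")
        assert period_containing("2022-04-09", ps).period_id == "04/03-04/09"
        assert period_containing("2022-04-10", ps).period_id == "04/10-04/16"
        assert period_containing("2022-04-03", ps).period_id == "04/03-04/09"
        assert period_containing("2022-04-17", ps) is None


class TestLoad:
    def test_daily_csv(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("site_id,date,count\nNH,2022-04-03,5\nNH,2022-04-04,0\n")
        t = load_occurrence(p)
        assert t.native_resolution == "daily"
        assert t.total() == 5

    def test_negative_count_names_row(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("site_id,date,count\nNH,2022-04-03,5\nBD,2022-04-03,-1\n")
        with pytest.raises(ValueError, match="row 1"):
            load_occurrence(p)

    def test_unknown_site_rejected(self, tmp_path):
        occ = tmp_path / "occ.csv"
        occ.write_text("site_id,date,count\nZZ,2022-04-03,5\n")
        sites = tmp_path / "sites.csv"
        sites.write_text("site_id,country,lat,lon\nNH,destination,34.8,127.9\n")
        with pytest.raises(ValueError, match="ZZ"):
            load_occurrence(occ, sites)

    def test_bad_date_rejected(self, tmp_path):
        p = tmp_path / "occ.csv"
        p.write_text("site_id,date,count\nNH,not-a-date,5\n")
        with pytest.raises(ValueError, match="date"):
            load_occurrence(p)

    def test_complete_fills_missing_with_zero(self):
        ps = weekly_periods("2022-04-03", "2022-07-01")[:13]
        t = occ_table([("S1", ps[0].period_id, 3)])
        sites = [f"S{i}" for i in range(1, 19)]
        full = complete(t, sites, ps)
        assert len(full.df) == 18 * 13
        assert full.total() == 3

    def test_sites_csv(self, tmp_path):
        p = tmp_path / "sites.csv"
        p.write_text("site_id,country,lat,lon\nNH,destination,34.8,127.9\n"
                     "BD,origin,38.8,115.5\n")
        sites = load_sites(p)
        assert [s.site_id for s in sites] == ["NH", "BD"]
        assert sites[1].country == "origin"


class TestAggregate:
    def make_daily(self, rows):
        df = pd.DataFrame(rows, columns=["site_id", "date", "count"])
        df["period_id"] = df["date"]
        df["date"] = pd.to_datetime(df["date"]).dt.date
        return OccurrenceTable(df[["site_id", "period_id", "count", "date"]],
                               native_resolution="daily")

    def test_sum_within_one_period(self):
        daily = self.make_daily([("A", "2022-04-04", 1), ("A", "2022-04-05", 2),
                                 ("A", "2022-04-06", 3)])
        ps = weekly_periods("2022-04-03", "2022-04-09")
        agg = aggregate_to_periods(daily, ps)
        assert agg.count_for("A", "04/03-04/09") == 6

    def test_boundary_end_date_included(self):
        daily = self.make_daily([("A", "2022-04-09", 4)])
        ps = weekly_periods("2022-04-03", "2022-04-16")
        agg = aggregate_to_periods(daily, ps)
        assert agg.count_for("A", "04/03-04/09") == 4
        assert agg.count_for("A", "04/10-04/16") == 0

    def test_days_outside_periods_dropped_and_conserved(self):
        daily = self.make_daily([("A", "2022-04-01", 7), ("A", "2022-04-04", 2)])
        ps = weekly_periods("2022-04-03", "2022-04-09")
        agg = aggregate_to_periods(daily, ps)
        assert agg.total() == 2
        assert agg.dropped_count == 7
        assert agg.total() + agg.dropped_count == daily.total()

    def test_overlapping_periods_rejected(self):
        from mothtraj import SamplingPeriod
        daily = self.make_daily([("A", "2022-04-04", 1)])
        bad = [SamplingPeriod("p1", dt.date(2022, 4, 3), dt.date(2022, 4, 9)),
               SamplingPeriod("p2", dt.date(2022, 4, 9), dt.date(2022, 4, 15))]
        with pytest.raises(ValueError, match="overlap"):
            aggregate_to_periods(daily, bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 50)),
                    min_size=1, max_size=30))
    def test_aggregation_conserves_totals(self, day_counts):
        base = dt.date(2022, 4, 3)
        rows = [("A", str(base + dt.timedelta(days=off)), c)
                for off, c in day_counts]
        df = pd.DataFrame(rows, columns=["site_id", "date", "count"])
        df = df.drop_duplicates("date")
        daily = self.make_daily(list(df.itertuples(index=False, name=None)))
        ps = weekly_periods("2022-04-03", "2022-04-30")
        agg = aggregate_to_periods(daily, ps)
        assert agg.total() + agg.dropped_count == daily.total()


class TestFilter:
    @pytest.fixture
    def ensemble(self):
        f = uniform_field(u=5.0, v=0.0, t0="2022-04-01", days=20)
        c = TrajectoryConfig(direction="forward", duration=6, daily_hours=(0, 12))
        return run_campaign([("A", 0.0, 0.0), ("B", 2.0, 2.0)],
                            ["2022-04-04", "2022-04-12"], c, f)

    def test_zero_count_site_excluded(self, ensemble):
        ps = weekly_periods("2022-04-03", "2022-04-16")
        occ = occ_table([("A", p.period_id, 5) for p in ps]
                        + [("B", p.period_id, 0) for p in ps])
        kept = filter_trajectories(ensemble, occ, ps)
        assert {t.site_id for t in kept} == {"A"}
        assert len(kept) == 4

    def test_all_positive_is_identity(self, ensemble):
        ps = weekly_periods("2022-04-03", "2022-04-16")
        occ = occ_table([(s, p.period_id, 1) for s in ("A", "B") for p in ps])
        kept = filter_trajectories(ensemble, occ, ps)
        assert len(kept) == len(ensemble)
        assert [id(t) for t in kept] == [id(t) for t in ensemble]

    def test_release_outside_all_periods_dropped(self, ensemble):
        ps = weekly_periods("2022-04-10", "2022-04-16")   # first release day excluded
        occ = occ_table([(s, ps[0].period_id, 9) for s in ("A", "B")])
        kept = filter_trajectories(ensemble, occ, ps)
        assert all(t.init_time.date() >= ps[0].start for t in kept)
        assert len(kept) == 4

    def test_filtering_is_idempotent(self, ensemble):
        ps = weekly_periods("2022-04-03", "2022-04-16")
        occ = occ_table([("A", ps[0].period_id, 2), ("B", ps[1].period_id, 1)])
        once = filter_trajectories(ensemble, occ, ps)
        twice = filter_trajectories(once, occ, ps)
        assert [id(t) for t in twice] == [id(t) for t in once]

    def test_filtered_cardinality_matches_positive_cells(self, ensemble):
        ps = weekly_periods("2022-04-03", "2022-04-16")
        occ = occ_table([("A", ps[0].period_id, 2), ("A", ps[1].period_id, 0),
                         ("B", ps[0].period_id, 0), ("B", ps[1].period_id, 3)])
        kept = filter_trajectories(ensemble, occ, ps)
        expected = sum(
            1 for t in ensemble
            if occ.count_for(t.site_id,
                             period_containing(t.init_time.date(), ps).period_id) > 0
        )
        assert len(kept) == expected == 4
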