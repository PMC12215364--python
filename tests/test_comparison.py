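import numpy as np
import pandas as pd
import pytest
import shapely

from mothtraj import (ComparisonGrid, Target, TrapSite, classify_cases,
                      hit_ratio, match_candidates, trajectory_crosses,
                      weekly_periods)
from mothtraj.comparison import HitRatio, target_from_buffer

from conftest import make_ensemble, make_traj, occ_table

PERIODS = weekly_periods("2022-04-03", "2022-04-16")   # two weekly bins
BOX = shapely.box(10.0, 10.0, 12.0, 12.0)


def grid_from(rows, sites, periods=None):
    pids = [p.period_id for p in (periods or PERIODS)][: len(rows)]
    return ComparisonGrid(pd.DataFrame(rows, index=pids, columns=sites))


class TestCrosses:
    def test_point_inside_polygon_crosses(self):
        t = make_traj([(5.0, 5.0), (11.0, 11.0)], init="2022-04-04")
        assert trajectory_crosses(make_ensemble([t]), BOX, PERIODS[0])

    def test_empty_ensemble_never_crosses(self):
        assert not trajectory_crosses(make_ensemble([]), BOX, PERIODS[0])

    def test_straddling_without_interior_point_does_not_cross(self):
        t = make_traj([(11.0, 9.0), (11.0, 13.0)], init="2022-04-04")
        assert not trajectory_crosses(make_ensemble([t]), BOX, PERIODS[0])

    def test_densification_can_turn_straddle_into_cross(self):
        t = make_traj([(11.0, 9.0), (11.0, 13.0)], init="2022-04-04")
        assert trajectory_crosses(make_ensemble([t]), BOX, PERIODS[0], densify=8)

    def test_release_in_other_period_ignored(self):
        t = make_traj([(11.0, 11.0)], init="2022-04-12")
        assert not trajectory_crosses(make_ensemble([t]), BOX, PERIODS[0])
        assert trajectory_crosses(make_ensemble([t]), BOX, PERIODS[1])


class TestClassify:
    def setup_method(self):
        site = TrapSite("T1", "origin", 11.0, 11.0)
        self.targets = [Target(site, BOX)]

    def classify(self, ens, count):
        occ = occ_table([("T1", p.period_id, count) for p in PERIODS])
        return classify_cases(ens, occ, self.targets, PERIODS)

    def test_cross_and_capture_is_OO(self):
        ens = make_ensemble([make_traj([(11.0, 11.0)], init="2022-04-04"),
                             make_traj([(11.0, 11.0)], init="2022-04-12")])
        g = self.classify(ens, count=3)
        assert set(g.df["T1"]) == {"OO"}

    def test_cross_without_capture_is_OX(self):
        ens = make_ensemble([make_traj([(11.0, 11.0)], init="2022-04-04"),
                             make_traj([(11.0, 11.0)], init="2022-04-12")])
        assert set(self.classify(ens, count=0).df["T1"]) == {"OX"}

    def test_capture_without_cross_is_XO(self):
        ens = make_ensemble([make_traj([(5.0, 5.0)], init="2022-04-04")])
        assert set(self.classify(ens, count=2).df["T1"]) == {"XO"}

    def test_neither_is_XX(self):
        assert set(self.classify(make_ensemble([]), count=0).df["T1"]) == {"XX"}

    def test_missing_occurrence_treated_as_zero(self):
        ens = make_ensemble([make_traj([(11.0, 11.0)], init="2022-04-04")])
        occ = occ_table([("T1", PERIODS[0].period_id, 1)])   # week 2 missing
        g = classify_cases(ens, occ, self.targets, PERIODS)
        assert g.label(PERIODS[0].period_id, "T1") == "OO"
        assert g.label(PERIODS[1].period_id, "T1") == "XX"

    def test_label_partition_sums_to_grid_size(self):
        rng = np.random.default_rng(1)
        sites = [TrapSite(f"T{i}", "origin", 11.0, 11.0) for i in range(4)]
        targets = [Target(s, BOX) for s in sites]
        trajs = [make_traj([(float(rng.uniform(5, 13)), float(rng.uniform(5, 13)))],
                           init=f"2022-04-{rng.integers(3, 17):02d}")
                 for _ in range(12)]
        occ = occ_table([(s.site_id, p.period_id, int(rng.integers(0, 3)))
                         for s in sites for p in PERIODS])
        g = classify_cases(make_ensemble(trajs), occ, targets, PERIODS)
        assert sum(g.counts().values()) == len(sites) * len(PERIODS)


class TestHitRatio:
    def test_all_OO_location_is_100(self):
        g = grid_from([["OO"], ["OO"]], ["HN"])
        (r,) = hit_ratio(g, by="location")
        assert r.ratio_percent == 100.0 and r.defined

    def test_all_XO_location_is_0_and_undefined(self):
        g = grid_from([["XO"], ["XO"]], ["NH"])
        (r,) = hit_ratio(g, by="location")
        assert r.ratio_percent == 0.0 and not r.defined

    def test_mixed_OO_OX_is_50(self):
        g = grid_from([["OO"], ["OX"]], ["LY"])
        (r,) = hit_ratio(g, by="location")
        assert r.ratio_percent == pytest.approx(50.0)

    def test_by_period_uses_rows(self):
        g = grid_from([["OO", "OX", "XO"], ["XX", "XX", "XX"]],
                      ["A", "B", "C"])
        rows = hit_ratio(g, by="period")
        assert rows[0].ratio_percent == pytest.approx(50.0)
        assert not rows[1].defined

    def test_XO_XX_cells_never_affect_ratios(self):
        base = grid_from([["OO", "XO"], ["OX", "XX"]], ["A", "B"])
        flipped = grid_from([["OO", "XX"], ["OX", "XO"]], ["A", "B"])
        for by in ("location", "period"):
            got = [(r.ratio_percent, r.defined) for r in hit_ratio(base, by)]
            exp = [(r.ratio_percent, r.defined) for r in hit_ratio(flipped, by)]
            assert got == exp

    def test_invalid_axis_rejected(self):
        with pytest.raises(ValueError):
            hit_ratio(grid_from([["OO"]], ["A"]), by="site")

    def test_ratio_bounds(self):
        for n_oo in range(4):
            for n_ox in range(4):
                r = HitRatio.from_counts("k", n_oo, n_ox)
                assert 0.0 <= r.ratio_percent <= 100.0


class TestMatching:
    """Hand-constructed two-country scenario, traced manually.

    Origin trap O at (11, 11) in polygon box(10,10,12,12); destinations
    D1 (11, 31) and D2 (13, 31) with 1-degree boxes around them.  In week 1
    the backward parcel from D1 reaches O's polygon, the forward parcel
    from O reaches D1's polygon, and both comparisons are OO -> exactly the
    pair (O, D1) in week 1.
    """

    def setup_method(self):
        self.origin = Target(TrapSite("O", "origin", 11.0, 11.0), BOX)
        self.d1 = Target(TrapSite("D1", "destination", 11.0, 31.0),
                         shapely.box(30.5, 10.5, 31.5, 11.5))
        self.d2 = Target(TrapSite("D2", "destination", 13.0, 31.0),
                         shapely.box(30.5, 12.5, 31.5, 13.5))
        # backward parcels released at destinations, heading west
        self.back = make_ensemble([
            make_traj([(11.0, 31.0), (11.0, 21.0), (11.0, 11.0)],
                      site_id="D1", init="2022-04-04", direction="backward"),
            make_traj([(13.0, 31.0), (13.0, 21.0), (13.0, 15.0)],
                      site_id="D2", init="2022-04-04", direction="backward"),
        ], direction="backward")
        self.fwd = make_ensemble([
            make_traj([(11.0, 11.0), (11.0, 21.0), (11.0, 31.0)],
                      site_id="O", init="2022-04-04")])

    def match(self, bg, fg):
        return match_candidates(bg, fg, self.back, self.fwd, [self.origin],
                                [self.d1, self.d2], PERIODS)

    def test_planted_single_pair_recovered(self):
        bg = grid_from([["OO"], ["XX"]], ["O"])
        fg = grid_from([["OO", "XO"], ["XX", "XX"]], ["D1", "D2"])
        pairs = self.match(bg, fg)
        assert [(c.origin_site, c.destination_site, c.period_id)
                for c in pairs] == [("O", "D1", PERIODS[0].period_id)]

    def test_no_forward_OO_means_no_pair(self):
        bg = grid_from([["OO"], ["XX"]], ["O"])
        fg = grid_from([["OX", "XO"], ["XX", "XX"]], ["D1", "D2"])
        assert self.match(bg, fg) == []

    def test_two_destinations_give_two_pairs(self):
        # give D2's backward parcel a point inside the origin polygon and a
        # forward parcel toward D2's polygon
        self.back = make_ensemble([
            self.back.trajectories[0],
            make_traj([(13.0, 31.0), (12.0, 21.0), (11.0, 11.0)],
                      site_id="D2", init="2022-04-04", direction="backward"),
        ], direction="backward")
        self.fwd = make_ensemble([
            self.fwd.trajectories[0],
            make_traj([(11.0, 11.0), (13.0, 21.0), (13.0, 31.0)],
                      site_id="O", init="2022-04-04")])
        bg = grid_from([["OO"], ["XX"]], ["O"])
        fg = grid_from([["OO", "OO"], ["XX", "XX"]], ["D1", "D2"])
        pairs = self.match(bg, fg)
        assert {(c.origin_site, c.destination_site) for c in pairs} == \
            {("O", "D1"), ("O", "D2")}
        assert all(c.period_id == PERIODS[0].period_id for c in pairs)

    def test_period_mismatch_rejected(self):
        bg = grid_from([["OO"], ["XX"]], ["O"])
        other = weekly_periods("2022-05-01", "2022-05-14")
        fg = grid_from([["OO", "OO"], ["XX", "XX"]], ["D1", "D2"],
                       periods=other)
        with pytest.raises(ValueError, match="period"):
            self.match(bg, fg)

    def test_emitted_pairs_have_replayable_crossings(self):
        bg = grid_from([["OO"], ["XX"]], ["O"])
        fg = grid_from([["OO", "XO"], ["XX", "XX"]], ["D1", "D2"])
        for c in self.match(bg, fg):
            back_from_dest = self.back.subset(
                lambda t: t.site_id == c.destination_site)
            fwd_from_origin = self.fwd.subset(
                lambda t: t.site_id == c.origin_site)
            period = next(p for p in PERIODS if p.period_id == c.period_id)
            assert trajectory_crosses(back_from_dest, self.origin.polygon, period)
            assert trajectory_crosses(fwd_from_origin, self.d1.polygon, period)


def test_buffer_target_contains_trap_and_scales_with_radius():
    site = TrapSite("T", "origin", 35.0, 120.0)
    small = target_from_buffer(site, 10.0)
    big = target_from_buffer(site, 100.0)
    assert small.polygon.covers(shapely.Point(120.0, 35.0))
    assert big.polygon.covers(small.polygon)
    # 100 km buffer reaches ~0.9 deg of latitude
    assert big.polygon.bounds[3] == pytest.approx(35.0 + 100 / 111.32, abs=0.02)


def test_invalid_case_label_rejected():
    with pytest.raises(ValueError):
        ComparisonGrid(pd.DataFrame({"A": ["OO", "ZZ"]},
                                    index=["p1", "p2"]))
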