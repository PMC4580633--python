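"""Covariate computations against hand-worked oracles."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from killcluster import ClusterParams, assign_season, detect_clusters
from killcluster.covariates import (
    CovariateParams,
    build_covariate_table,
    compute_activity,
    compute_groundtruth_covs,
    compute_spatiotemporal,
)
from killcluster.schedule import FixSchedule

SCHEDULE = FixSchedule()
PARAMS = CovariateParams()


def _one_cluster(make_fixes, rows, **kw):
    df = make_fixes(rows, **kw)
    clusters = detect_clusters(df, SCHEDULE, ClusterParams())
    assert len(clusters) == 1
    return clusters[0], df


class TestSpatiotemporal:
    def test_center_two_members(self, make_fixes):
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 120, 0)],
        )
        out = compute_spatiotemporal(c, df)
        assert out["CENTER"] == pytest.approx(60.0)
        assert out["POSCOUNT"] == 2
        assert out["TIMEBIN24"] is False

    def test_nightprop_all_night(self, make_fixes):
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T21:00:00", 0, 0), ("2011-01-02T02:00:00", 50, 0)],
        )
        out = compute_spatiotemporal(c, df)
        assert out["NIGHTPROP"] == 1.0

    def test_five_member_hand_computation(self, make_fixes):
        # cross of 4 points 100 m from center plus the center itself
        rows = [
            ("2011-01-01T02:00:00", 100, 0),
            ("2011-01-01T05:00:00", -100, 0),
            ("2011-01-01T08:00:00", 0, 100),
            ("2011-01-01T12:00:00", 0, -100),
            ("2011-01-02T16:00:00", 0, 0),
        ]
        c, df = _one_cluster(make_fixes, rows)
        out = compute_spatiotemporal(c, df)
        assert out["POSCOUNT"] == 5
        assert out["CENTER"] == pytest.approx(80.0)  # (4*100 + 0) / 5
        assert out["NIGHTPROP"] == pytest.approx(2 / 5)  # 02:00 and 05:00
        assert out["TIMEBIN24"] is True  # 02:00 day1 -> 16:00 day2


class TestActivity:
    def _records(self, times, ax, ay):
        starts = pd.to_datetime(times).to_numpy()
        order = np.argsort(starts)
        return (
            starts[order],
            np.asarray(ax, float)[order],
            np.asarray(ay, float)[order],
        )

    def test_constant_records(self, make_fixes):
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 50, 0)],
        )
        starts, ax, ay = self._records(
            ["2011-01-01T02:00:00", "2011-01-01T05:00:00"], [100, 100], [100, 100]
        )
        out = compute_activity(c, df, starts, ax, ay, PARAMS)
        assert out == {"ACCX": 100.0, "ACCY": 100.0, "ACCXYDIFF": 0.0}

    def test_no_records_all_missing(self, make_fixes):
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 50, 0)],
        )
        starts, ax, ay = self._records(["2011-01-02T12:00:00"], [5], [5])
        out = compute_activity(c, df, starts, ax, ay, PARAMS)
        assert all(np.isnan(v) for v in out.values())

    def test_two_stage_mean_hand_case(self, make_fixes):
        # fix1 at 02:00 with blocks ax 10, 20; fix2 at 08:00 with block ax 30
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T08:00:00", 50, 0)],
        )
        starts, ax, ay = self._records(
            ["2011-01-01T01:00:00", "2011-01-01T03:00:00", "2011-01-01T07:30:00"],
            [10, 20, 30],
            [0, 0, 0],
        )
        out = compute_activity(c, df, starts, ax, ay, PARAMS)
        assert out["ACCX"] == pytest.approx(np.mean([15.0, 30.0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_two_stage_diff_identity(self, seed, make_fixes):
        """ACCXYDIFF from per-block differences equals ACCX - ACCY exactly
        when every member window holds at least one block (equal weights)."""
        rng = np.random.default_rng(seed)
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 50, 0)],
        )
        n = 40
        t0 = pd.Timestamp("2011-01-01T00:45:00")
        starts = (t0 + pd.to_timedelta(288 * np.arange(n), "s")).to_numpy()
        ax = rng.integers(0, 256, n).astype(float)
        ay = rng.integers(0, 256, n).astype(float)
        out = compute_activity(c, df, starts, ax, ay, PARAMS)
        assert out["ACCXYDIFF"] == pytest.approx(
            out["ACCX"] - out["ACCY"], abs=1e-9
        )

    def test_reorder_invariance(self, small_sim, small_sim_covariates):
        cfg = small_sim.truth.config
        shuffled = small_sim.activity.sample(
            frac=1.0, random_state=1
        ).sort_values(["animal_id", "start"]).reset_index(drop=True)
        again = build_covariate_table(
            small_sim.clusters, small_sim.fixes, shuffled, small_sim.visits,
            cfg.schedule,
        )
        pd.testing.assert_frame_equal(again, small_sim_covariates)


class TestGroundtruth:
    def test_fixrate_perfect(self, make_fixes):
        # every scheduled slot over 4 days acquired
        rows = []
        for d in range(1, 5):
            for s in ("02:00", "05:00", "08:00", "12:00", "16:00", "19:00", "21:00"):
                rows.append((f"2011-01-0{d}T{s}:00", 0.0, 0.0))
        df = make_fixes(rows)
        clusters = detect_clusters(df, SCHEDULE, ClusterParams())
        c = clusters[0]
        out = compute_groundtruth_covs(
            c, df, np.sort(df["slot_dt"].to_numpy()), SCHEDULE,
            (df["time"].iloc[0], df["time"].iloc[-1]),
        )
        assert out["FIXRATE"] == pytest.approx(1.0)
        assert out["FIELDPROP"] == 1.0

    def test_fixrate_hand_counted_misses(self, make_fixes):
        """4-day schedule with 3 specific slots missing; FIXRATE for a
        2-member cluster equals the enumerated slot-count ratio."""
        missing = {
            ("2011-01-02", "08:00"),
            ("2011-01-02", "16:00"),
            ("2011-01-03", "05:00"),
        }
        rows = []
        for d in ("2011-01-01", "2011-01-02", "2011-01-03", "2011-01-04"):
            for s in ("02:00", "05:00", "08:00", "12:00", "16:00", "19:00", "21:00"):
                if (d, s) not in missing:
                    # fixes mostly far apart; two of them form the cluster
                    rows.append((f"{d}T{s}:00", 1e6, 1e6))
        # overwrite two fixes to sit together (the cluster): day2 02:00, 05:00
        df = make_fixes(rows)
        df.loc[df["time"] == "2011-01-02T02:00:00", ["x", "y"]] = (0.0, 0.0)
        df.loc[df["time"] == "2011-01-02T05:00:00", ["x", "y"]] = (50.0, 0.0)
        clusters = detect_clusters(df, SCHEDULE, ClusterParams())
        c = next(cl for cl in clusters if cl.n_members == 2 and cl.centroid[0] < 1000)
        deployment = (df["time"].iloc[0], df["time"].iloc[-1])
        out = compute_groundtruth_covs(
            c, df, np.sort(df["slot_dt"].to_numpy()), SCHEDULE, deployment
        )
        # hand enumeration: windows are +-48 h clipped to the deployment
        expected = []
        for t in (pd.Timestamp("2011-01-02T02:00:00"),
                  pd.Timestamp("2011-01-02T05:00:00")):
            lo = max(t - pd.Timedelta(hours=48), deployment[0])
            hi = min(t + pd.Timedelta(hours=48), deployment[1])
            slots = SCHEDULE.occurrences(lo.to_pydatetime(), hi.to_pydatetime())
            acq = sum(
                1 for s in slots
                if (s.strftime("%Y-%m-%d"), s.strftime("%H:%M")) not in missing
            )
            expected.append(acq / len(slots))
        assert out["FIXRATE"] == pytest.approx(np.mean(expected))

    def test_fieldprop_all_none(self, make_fixes):
        rows = [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 50, 0)]
        c, df = _one_cluster(make_fixes, rows, downloaded=[True, True])
        out = compute_groundtruth_covs(
            c, df, np.sort(df["slot_dt"].to_numpy()), SCHEDULE,
            (df["time"].iloc[0], df["time"].iloc[-1]),
        )
        assert out["FIELDPROP"] == 1.0
        c2, df2 = _one_cluster(make_fixes, rows, downloaded=[False, False])
        out2 = compute_groundtruth_covs(
            c2, df2, np.sort(df2["slot_dt"].to_numpy()), SCHEDULE,
            (df2["time"].iloc[0], df2["time"].iloc[-1]),
        )
        assert out2["FIELDPROP"] == 0.0

    def test_negative_search_lag_rejected(self, make_fixes):
        c, df = _one_cluster(
            make_fixes,
            [("2011-01-05T02:00:00", 0, 0), ("2011-01-05T05:00:00", 50, 0)],
        )
        with pytest.raises(ValueError, match="negative"):
            compute_groundtruth_covs(
                c, df, np.sort(df["slot_dt"].to_numpy()), SCHEDULE,
                (df["time"].iloc[0], df["time"].iloc[-1]),
                visit_time=pd.Timestamp("2011-01-01"),
            )


class TestSeason:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (date(2011, 7, 4), "SUM"),
            (date(2011, 6, 1), "SUM"),
            (date(2011, 9, 30), "SUM"),
            (date(2011, 1, 15), "FAL"),
            (date(2011, 1, 16), "WIN"),
            (date(2011, 12, 31), "FAL"),
            (date(2011, 10, 1), "FAL"),
            (date(2011, 5, 31), "WIN"),
        ],
    )
    def test_boundaries(self, d, expected):
        assert assign_season(d) == expected

    def test_tiles_the_year(self):
        d = pd.Timestamp("2011-01-01")
        seen = set()
        while d.year == 2011:
            seen.add(assign_season(d))
            d += pd.Timedelta(days=1)
        assert seen == {"SUM", "FAL", "WIN"}
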