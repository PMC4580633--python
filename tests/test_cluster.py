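"""Cluster detection against an independent brute-force replay of the rules."""

import math
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from killcluster import ClusterParams, detect_clusters, truncate_fixes
from killcluster.schedule import FixSchedule

SCHEDULE = FixSchedule()
PARAMS = ClusterParams()


# ---------------------------------------------------------------------------
# Brute-force oracle: a plain, slow replay of the stated formation rules.
# ---------------------------------------------------------------------------

def _slots_between(t1: datetime, t2: datetime) -> int:
    count = 0
    d = t1.date() - timedelta(days=1)
    while d <= t2.date() + timedelta(days=1):
        for st in SCHEDULE.slot_times:
            occ = datetime.combine(d, st)
            if t1 < occ < t2:
                count += 1
        d += timedelta(days=1)
    return count


def oracle_clusters(times, xy, params: ClusterParams):
    """Exhaustive-scan replay: greedy seeding, centroid joining with repeated
    passes, farthest-first pruning, then consecutive-pair S2 formation."""
    n = len(times)
    t_days = [(t - times[0]).total_seconds() / 86400.0 for t in times]
    assigned = [False] * n
    forbidden = set()
    s1 = []

    def dist(a, b):
        return math.hypot(a[0] - b[0], a[1] - b[1])

    while True:
        seed = None
        for i in range(n):
            if assigned[i]:
                continue
            for j in range(i + 1, n):
                if assigned[j] or (i, j) in forbidden:
                    continue
                if (
                    t_days[j] - t_days[i] <= params.window_days
                    and dist(xy[i], xy[j]) <= params.radius_m
                ):
                    seed = (i, j)
                    break
            if seed:
                break
        if seed is None:
            break
        i, j = seed
        members = [i, j]
        assigned[i] = assigned[j] = True
        changed = True
        while changed:
            changed = False
            for k in range(i + 1, n):
                if assigned[k]:
                    continue
                centroid = (
                    sum(xy[m][0] for m in members) / len(members),
                    sum(xy[m][1] for m in members) / len(members),
                )
                latest = max(t_days[m] for m in members)
                if (
                    t_days[k] - latest <= params.window_days
                    and dist(xy[k], centroid) <= params.radius_m
                ):
                    members.append(k)
                    assigned[k] = True
                    changed = True
        members = sorted(members)
        while len(members) > 2:
            centroid = (
                sum(xy[m][0] for m in members) / len(members),
                sum(xy[m][1] for m in members) / len(members),
            )
            dists = [dist(xy[m], centroid) for m in members]
            far = dists.index(max(dists))
            if dists[far] <= params.radius_m:
                break
            assigned[members[far]] = False
            members.pop(far)
        if len(members) == 2:
            centroid = (
                (xy[members[0]][0] + xy[members[1]][0]) / 2,
                (xy[members[0]][1] + xy[members[1]][1]) / 2,
            )
            if max(dist(xy[m], centroid) for m in members) > params.radius_m:
                for m in members:
                    assigned[m] = False
                forbidden.add(seed)
                continue
        s1.append(tuple(members))

    s2 = []
    for k in range(n - 1):
        if assigned[k] or assigned[k + 1]:
            continue
        d = dist(xy[k], xy[k + 1])
        if params.s2_min_m < d <= params.s2_max_m and _slots_between(
            times[k], times[k + 1]
        ) == 1:
            assigned[k] = assigned[k + 1] = True
            s2.append((k, k + 1))
    return s1, s2


def _random_instance(rng, n_max=30):
    """Random track on the collar schedule with a few attracting centers."""
    start = datetime(2011, 3, 1)
    occs = SCHEDULE.occurrences(start, start + timedelta(days=5))
    keep = rng.random(len(occs)) < 0.75
    times = [t for t, k in zip(occs, keep) if k][:n_max]
    centers = rng.uniform(0, 1200, size=(3, 2))
    xy = []
    for _ in times:
        if rng.random() < 0.6:
            c = centers[rng.integers(3)]
            xy.append(tuple(c + rng.normal(0, 90, 2)))
        else:
            xy.append(tuple(rng.uniform(0, 1200, 2)))
    return times, xy


def _frame(times, xy, schedule=SCHEDULE):
    df = pd.DataFrame(
        {
            "animal_id": "A",
            "time": pd.to_datetime(times),
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "downloaded": True,
        }
    )
    df["slot"] = [FixSchedule.label(t.time()) for t in df["time"]]
    df["slot_dt"] = df["time"]
    df["night"] = [t.time() in schedule.night_slots for t in df["time"]]
    return df


def _memberships(clusters, df):
    pos = {label: i for i, label in enumerate(df.index)}
    return sorted(
        (c.kind, tuple(pos[m] for m in c.member_index)) for c in clusters
    )


class TestDetection:
    def test_single_fix_no_cluster(self, make_fixes):
        df = make_fixes([("2011-01-01T02:00:00", 0, 0)])
        assert detect_clusters(df, SCHEDULE, PARAMS) == []

    def test_two_close_fixes_form_s1(self, make_fixes):
        df = make_fixes(
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 100, 0)]
        )
        (c,) = detect_clusters(df, SCHEDULE, PARAMS)
        assert c.kind == "S1"
        assert c.n_members == 2
        assert c.centroid == (50.0, 0.0)

    def test_s2_requires_missing_slot(self, make_fixes):
        # 02:00 and 08:00 fixes 300 m apart; the 05:00 slot is missing
        df = make_fixes(
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T08:00:00", 300, 0)]
        )
        (c,) = detect_clusters(df, SCHEDULE, PARAMS)
        assert c.kind == "S2"
        # with the 05:00 fix present (far away), no cluster forms at all
        df2 = make_fixes(
            [
                ("2011-01-01T02:00:00", 0, 0),
                ("2011-01-01T05:00:00", 5000, 5000),
                ("2011-01-01T08:00:00", 300, 0),
            ]
        )
        assert detect_clusters(df2, SCHEDULE, PARAMS) == []

    def test_unsorted_input_rejected(self, make_fixes):
        df = make_fixes(
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 50, 0)]
        ).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            detect_clusters(df, SCHEDULE, PARAMS)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        times, xy = _random_instance(rng)
        df = _frame(times, xy)
        got = _memberships(detect_clusters(df, SCHEDULE, PARAMS), df)
        s1, s2 = oracle_clusters(times, xy, PARAMS)
        want = sorted([("S1", m) for m in s1] + [("S2", m) for m in s2])
        assert got == want

    @pytest.mark.parametrize("seed", range(25))
    def test_invariants(self, seed):
        rng = np.random.default_rng(2000 + seed)
        times, xy = _random_instance(rng)
        df = _frame(times, xy)
        clusters = detect_clusters(df, SCHEDULE, PARAMS)
        seen = set()
        for c in clusters:
            mem = set(c.member_index)
            assert not (mem & seen), "fix assigned to more than one cluster"
            seen |= mem
            m = c.members(df)
            assert m["time"].is_monotonic_increasing
            if c.kind == "S1":
                d = np.hypot(m["x"] - c.centroid[0], m["y"] - c.centroid[1])
                assert (d <= PARAMS.radius_m + 1e-9).all()

        # translation invariance
        df_shift = df.assign(x=df["x"] + 54321.0, y=df["y"] - 9876.5)
        assert _memberships(
            detect_clusters(df_shift, SCHEDULE, PARAMS), df_shift
        ) == _memberships(clusters, df)

        # time shift by whole days (the schedule is clock-time anchored)
        df_t = df.copy()
        for col in ("time", "slot_dt"):
            df_t[col] = df_t[col] + pd.Timedelta(days=13)
        assert _memberships(
            detect_clusters(df_t, SCHEDULE, PARAMS), df_t
        ) == _memberships(clusters, df)


class TestTruncation:
    def test_no_captures_identity(self, make_fixes):
        df = make_fixes([("2011-01-01T02:00:00", 0, 0)])
        out = truncate_fixes(df, {}, PARAMS)
        pd.testing.assert_frame_equal(out, df)

    def test_seven_day_boundary(self, make_fixes):
        cap = pd.Timestamp("2011-01-01T00:00:00")
        df = make_fixes(
            [
                ("2011-01-07T21:36:00", 0, 0),   # 6.9 d post-capture: removed
                ("2011-01-08T02:24:00", 1, 0),   # 7.1 d post-capture: kept
            ]
        )
        out = truncate_fixes(df, {"A01": cap}, PARAMS)
        assert out["x"].tolist() == [1.0]

    def test_unknown_animal_ignored(self, make_fixes, caplog):
        df = make_fixes([("2011-01-01T02:00:00", 0, 0)])
        out = truncate_fixes(df, {"ZZ": pd.Timestamp("2011-01-01")}, PARAMS)
        assert len(out) == 1

    def test_matches_per_row_predicate(self, small_sim):
        fixes = small_sim.fixes
        caps = {
            "A01": pd.Timestamp("2011-08-20"),
            "A03": pd.Timestamp("2011-09-15"),
        }
        out = truncate_fixes(fixes, caps, PARAMS)

        def keep(row):
            cap = caps.get(row["animal_id"])
            if cap is None:
                return True
            d = (row["time"] - cap).total_seconds() / 86400.0
            return not (0 <= d < PARAMS.capture_truncation_days)

        expected = fixes[fixes.apply(keep, axis=1)].reset_index(drop=True)
        pd.testing.assert_frame_equal(out, expected)

    def test_exclusion_zone(self, make_fixes):
        df = make_fixes(
            [("2011-01-01T02:00:00", 0, 0), ("2011-01-01T05:00:00", 5000, 0)]
        )
        zone = {
            "t0": "2011-01-01", "t1": "2011-01-02",
            "x0": -10, "x1": 10, "y0": -10, "y1": 10,
        }
        out = truncate_fixes(df, {}, PARAMS, exclusion_zones=[zone])
        assert out["x"].tolist() == [5000.0]
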