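"""Candidate feeding-cluster detection from GPS fixes.

Two cluster kinds are formed per animal, after truncating post-capture fixes:

* **S1** — at least two fixes within ``radius_m`` (default 200 m) of the
  cluster centroid and within ``window_days`` (default 4 d) of each other.
  Formation is a chronological greedy agglomeration: the earliest unassigned
  pair satisfying the distance/time rule seeds a cluster; unassigned later
  fixes join when within ``radius_m`` of the running centroid and within
  ``window_days`` of the latest member, the centroid being recomputed after
  every addition.  Passes repeat until no fix can join.  After closing, any
  member farther than ``radius_m`` from the final centroid is pruned
  (farthest first) so the closed cluster always satisfies its own radius
  rule.
* **S2** — two consecutive acquired fixes 200–500 m apart with exactly one
  scheduled slot missing in between (the collar failed to record at a slot
  while the animal plausibly sat at a carcass between the two positions).

A fix belongs to at most one cluster; clusters are seeded earliest-first so
membership is exclusive and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schedule import FixSchedule

__all__ = ["ClusterParams", "Cluster", "truncate_fixes", "detect_clusters",
           "clusters_to_frame"]

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ClusterParams:
    """Spatial and temporal rules for cluster formation."""

    radius_m: float = 200.0
    window_days: float = 4.0
    s2_min_m: float = 200.0
    s2_max_m: float = 500.0
    capture_truncation_days: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.radius_m <= self.s2_min_m < self.s2_max_m):
            raise ValueError(
                "require 0 < radius_m <= s2_min_m < s2_max_m, got "
                f"{self.radius_m}, {self.s2_min_m}, {self.s2_max_m}"
            )
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")


@dataclass
class Cluster:
    """A detected candidate feeding cluster."""

    cluster_id: str
    animal_id: str
    kind: str  # "S1" or "S2"
    member_index: np.ndarray  # index labels into the fixes frame, time order
    centroid: tuple[float, float]
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def n_members(self) -> int:
        return len(self.member_index)

    def members(self, fixes: pd.DataFrame) -> pd.DataFrame:
        return fixes.loc[self.member_index]


# ---------------------------------------------------------------------------
# Truncation
# ---------------------------------------------------------------------------

def truncate_fixes(
    fixes: pd.DataFrame,
    capture_times: Mapping[str, object] | None,
    params: ClusterParams = ClusterParams(),
    exclusion_zones: Sequence[Mapping[str, object]] = (),
) -> pd.DataFrame:
    """Remove post-capture fixes and fixes inside user-supplied exclusion zones.

    A fix is removed when ``0 <= time - capture_time < capture_truncation_days``
    for a matching animal (collar behaviour immediately after capture is not
    representative).  ``capture_times`` maps ``animal_id`` to one or more
    capture timestamps.  Each exclusion zone is a mapping with keys
    ``t0, t1, x0, x1, y0, y1`` and optionally ``animal_id``; fixes inside the
    space-time box are removed (e.g., known natal dens).
    """
    if fixes.empty:
        return fixes.copy()
    keep = np.ones(len(fixes), dtype=bool)
    t = fixes["time"].to_numpy()
    capture_times = capture_times or {}
    known = set(fixes["animal_id"].unique())
    for animal, caps in capture_times.items():
        if animal not in known:
            log.warning("truncate_fixes: capture time for unknown animal %r", animal)
            continue
        caps_list = caps if isinstance(caps, (list, tuple, np.ndarray)) else [caps]
        mask_animal = (fixes["animal_id"] == animal).to_numpy()
        for cap in caps_list:
            cap = pd.Timestamp(cap).to_datetime64()
            delta_days = (t - cap) / np.timedelta64(1, "s") / SECONDS_PER_DAY
            keep &= ~(
                mask_animal
                & (delta_days >= 0)
                & (delta_days < params.capture_truncation_days)
            )
    for zone in exclusion_zones:
        m = np.ones(len(fixes), dtype=bool)
        if zone.get("animal_id") is not None:
            m &= (fixes["animal_id"] == zone["animal_id"]).to_numpy()
        m &= (t >= pd.Timestamp(zone["t0"]).to_datetime64()) & (
            t <= pd.Timestamp(zone["t1"]).to_datetime64()
        )
        m &= (fixes["x"].to_numpy() >= zone["x0"]) & (fixes["x"].to_numpy() <= zone["x1"])
        m &= (fixes["y"].to_numpy() >= zone["y0"]) & (fixes["y"].to_numpy() <= zone["y1"])
        keep &= ~m
    removed = int((~keep).sum())
    if removed:
        log.info("truncate_fixes: removed %d fixes", removed)
    return fixes[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _detect_s1_animal(
    t_days: np.ndarray, xy: np.ndarray, params: ClusterParams
) -> list[np.ndarray]:
    """Greedy chronological S1 agglomeration on one animal's fixes.

    Returns a list of member positional-index arrays (time order).
    ``t_days`` must be sorted ascending.
    """
    n = len(t_days)
    assigned = np.zeros(n, dtype=bool)
    forbidden: set[tuple[int, int]] = set()
    clusters: list[np.ndarray] = []
    r2 = params.radius_m**2
    w = params.window_days

    while True:
        # earliest unassigned pair (i, j) within radius and window
        seed = None
        for i in range(n):
            if assigned[i]:
                continue
            j_hi = int(np.searchsorted(t_days, t_days[i] + w, side="right"))
            for j in range(i + 1, j_hi):
                if assigned[j] or (i, j) in forbidden:
                    continue
                d2 = (xy[j, 0] - xy[i, 0]) ** 2 + (xy[j, 1] - xy[i, 1]) ** 2
                if d2 <= r2:
                    seed = (i, j)
                    break
            if seed is not None:
                break
        if seed is None:
            break

        i, j = seed
        members = [i, j]
        assigned[i] = assigned[j] = True
        cx, cy = xy[[i, j], 0].mean(), xy[[i, j], 1].mean()
        t_latest = t_days[j]

        changed = True
        while changed:
            changed = False
            for k in range(i + 1, n):
                if assigned[k]:
                    continue
                if t_days[k] - t_latest > w:
                    # later fixes only get farther in time
                    break
                d2 = (xy[k, 0] - cx) ** 2 + (xy[k, 1] - cy) ** 2
                if d2 <= r2:
                    members.append(k)
                    assigned[k] = True
                    m = len(members)
                    cx += (xy[k, 0] - cx) / m
                    cy += (xy[k, 1] - cy) / m
                    t_latest = max(t_latest, t_days[k])
                    changed = True

        # prune members that drifted outside the radius of the final centroid
        idx = np.array(sorted(members))
        while len(idx) > 2:
            d2m = (xy[idx, 0] - xy[idx, 0].mean()) ** 2 + (
                xy[idx, 1] - xy[idx, 1].mean()
            ) ** 2
            far = int(np.argmax(d2m))
            if d2m[far] <= r2:
                break
            assigned[idx[far]] = False
            idx = np.delete(idx, far)
        if len(idx) == 2:
            d2m = (xy[idx, 0] - xy[idx, 0].mean()) ** 2 + (
                xy[idx, 1] - xy[idx, 1].mean()
            ) ** 2
            if d2m.max() > r2:
                # degenerate: the surviving pair violates the radius rule;
                # dissolve and never reuse this seed
                assigned[idx] = False
                forbidden.add(seed)
                continue
        clusters.append(idx)
    return clusters


def _detect_s2_animal(
    t: pd.Series,
    xy: np.ndarray,
    assigned: np.ndarray,
    schedule: FixSchedule,
    params: ClusterParams,
) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    tv = t.to_numpy()
    for k in range(len(t) - 1):
        if assigned[k] or assigned[k + 1]:
            continue
        dx = xy[k + 1, 0] - xy[k, 0]
        dy = xy[k + 1, 1] - xy[k, 1]
        d = np.hypot(dx, dy)
        if not (params.s2_min_m < d <= params.s2_max_m):
            continue
        t1 = pd.Timestamp(tv[k]).to_pydatetime()
        t2 = pd.Timestamp(tv[k + 1]).to_pydatetime()
        if (t2 - t1).total_seconds() / SECONDS_PER_DAY > 2.0:
            continue  # more than one slot necessarily missing
        if schedule.count_between(t1, t2) == 1:
            assigned[k] = assigned[k + 1] = True
            out.append(np.array([k, k + 1]))
    return out


def detect_clusters(
    fixes: pd.DataFrame,
    schedule: FixSchedule,
    params: ClusterParams = ClusterParams(),
) -> list[Cluster]:
    """Detect S1 and S2 clusters per animal.

    ``fixes`` must be sorted by time within each animal (as produced by
    :func:`killcluster.io.read_gps_fixes`); unsorted input is an error.
    Output order and membership are deterministic for identical input.
    """
    clusters: list[Cluster] = []
    if len(fixes) < 2:
        return clusters
    for animal, grp in fixes.groupby("animal_id", sort=True):
        tv = grp["time"]
        if not tv.is_monotonic_increasing:
            raise ValueError(f"fixes for animal {animal!r} are not time-sorted")
        t_days = (
            (tv - tv.iloc[0]).dt.total_seconds().to_numpy() / SECONDS_PER_DAY
        )
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        s1 = _detect_s1_animal(t_days, xy, params)
        assigned = np.zeros(len(grp), dtype=bool)
        for idx in s1:
            assigned[idx] = True
        s2 = _detect_s2_animal(tv, xy, assigned, schedule, params)

        records = [(idx, "S1") for idx in s1] + [(idx, "S2") for idx in s2]
        records.sort(key=lambda r: (t_days[r[0][0]], r[0][0]))
        for n_c, (idx, kind) in enumerate(records, start=1):
            labels = grp.index.to_numpy()[idx]
            clusters.append(
                Cluster(
                    cluster_id=f"{animal}-{n_c:04d}",
                    animal_id=str(animal),
                    kind=kind,
                    member_index=labels,
                    centroid=(float(xy[idx, 0].mean()), float(xy[idx, 1].mean())),
                    start=tv.iloc[idx[0]],
                    end=tv.iloc[idx[-1]],
                )
            )
    clusters.sort(key=lambda c: (c.animal_id, c.start, c.cluster_id))
    return clusters


def clusters_to_frame(clusters: Iterable[Cluster]) -> pd.DataFrame:
    """Tabular summary of detected clusters (CSV-writable)."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "animal_id": c.animal_id,
            "kind": c.kind,
            "n_members": c.n_members,
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "start": c.start,
            "end": c.end,
            "member_fixes": ";".join(str(i) for i in c.member_index),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "animal_id", "kind", "n_members",
            "centroid_x", "centroid_y", "start", "end", "member_fixes",
        ],
    )
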