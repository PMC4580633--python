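"""Cluster covariates for the feeding-prediction model.

For each detected cluster the following covariates are computed:

* ``POSCOUNT`` — number of member fixes (proxy for handling time).
* ``TIMEBIN24`` — cluster persisted beyond 24 h (more than one night).
* ``NIGHTPROP`` — proportion of member fixes on night-time schedule slots.
* ``CENTER`` — mean distance (m) from the cluster centroid to its members
  (spatial dispersion).
* ``ACCX`` / ``ACCY`` — two-stage mean of activity counts: per member fix,
  the mean of all ~5-minute activity blocks starting within ±1.5 h of the
  fix; then the mean of those per-fix means over the cluster.
* ``ACCXYDIFF`` — the same two-stage mean applied to the per-block
  difference ``ax - ay`` (forward-backward minus side-to-side motion; more
  positive while feeding).
* ``FIXRATE`` — GPS acquisition success over a 96-h window centred on each
  member fix (acquired scheduled slots / scheduled slots), averaged over
  members; windows are clipped to the collar deployment interval.
* ``FIELDPROP`` — proportion of member fixes downloaded via satellite
  before ground-truthing (governs the observer's search guidance).
* ``SEARCH_LAG`` — days from cluster initiation (first fix) to the
  ground-truthing visit; missing for unvisited clusters.
* ``SEAS`` — season of the cluster start date (SUM: Jun 1–Sep 30,
  FAL: Oct 1–Jan 15, WIN: Jan 16–May 31).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .cluster import Cluster
from .schedule import FixSchedule

__all__ = [
    "CovariateParams",
    "assign_season",
    "compute_spatiotemporal",
    "compute_activity",
    "compute_groundtruth_covs",
    "build_covariate_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateParams:
    activity_halfwindow_h: float = 1.5
    fixrate_window_h: float = 96.0

    def __post_init__(self) -> None:
        if self.activity_halfwindow_h <= 0 or self.fixrate_window_h <= 0:
            raise ValueError("covariate windows must be positive")


def assign_season(d: date | datetime | pd.Timestamp) -> str:
    """Season of a calendar date, year-agnostic.

    SUM: Jun 1 – Sep 30; FAL: Oct 1 – Jan 15; WIN: Jan 16 – May 31.
    """
    d = pd.Timestamp(d)
    m, day = d.month, d.day
    if (m, day) >= (6, 1) and (m, day) <= (9, 30):
        return "SUM"
    if (m, day) >= (10, 1) or (m, day) <= (1, 15):
        return "FAL"
    return "WIN"


# ---------------------------------------------------------------------------
# Per-cluster computations
# ---------------------------------------------------------------------------

def compute_spatiotemporal(cluster: Cluster, fixes: pd.DataFrame) -> dict:
    """POSCOUNT, TIMEBIN24, NIGHTPROP, CENTER from member geometry/timing."""
    mem = cluster.members(fixes)
    xy = mem[["x", "y"]].to_numpy(dtype=float)
    cx, cy = xy[:, 0].mean(), xy[:, 1].mean()
    center = float(np.hypot(xy[:, 0] - cx, xy[:, 1] - cy).mean())
    return {
        "POSCOUNT": int(len(mem)),
        "TIMEBIN24": bool((cluster.end - cluster.start) > pd.Timedelta(hours=24)),
        "NIGHTPROP": float(mem["night"].mean()),
        "CENTER": center,
    }


def compute_activity(
    cluster: Cluster,
    fixes: pd.DataFrame,
    activity_starts: np.ndarray,
    ax: np.ndarray,
    ay: np.ndarray,
    params: CovariateParams = CovariateParams(),
) -> dict:
    """Two-stage activity means for one cluster.

    ``activity_starts`` must be the sorted block-start times (datetime64) of
    the cluster's animal, with ``ax``/``ay`` aligned.  Member fixes with no
    activity block in their window are excluded from the cluster-level mean;
    if no member has any block all three covariates are missing (NaN).
    """
    half = np.timedelta64(int(params.activity_halfwindow_h * 3600), "s")
    per_fix_x, per_fix_y, per_fix_d = [], [], []
    times = cluster.members(fixes)["time"].to_numpy()
    for t in times:
        lo = np.searchsorted(activity_starts, t - half, side="left")
        hi = np.searchsorted(activity_starts, t + half, side="right")
        if hi > lo:
            per_fix_x.append(ax[lo:hi].mean())
            per_fix_y.append(ay[lo:hi].mean())
            per_fix_d.append((ax[lo:hi] - ay[lo:hi]).mean())
    if not per_fix_x:
        return {"ACCX": np.nan, "ACCY": np.nan, "ACCXYDIFF": np.nan}
    return {
        "ACCX": float(np.mean(per_fix_x)),
        "ACCY": float(np.mean(per_fix_y)),
        "ACCXYDIFF": float(np.mean(per_fix_d)),
    }


def compute_groundtruth_covs(
    cluster: Cluster,
    fixes: pd.DataFrame,
    animal_slot_dts: np.ndarray,
    schedule: FixSchedule,
    deployment: tuple[pd.Timestamp, pd.Timestamp],
    visit_time: pd.Timestamp | None = None,
    params: CovariateParams = CovariateParams(),
) -> dict:
    """FIXRATE, FIELDPROP, SEARCH_LAG for one cluster.

    ``animal_slot_dts`` are the sorted slot-occurrence datetimes (datetime64)
    of the animal's *acquired* on-schedule fixes; FIXRATE compares them with
    the scheduled occurrences inside each member's clipped 96-h window.
    """
    mem = cluster.members(fixes)
    half = timedelta(hours=params.fixrate_window_h / 2.0)
    d0, d1 = pd.Timestamp(deployment[0]), pd.Timestamp(deployment[1])
    rates = []
    for t in mem["time"]:
        lo = max(pd.Timestamp(t) - half, d0)
        hi = min(pd.Timestamp(t) + half, d1)
        expected = schedule.occurrences(lo.to_pydatetime(), hi.to_pydatetime())
        if not expected:
            continue
        lo64 = np.datetime64(lo.to_datetime64())
        hi64 = np.datetime64(hi.to_datetime64())
        a = np.searchsorted(animal_slot_dts, lo64, side="left")
        b = np.searchsorted(animal_slot_dts, hi64, side="right")
        rates.append((b - a) / len(expected))
    fixrate = float(np.mean(rates)) if rates else np.nan
    fieldprop = float(mem["downloaded"].mean())
    if visit_time is None:
        lag = np.nan
    else:
        lag = (pd.Timestamp(visit_time) - cluster.start).total_seconds() / 86400.0
        if lag < 0:
            raise ValueError(
                f"cluster {cluster.cluster_id}: visit precedes cluster start "
                f"(negative search lag {lag:.2f} d)"
            )
    return {"FIXRATE": fixrate, "FIELDPROP": fieldprop, "SEARCH_LAG": lag}


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def build_covariate_table(
    clusters: list[Cluster],
    fixes: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    visits: pd.DataFrame | None = None,
    schedule: FixSchedule | None = None,
    deployments: dict[str, tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    params: CovariateParams = CovariateParams(),
) -> pd.DataFrame:
    """Full covariate vector for every cluster.

    Deployment intervals default to each animal's first/last fix.  ``visits``
    (columns ``cluster_id, visit_time[, feeding, ...]``) attaches SEARCH_LAG
    and, when present, the FEEDING response.
    """
    schedule = schedule or FixSchedule()

    act_by_animal: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if activity is not None and len(activity):
        for animal, grp in activity.groupby("animal_id", sort=False):
            act_by_animal[str(animal)] = (
                grp["start"].to_numpy(),
                grp["ax"].to_numpy(dtype=float),
                grp["ay"].to_numpy(dtype=float),
            )

    slots_by_animal: dict[str, np.ndarray] = {}
    deploy_by_animal: dict[str, tuple[pd.Timestamp, pd.Timestamp]] = {}
    for animal, grp in fixes.groupby("animal_id", sort=False):
        on = grp[grp["slot"] != ""]
        slots_by_animal[str(animal)] = np.sort(on["slot_dt"].to_numpy())
        deploy_by_animal[str(animal)] = (grp["time"].iloc[0], grp["time"].iloc[-1])
    if deployments:
        deploy_by_animal.update(deployments)

    visit_map: dict[str, pd.Series] = {}
    if visits is not None and len(visits):
        visit_map = {
            str(r["cluster_id"]): r for _, r in visits.iterrows()
        }

    rows = []
    n_no_activity = 0
    for c in clusters:
        row: dict = {"cluster_id": c.cluster_id, "animal_id": c.animal_id,
                     "kind": c.kind}
        row.update(compute_spatiotemporal(c, fixes))
        if c.animal_id in act_by_animal:
            starts, ax, ay = act_by_animal[c.animal_id]
            row.update(compute_activity(c, fixes, starts, ax, ay, params))
        else:
            row.update({"ACCX": np.nan, "ACCY": np.nan, "ACCXYDIFF": np.nan})
        if np.isnan(row["ACCX"]):
            n_no_activity += 1
        visit = visit_map.get(c.cluster_id)
        row.update(
            compute_groundtruth_covs(
                c,
                fixes,
                slots_by_animal[c.animal_id],
                schedule,
                deploy_by_animal[c.animal_id],
                None if visit is None else visit["visit_time"],
                params,
            )
        )
        row["SEAS"] = assign_season(c.start)
        if visit is not None and "feeding" in visit.index:
            row["FEEDING"] = bool(visit["feeding"])
        rows.append(row)
    if n_no_activity:
        log.info(
            "build_covariate_table: %d clusters with no activity records",
            n_no_activity,
        )
    cols = ["cluster_id", "animal_id", "kind", "POSCOUNT", "TIMEBIN24",
            "NIGHTPROP", "CENTER", "ACCX", "ACCY", "ACCXYDIFF", "FIXRATE",
            "FIELDPROP", "SEARCH_LAG", "SEAS"]
    if any("FEEDING" in r for r in rows):
        cols.append("FEEDING")
    return pd.DataFrame(rows, columns=cols)
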