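"""Tabular input/output for telemetry and cluster tables.

All files are plain CSV (RFC 4180, UTF-8, ``.`` decimal separator).  Four
dialects are understood:

``gps_fixes``
    ``animal_id, timestamp, x, y[, downloaded]`` — projected coordinates in
    meters; ``downloaded`` flags fixes retrieved via satellite uplink before
    ground-truthing.
``activity``
    ``animal_id, start, ax, ay`` — dual-axis activity counts (0–255)
    accumulated over fixed 288-second blocks.
``standard_visits`` / ``all_clusters``
    Cluster covariate tables; ``standard_visits`` additionally carries the
    binary ground-truthing response ``FEEDING``.
``double_observer``
    Paired-visit experiment table with columns ``LargeSizedPrey,
    WildUngulate, Visit1FEEDING, Visit1SEARCH_LAG, Visit2FEEDING,
    Visit2SEARCH_LAG``.

Column names in the cluster dialects are matched case-insensitively and can
be remapped with an explicit ``column_map`` for files whose headers deviate
from the canonical covariate symbols.
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .schedule import DEFAULT_SCHEDULE, FixSchedule

__all__ = [
    "TableError",
    "read_gps_fixes",
    "read_activity_log",
    "read_cluster_tables",
    "read_visits",
    "write_table",
    "FIX_COLUMNS",
    "COVARIATE_COLUMNS",
    "SIZE_CLASS_THRESHOLD_KG",
]

log = logging.getLogger(__name__)

ACTIVITY_BLOCK_S = 288
SIZE_CLASS_THRESHOLD_KG = 23.7

FIX_COLUMNS = ["animal_id", "time", "x", "y", "downloaded", "slot", "slot_dt", "night"]

COVARIATE_COLUMNS = [
    "POSCOUNT",
    "TIMEBIN24",
    "NIGHTPROP",
    "CENTER",
    "ACCX",
    "ACCY",
    "ACCXYDIFF",
    "FIXRATE",
    "FIELDPROP",
    "SEARCH_LAG",
    "SEAS",
]

_OBSERVER_COLUMNS = {
    "largesizedprey": "large_prey",
    "wildungulate": "wild_ungulate",
    "visit1feeding": "visit1_feeding",
    "visit1search_lag": "visit1_lag_days",
    "visit2feeding": "visit2_feeding",
    "visit2search_lag": "visit2_lag_days",
}

_TRUE_CODES = {"1", "true", "t", "y", "yes"}
_FALSE_CODES = {"0", "false", "f", "n", "no"}


class TableError(ValueError):
    """Raised for malformed tabular input, with row context where possible."""


def _coerce_bool(values: pd.Series, column: str) -> pd.Series:
    s = values.astype(str).str.strip().str.lower()
    out = pd.Series(index=values.index, dtype=bool)
    bad = ~(s.isin(_TRUE_CODES) | s.isin(_FALSE_CODES))
    if bad.any():
        rows = (values.index[bad] + 2).tolist()[:5]
        raise TableError(
            f"column {column!r}: unrecognized boolean codes "
            f"{sorted(s[bad].unique())[:5]} (file lines {rows}); accepted "
            "encodings are 1/0, TRUE/FALSE, Y/N"
        )
    out[:] = s.isin(_TRUE_CODES)
    return out


def _require(df: pd.DataFrame, needed: list[str], path: Path) -> dict[str, str]:
    """Case-insensitive header lookup; raises listing expected vs found."""
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in needed if c.lower() not in lower]
    if missing:
        raise TableError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"found headers {list(df.columns)}"
        )
    return {c: lower[c.lower()] for c in needed}


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

def read_gps_fixes(
    path: str | Path,
    schedule: FixSchedule = DEFAULT_SCHEDULE,
    tz: str | None = None,
) -> pd.DataFrame:
    """Read a GPS fix table and assign schedule slots.

    Timestamps are local civil time (``tz`` is recorded as metadata in
    ``df.attrs`` but no timezone arithmetic is performed).  Each fix is
    assigned the nearest schedule slot within ±30 minutes; fixes without one
    are kept but flagged off-schedule (``slot`` empty).  Duplicate
    (animal, slot occurrence) rows collapse to the first.  Coordinates must
    be projected meters; inputs that look geographic (all ``|x| ≤ 360`` and
    ``|y| ≤ 90``) are rejected.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.empty:
        df = pd.DataFrame(columns=FIX_COLUMNS)
        df.attrs["tz"] = tz
        return df
    cols = _require(raw, ["animal_id", "timestamp", "x", "y"], path)

    times = pd.to_datetime(raw[cols["timestamp"]], errors="coerce", format="ISO8601")
    bad_t = times.isna()
    if bad_t.any():
        lines = (raw.index[bad_t] + 2).tolist()[:5]
        raise TableError(f"{path}: unparseable timestamp at file line(s) {lines}")
    x = pd.to_numeric(raw[cols["x"]], errors="coerce")
    y = pd.to_numeric(raw[cols["y"]], errors="coerce")
    bad_xy = x.isna() | y.isna() | ~np.isfinite(x) | ~np.isfinite(y)
    if bad_xy.any():
        lines = (raw.index[bad_xy] + 2).tolist()[:5]
        raise TableError(f"{path}: non-numeric coordinate at file line(s) {lines}")
    if (x.abs() <= 360).all() and (y.abs() <= 90).all():
        raise TableError(
            f"{path}: coordinates look geographic (degrees); projected "
            "coordinates in meters are required because all cluster distance "
            "rules are metric"
        )

    lower = {c.lower(): c for c in raw.columns}
    if "downloaded" in lower:
        downloaded = _coerce_bool(raw[lower["downloaded"]], "downloaded")
    else:
        downloaded = pd.Series(True, index=raw.index)

    df = pd.DataFrame(
        {
            "animal_id": raw[cols["animal_id"]].astype(str),
            "time": times,
            "x": x.astype(float),
            "y": y.astype(float),
            "downloaded": downloaded,
        }
    )

    slots: list[str] = []
    slot_dt: list = []
    night: list[bool] = []
    for ts in df["time"]:
        hit = schedule.assign_slot(ts.to_pydatetime())
        if hit is None:
            slots.append("")
            slot_dt.append(pd.NaT)
            night.append(False)
        else:
            st, sd = hit
            slots.append(FixSchedule.label(st))
            slot_dt.append(pd.Timestamp(datetime.combine(sd, st)))
            night.append(schedule.is_night(st))
    df["slot"] = slots
    df["slot_dt"] = pd.to_datetime(pd.Series(slot_dt, index=df.index))
    df["night"] = night

    df = df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)

    on = df["slot"] != ""
    dup = on & df.duplicated(subset=["animal_id", "slot_dt"], keep="first")
    if dup.any():
        log.info("read_gps_fixes: dropped %d duplicate slot fixes", int(dup.sum()))
        df = df[~dup].reset_index(drop=True)
    df.attrs["tz"] = tz
    return df


# ---------------------------------------------------------------------------
# Activity log
# ---------------------------------------------------------------------------

def read_activity_log(path: str | Path) -> pd.DataFrame:
    """Read a dual-axis activity log.

    Counts outside [0, 255] are rejected (not clipped); overlapping intervals
    for one animal are an error naming both offending rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.empty:
        return pd.DataFrame(columns=["animal_id", "start", "duration_s", "ax", "ay"])
    cols = _require(raw, ["animal_id", "start", "ax", "ay"], path)
    start = pd.to_datetime(raw[cols["start"]], errors="coerce", format="ISO8601")
    if start.isna().any():
        lines = (raw.index[start.isna()] + 2).tolist()[:5]
        raise TableError(f"{path}: unparseable start timestamp at line(s) {lines}")
    ax = pd.to_numeric(raw[cols["ax"]], errors="coerce")
    ay = pd.to_numeric(raw[cols["ay"]], errors="coerce")
    bad = ax.isna() | ay.isna() | (ax < 0) | (ax > 255) | (ay < 0) | (ay > 255)
    if bad.any():
        lines = (raw.index[bad] + 2).tolist()[:5]
        raise TableError(
            f"{path}: activity count missing or outside [0, 255] at line(s) {lines}"
        )
    df = pd.DataFrame(
        {
            "animal_id": raw[cols["animal_id"]].astype(str),
            "start": start,
            "duration_s": ACTIVITY_BLOCK_S,
            "ax": ax.astype(float),
            "ay": ay.astype(float),
        }
    )
    df = df.sort_values(["animal_id", "start"], kind="stable").reset_index(drop=True)
    for _, grp in df.groupby("animal_id", sort=False):
        gaps = grp["start"].diff().dt.total_seconds().iloc[1:]
        bad_i = np.nonzero(gaps.to_numpy() < ACTIVITY_BLOCK_S)[0]
        if bad_i.size:
            i = int(bad_i[0])
            r1, r2 = grp.index[i], grp.index[i + 1]
            raise TableError(
                f"{path}: overlapping activity intervals for animal "
                f"{grp['animal_id'].iloc[0]!r} (rows {r1} and {r2})"
            )
    return df


# ---------------------------------------------------------------------------
# Cluster covariate / observer tables
# ---------------------------------------------------------------------------

def read_cluster_tables(
    path: str | Path,
    dialect: str,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cluster covariate or double-observer table.

    ``dialect`` is one of ``standard_visits``, ``all_clusters``,
    ``double_observer``.  ``column_map`` optionally maps canonical field
    names to the file's actual headers (useful when supplementary files use
    variant spellings).  Unknown extra columns are preserved untouched.
    """
    path = Path(path)
    raw = pd.read_csv(path, skipinitialspace=True)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})

    if dialect == "double_observer":
        cols = _require(raw, list(_OBSERVER_COLUMNS), path)
        df = raw.rename(columns={cols[k]: v for k, v in _OBSERVER_COLUMNS.items()})
        for c in ("large_prey", "wild_ungulate", "visit1_feeding", "visit2_feeding"):
            df[c] = _coerce_bool(df[c], c)
        for c in ("visit1_lag_days", "visit2_lag_days"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
            if (df[c] < 0).any():
                raise TableError(f"{path}: negative search lag in column {c}")
        return df.reset_index(drop=True)

    if dialect not in ("standard_visits", "all_clusters"):
        raise ValueError(f"unknown dialect {dialect!r}")

    lower = {c.lower(): c for c in raw.columns}
    rename = {}
    for canon in COVARIATE_COLUMNS + ["CLUSTER_ID", "ANIMAL_ID", "FEEDING"]:
        if canon.lower() in lower:
            rename[lower[canon.lower()]] = (
                canon.lower() if canon in ("CLUSTER_ID", "ANIMAL_ID") else canon
            )
    df = raw.rename(columns=rename)
    if dialect == "standard_visits":
        if "FEEDING" not in df.columns:
            raise TableError(
                f"{path}: standard_visits dialect requires a FEEDING column; "
                f"found headers {list(raw.columns)}"
            )
        if len(df):
            df["FEEDING"] = _coerce_bool(df["FEEDING"], "FEEDING")
        else:
            df["FEEDING"] = df["FEEDING"].astype(bool)
    return df.reset_index(drop=True)


def read_visits(path: str | Path) -> pd.DataFrame:
    """Read a ground-truthing visit table.

    Columns: ``cluster_id, visit_time, feeding[, prey_mass_kg]``.  The
    small/large prey size class is derived from mass with the 23.7 kg
    threshold (mule deer fawn size at the summer–fall transition).
    """
    path = Path(path)
    raw = pd.read_csv(path, skipinitialspace=True)
    if raw.empty:
        return pd.DataFrame(
            columns=["cluster_id", "visit_time", "feeding", "prey_mass_kg", "size_class"]
        )
    cols = _require(raw, ["cluster_id", "visit_time", "feeding"], path)
    df = pd.DataFrame(
        {
            "cluster_id": raw[cols["cluster_id"]].astype(str),
            "visit_time": pd.to_datetime(raw[cols["visit_time"]], format="ISO8601"),
            "feeding": _coerce_bool(raw[cols["feeding"]], "feeding"),
        }
    )
    lower = {c.lower(): c for c in raw.columns}
    if "prey_mass_kg" in lower:
        mass = pd.to_numeric(raw[lower["prey_mass_kg"]], errors="coerce")
    else:
        mass = pd.Series(np.nan, index=raw.index)
    mass = mass.where(df["feeding"])
    df["prey_mass_kg"] = mass
    df["size_class"] = np.where(
        mass.notna(), np.where(mass > SIZE_CLASS_THRESHOLD_KG, "large", "small"), ""
    )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any of the package's tables back to CSV (round-trip stable)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
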