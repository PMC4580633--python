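"""Synthetic biologging data with known ground truth.

The generator emulates the data-collection design the analysis assumes: a
store-on-board GPS collar attempting 7 fixes per day on a fixed clock
schedule with stochastic acquisition failure and stochastic satellite
download, a dual-axis activity sensor accumulating counts per 288-s block,
and a ground-truthing observation process whose success declines with
search lag, improves with the fraction of fixes in hand, and is worse for
small prey.

Movement follows three behavioural states:

* **kill handling** — kills arrive as a Poisson process (arrivals during an
  active handling interval are discarded); handling lasts
  ``min(1 + mass/30, 8)`` days; night positions scatter tightly around the
  kill site, day positions sit at a fixed day-bed offset 220–400 m away
  (outside the 200-m cluster extent, as day-time resting typically is).
* **day-bed** — outside handling, some days are spent at one tight day-bed
  (re-used across nearby days with a configurable probability), producing
  non-feeding clusters — the confusable class the model must reject; on
  other days the animal rests at dispersed spots a few hundred meters
  apart.
* **travel** — night-time steps of 500–2000 m per slot gap along a
  persistent heading (quasi-ballistic, so the track rarely recrosses
  itself by chance).

Activity emissions are state-dependent with the feeding state producing
more forward-backward (x) than side-to-side (y) motion and travel the
reverse; resting is low on both axes.

Everything is reproducible from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cluster import Cluster, ClusterParams, detect_clusters
from .io import ACTIVITY_BLOCK_S
from .schedule import DEFAULT_SCHEDULE, FixSchedule

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "RECOVERY_SPEC",
    "simulate_dataset",
    "truth_join",
    "simulate_observer_pairs",
    "simulate_covariates",
]

SECONDS_PER_DAY = 86400.0

# Model used in simulation studies: the full feeding-model structure minus
# the season dummy, the FIELDPROP quadratic and the cross-group interactions
# (terms the simulated data cannot identify at moderate sample sizes).
from .model import ModelSpec  # noqa: E402  (cycle-free: model has no sim import)

RECOVERY_SPEC = ModelSpec(
    "sim-recovery",
    ("log(POSCOUNT)", "NIGHTPROP", "log(POSCOUNT):NIGHTPROP",
     "CENTER", "CENTER^2", "ACCX", "ACCX^2", "ACCXYDIFF",
     "SEARCH_LAG", "FIELDPROP"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cougar telemetry generator."""

    n_animals: int = 30
    duration_days: float = 120.0
    start: str = "2011-08-15"  # spans the summer and fall seasons
    schedule: FixSchedule = field(default_factory=FixSchedule)
    fix_success_p: float = 0.81
    download_success_p: float = 0.92
    kill_rate_per_week: float = 0.4
    # prey body-mass mixture (kg): small mode ~5-20, large mode ~40-80
    prey_small_frac: float = 0.38
    prey_small_logmean: float = math.log(10.0)
    prey_small_logsd: float = 0.45
    prey_large_logmean: float = math.log(60.0)
    prey_large_logsd: float = 0.30
    # handling time as a function of mass
    handling_base_days: float = 1.0
    handling_days_per_kg: float = 1.0 / 30.0
    handling_cap_days: float = 8.0
    # movement
    daybed_offset_m: tuple[float, float] = (220.0, 400.0)
    kill_site_sd_m: float = 30.0
    travel_step_m: tuple[float, float] = (500.0, 2000.0)
    p_bed_day: float = 0.08          # day spent at one tight day-bed
    p_daybed_reuse: float = 0.3      # re-use the previous bed on a bed day
    daybed_move_m: tuple[float, float] = (300.0, 800.0)  # dispersed resting
    # activity emissions: state -> ((mean_ax, sd_ax), (mean_ay, sd_ay))
    emissions: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: {
            "feeding": ((140.0, 25.0), (60.0, 25.0)),
            "resting": ((15.0, 10.0), (12.0, 10.0)),
            "travel": ((80.0, 25.0), (140.0, 25.0)),
        }
    )
    # fraction of handling-night activity blocks spent actually feeding
    # (short, low-intensity bouts on small prey; near-continuous on large)
    feed_intensity_base: float = 0.4
    feed_intensity_per_kg: float = 0.01
    feed_intensity_max: float = 0.95
    # observer detection model (logit scale)
    d0: float = 0.3
    d_lag: float = -0.07
    d_fieldprop: float = 2.0
    d_logmass: float = 0.6
    # ground-truthing design
    visit_p: float = 0.6
    visit_lag_days: tuple[float, float] = (2.0, 60.0)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.fix_success_p, self.download_success_p, self.visit_p,
                  self.prey_small_frac, self.p_bed_day, self.p_daybed_reuse):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.handling_cap_days >= self.duration_days:
            raise ValueError("handling cap must be shorter than the simulation")
        fx, fy = self.emissions["feeding"]
        tx, ty = self.emissions["travel"]
        if not fx[0] > fy[0]:
            raise ValueError("feeding must emit more x- than y-axis activity")
        if not ty[0] >= tx[0]:
            raise ValueError("travel must emit at least as much y- as x-axis")

    def handling_days(self, mass_kg: float) -> float:
        return min(
            self.handling_base_days + self.handling_days_per_kg * mass_kg,
            self.handling_cap_days,
        )

    def feed_intensity(self, mass_kg: float) -> float:
        return min(
            self.feed_intensity_base + self.feed_intensity_per_kg * mass_kg,
            self.feed_intensity_max,
        )


@dataclass
class SimTruth:
    """Ground-truth kill ledger and per-fix behavioural states."""

    kills: pd.DataFrame       # animal_id, kill_id, time, x, y, mass_kg, handling_end
    fix_states: pd.Series     # aligned with the fixes frame index
    config: SimConfig


@dataclass
class SimData:
    fixes: pd.DataFrame
    activity: pd.DataFrame
    visits: pd.DataFrame
    truth: SimTruth
    clusters: list[Cluster]


def _is_night_hour(hour: int) -> bool:
    return hour >= 20 or hour < 6


def _simulate_animal(
    animal: str,
    origin: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    start_dt: datetime,
):
    """Slot-level positions/states and the kill ledger for one animal."""
    # --- kill arrivals (Poisson; arrivals during handling discarded) -------
    rate_per_day = cfg.kill_rate_per_week / 7.0
    kills = []
    t = 0.0
    while True:
        if rate_per_day <= 0:
            break
        t += rng.exponential(1.0 / rate_per_day)
        if t >= cfg.duration_days:
            break
        if kills and t < kills[-1]["end"]:
            continue
        if rng.random() < cfg.prey_small_frac:
            mass = float(rng.lognormal(cfg.prey_small_logmean, cfg.prey_small_logsd))
        else:
            mass = float(rng.lognormal(cfg.prey_large_logmean, cfg.prey_large_logsd))
        theta = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(*cfg.daybed_offset_m)
        kills.append(
            {
                "t": t,
                "end": t + cfg.handling_days(mass),
                "mass": mass,
                "xy": None,
                "daybed": np.array([dist * np.cos(theta), dist * np.sin(theta)]),
            }
        )

    # --- slot positions ----------------------------------------------------
    slot_times = cfg.schedule.occurrences(
        start_dt, start_dt + timedelta(days=cfg.duration_days)
    )
    pos = origin.astype(float).copy()
    heading = rng.uniform(0, 2 * np.pi)  # persistent travel direction
    daybed: np.ndarray | None = None   # last tight day-bed used
    last_bed_day = None                # date of that bed day
    cur_date = None
    bedded_today = False
    rows = []
    ki = 0
    for ts in slot_times:
        td = (ts - start_dt).total_seconds() / SECONDS_PER_DAY
        while ki < len(kills) and kills[ki]["end"] <= td:
            ki += 1
        kill = kills[ki] if ki < len(kills) and kills[ki]["t"] <= td else None
        is_night_slot = ts.time() in cfg.schedule.night_slots
        if kill is not None:
            if kill["xy"] is None:
                kill["xy"] = pos + rng.normal(0.0, 200.0, size=2)
            if is_night_slot:
                p = kill["xy"] + rng.normal(0.0, cfg.kill_site_sd_m, size=2)
            else:
                p = (
                    kill["xy"]
                    + kill["daybed"]
                    + rng.normal(0.0, cfg.kill_site_sd_m, size=2)
                )
            state = "handling"
        elif not is_night_slot:
            if cur_date != ts.date():
                cur_date = ts.date()
                bedded_today = rng.random() < cfg.p_bed_day
                if bedded_today:
                    recent = (
                        daybed is not None
                        and last_bed_day is not None
                        and (ts.date() - last_bed_day).days <= 4
                    )
                    if not (recent and rng.random() < cfg.p_daybed_reuse):
                        daybed = pos.copy()
                    last_bed_day = ts.date()
            if bedded_today:
                p = daybed + rng.normal(0.0, cfg.kill_site_sd_m, size=2)
            else:
                # dispersed resting: a short relocation before each day slot,
                # drifting along the persistent heading
                step = rng.uniform(*cfg.daybed_move_m)
                heading += rng.normal(0.0, 0.9)
                p = pos + np.array([step * np.cos(heading), step * np.sin(heading)])
            state = "daybed"
        else:
            step = rng.uniform(*cfg.travel_step_m)
            heading += rng.normal(0.0, 0.7)
            p = pos + np.array([step * np.cos(heading), step * np.sin(heading)])
            state = "travel"
        pos = np.asarray(p, dtype=float)
        rows.append((ts, pos[0], pos[1], state))

    # fixes that survive acquisition failure
    acquired = rng.random(len(rows)) < cfg.fix_success_p
    downloaded = rng.random(len(rows)) < cfg.download_success_p

    kill_rows = [
        {
            "animal_id": animal,
            "kill_id": f"{animal}-K{j:03d}",
            "time": start_dt + timedelta(days=k["t"]),
            "x": float(k["xy"][0]) if k["xy"] is not None else np.nan,
            "y": float(k["xy"][1]) if k["xy"] is not None else np.nan,
            "mass_kg": k["mass"],
            "handling_end": start_dt + timedelta(days=k["end"]),
        }
        for j, k in enumerate(kills, start=1)
    ]
    return rows, acquired, downloaded, kill_rows


def _simulate_activity(
    animal: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    start_dt: datetime,
    kills: list[dict],
) -> pd.DataFrame:
    n_blocks = int(cfg.duration_days * SECONDS_PER_DAY // ACTIVITY_BLOCK_S)
    t0 = np.datetime64(start_dt)
    starts = t0 + (np.arange(n_blocks) * ACTIVITY_BLOCK_S).astype("timedelta64[s]")
    t_days = np.arange(n_blocks) * (ACTIVITY_BLOCK_S / SECONDS_PER_DAY)
    hours = ((t_days % 1.0) * 24 + start_dt.hour) % 24
    night = (hours >= 20) | (hours < 6)
    handling = np.zeros(n_blocks, dtype=bool)
    feeding = np.zeros(n_blocks, dtype=bool)
    for k in kills:
        span = (t_days >= k["t"]) & (t_days < k["end"])
        handling |= span
        # short feeding bouts interleave with resting, more of the night on
        # larger prey
        bout = rng.random(n_blocks) < cfg.feed_intensity(k["mass"])
        feeding |= span & night & bout
    state = np.where(feeding, "feeding",
                     np.where(~handling & night, "travel", "resting"))
    ax = np.empty(n_blocks)
    ay = np.empty(n_blocks)
    for s, ((mx, sx), (my, sy)) in cfg.emissions.items():
        m = state == s
        ax[m] = rng.normal(mx, sx, size=int(m.sum()))
        ay[m] = rng.normal(my, sy, size=int(m.sum()))
    ax = np.clip(np.rint(ax), 0, 255)
    ay = np.clip(np.rint(ay), 0, 255)
    return pd.DataFrame(
        {
            "animal_id": animal,
            "start": pd.to_datetime(starts),
            "duration_s": ACTIVITY_BLOCK_S,
            "ax": ax,
            "ay": ay,
        }
    )


def simulate_dataset(config: SimConfig = SimConfig()) -> SimData:
    """Generate fixes, activity, ground-truthing visits and the kill ledger.

    Clusters are detected with the analysis detector so the visit table's
    cluster ids coincide with what a downstream pipeline re-detects from the
    same fixes.
    """
    rng = np.random.default_rng(config.seed)
    start_dt = datetime.fromisoformat(config.start)

    fix_frames = []
    act_frames = []
    kill_rows_all: list[dict] = []
    state_all: list[str] = []
    for a in range(config.n_animals):
        animal = f"A{a + 1:02d}"
        origin = np.array([a * 100000.0, 0.0])
        rows, acquired, downloaded, kill_rows = _simulate_animal(
            animal, origin, config, rng, start_dt
        )
        kills = [
            {
                "t": (k["time"] - start_dt).total_seconds() / SECONDS_PER_DAY,
                "end": (k["handling_end"] - start_dt).total_seconds() / SECONDS_PER_DAY,
                "mass": k["mass_kg"],
            }
            for k in kill_rows
        ]
        act_frames.append(_simulate_activity(animal, config, rng, start_dt, kills))
        kill_rows_all.extend(kill_rows)
        kept = [(r, d) for r, keep, d in zip(rows, acquired, downloaded) if keep]
        if not kept:
            continue
        frame = pd.DataFrame(
            {
                "animal_id": animal,
                "time": pd.to_datetime([r[0] for r, _ in kept]),
                "x": [r[1] for r, _ in kept],
                "y": [r[2] for r, _ in kept],
                "downloaded": [bool(d) for _, d in kept],
            }
        )
        frame["slot"] = [
            FixSchedule.label(ts.time()) for ts in frame["time"]
        ]
        frame["slot_dt"] = frame["time"]
        frame["night"] = [
            ts.time() in config.schedule.night_slots for ts in frame["time"]
        ]
        fix_frames.append(frame)
        state_all.extend(r[3] for r, _ in kept)

    fixes = pd.concat(fix_frames, ignore_index=True) if fix_frames else pd.DataFrame()
    activity = pd.concat(act_frames, ignore_index=True)
    kills = pd.DataFrame(
        kill_rows_all,
        columns=["animal_id", "kill_id", "time", "x", "y", "mass_kg", "handling_end"],
    )
    truth = SimTruth(
        kills=kills,
        fix_states=pd.Series(state_all, index=fixes.index, name="state"),
        config=config,
    )

    clusters = detect_clusters(fixes, config.schedule, config.cluster_params) if len(
        fixes
    ) else []
    labels = truth_join(clusters, truth, config.cluster_params.radius_m)

    visit_rows = []
    for c in clusters:
        if rng.random() >= config.visit_p:
            continue
        lag = rng.uniform(*config.visit_lag_days)
        fieldprop = float(c.members(fixes)["downloaded"].mean())
        row = labels.loc[c.cluster_id]
        found = False
        mass = np.nan
        if bool(row["true_feeding"]):
            mass = float(row["kill_mass_kg"])
            p_det = expit(
                config.d0
                + config.d_lag * lag
                + config.d_fieldprop * fieldprop
                + config.d_logmass * math.log(mass)
            )
            found = bool(rng.random() < p_det)
        visit_rows.append(
            {
                "cluster_id": c.cluster_id,
                "visit_time": c.start + pd.Timedelta(days=lag),
                "feeding": found,
                "prey_mass_kg": mass if found else np.nan,
            }
        )
    visits = pd.DataFrame(
        visit_rows, columns=["cluster_id", "visit_time", "feeding", "prey_mass_kg"]
    )
    return SimData(fixes=fixes, activity=activity, visits=visits, truth=truth,
                   clusters=clusters)


def truth_join(
    clusters: list[Cluster], truth: SimTruth, radius_m: float = 200.0
) -> pd.DataFrame:
    """True feeding labels: a cluster is truly feeding iff its time span
    overlaps a kill's handling interval and its centroid lies within
    ``radius_m`` of the kill site.  Indexed by ``cluster_id``."""
    kills_by_animal = dict(tuple(truth.kills.groupby("animal_id", sort=False)))
    rows = []
    for c in clusters:
        label = False
        mass = np.nan
        kill_id = ""
        kk = kills_by_animal.get(c.animal_id)
        if kk is not None:
            for _, k in kk.iterrows():
                if pd.isna(k["x"]):
                    continue
                if c.start <= k["handling_end"] and k["time"] <= c.end:
                    d = math.hypot(c.centroid[0] - k["x"], c.centroid[1] - k["y"])
                    if d <= radius_m:
                        label = True
                        mass = float(k["mass_kg"])
                        kill_id = str(k["kill_id"])
                        break
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "true_feeding": label,
                "kill_mass_kg": mass,
                "kill_id": kill_id,
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "true_feeding", "kill_mass_kg", "kill_id"]
    ).set_index("cluster_id")


def simulate_observer_pairs(
    sim: SimData,
    n_pairs: int = 174,
    nonfeeding_frac: float = 0.07,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic double-observer experiment over the simulated clusters.

    Samples mostly truly-feeding clusters (the initial investigator targeted
    apparent kills in near-real time), sends an early initial visit with a
    reduced fix complement in hand and an independent standard visit 2–60
    days later, and draws both classifications from the detection model.
    Returns a table in the ``double_observer`` layout.
    """
    rng = np.random.default_rng(seed)
    cfg = sim.truth.config
    labels = truth_join(sim.clusters, sim.truth, cfg.cluster_params.radius_m)
    feeding_ids = labels.index[labels["true_feeding"]].to_numpy()
    other_ids = labels.index[~labels["true_feeding"]].to_numpy()
    n_non = min(int(round(n_pairs * nonfeeding_frac)), len(other_ids))
    n_feed = min(n_pairs - n_non, len(feeding_ids))
    chosen = np.concatenate(
        [
            rng.choice(feeding_ids, size=n_feed, replace=False),
            rng.choice(other_ids, size=n_non, replace=False),
        ]
    )
    by_id = {c.cluster_id: c for c in sim.clusters}
    rows = []
    for cid in chosen:
        c = by_id[cid]
        info = labels.loc[cid]
        fieldprop = float(c.members(sim.fixes)["downloaded"].mean())
        lag1 = rng.uniform(0.25, 3.0)
        lag2 = rng.uniform(*cfg.visit_lag_days)
        found1 = found2 = False
        large = False
        ungulate = False
        if bool(info["true_feeding"]):
            mass = float(info["kill_mass_kg"])
            large = mass > 23.7
            ungulate = large or bool(rng.random() < 0.55)
            # the initial observer works from a partial, real-time download
            p1 = expit(cfg.d0 + cfg.d_lag * lag1
                       + cfg.d_fieldprop * fieldprop * 0.7
                       + cfg.d_logmass * math.log(mass))
            p2 = expit(cfg.d0 + cfg.d_lag * lag2
                       + cfg.d_fieldprop * fieldprop
                       + cfg.d_logmass * math.log(mass))
            found1 = bool(rng.random() < p1)
            found2 = bool(rng.random() < p2)
        rows.append(
            {
                "cluster_id": cid,
                "large_prey": large and (found1 or found2),
                "wild_ungulate": ungulate and (found1 or found2),
                "visit1_feeding": found1,
                "visit1_lag_days": lag1,
                "visit2_feeding": found2,
                "visit2_lag_days": lag2,
            }
        )
    return pd.DataFrame(rows)


def simulate_covariates(
    n: int, beta: Mapping[str, float], seed: int = 0
) -> tuple[pd.DataFrame, "ModelSpec"]:
    """Draw covariate rows and Bernoulli responses from a known logit model.

    ``beta`` maps term expressions (plus ``"(Intercept)"``) to coefficients;
    the returned spec contains the non-intercept terms in order.  Intended
    for coefficient-recovery tests where the full movement simulation is
    unnecessary.
    """
    from .model import ModelSpec, build_design_matrix

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "POSCOUNT": 2 + rng.poisson(4.0, n),
            "NIGHTPROP": rng.beta(1.5, 1.5, n),
            "CENTER": rng.gamma(2.0, 30.0, n),
            "ACCX": np.clip(rng.normal(90.0, 35.0, n), 0, 255),
            "ACCXYDIFF": rng.normal(10.0, 25.0, n),
            "SEARCH_LAG": rng.uniform(0.0, 60.0, n),
            "FIELDPROP": rng.beta(9.0, 1.0, n),
            "SEAS": rng.choice(["SUM", "FAL", "WIN"], n),
        }
    )
    terms = tuple(k for k in beta if k != "(Intercept)")
    spec = ModelSpec("synthetic", terms)
    X, names, _ = build_design_matrix(df, spec, response=None)
    b = np.array([beta.get("(Intercept)", 0.0)] + [beta[t] for t in terms])
    p = expit(X @ b)
    df["FEEDING"] = rng.random(n) < p
    return df, spec
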