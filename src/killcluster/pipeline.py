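"""End-to-end orchestration: cluster → covariates → select → evaluate → predict.

A run is driven by a single :class:`RunConfig` (typically loaded from YAML)
that either points at input CSVs or embeds a simulation block.  Every
artifact is written under the output directory together with a ``run.json``
carrying the config hash and seeds, so a rerun with an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .cluster import Cluster, ClusterParams, clusters_to_frame, detect_clusters, truncate_fixes
from .covariates import CovariateParams, build_covariate_table
from .evaluation import EvalResult, evaluate_model
from .model import (
    FeedingResults,
    component_candidate_set,
    named_spec,
    select_models,
)
from .prediction import count_events
from .schedule import DEFAULT_SCHEDULE, FixSchedule, parse_slot_times
from .simulate import SimConfig, SimData, simulate_dataset, truth_join

__all__ = ["RunConfig", "run_pipeline", "frame_to_clusters"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``fixes_path`` (with optional activity/visits paths) or
    ``simulate`` must be set.
    """

    outdir: str = "killcluster_run"
    fixes_path: str | None = None
    activity_path: str | None = None
    visits_path: str | None = None
    captures_path: str | None = None
    simulate: SimConfig | None = None
    schedule: FixSchedule = field(default_factory=FixSchedule)
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    spec_name: str = "components"  # "components" = AICc-select over the 16-model set
    cv_folds: int = 20
    eval_seed: int = 0
    predict_draws: int = 1000
    predict_seed: int = 0
    nuisance_means: tuple[float, float] | None = None  # None = recompute from visits

    def __post_init__(self) -> None:
        has_inputs = self.fixes_path is not None
        has_sim = self.simulate is not None
        if has_inputs == has_sim:
            raise ValueError("exactly one of fixes_path or simulate must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict[str, Any] = {}
        for key in ("outdir", "fixes_path", "activity_path", "visits_path",
                    "captures_path", "spec_name", "cv_folds", "eval_seed",
                    "predict_draws", "predict_seed"):
            if key in raw:
                kw[key] = raw[key]
        if "nuisance_means" in raw and raw["nuisance_means"] is not None:
            kw["nuisance_means"] = tuple(raw["nuisance_means"])
        if "schedule" in raw:
            s = raw["schedule"]
            kw["schedule"] = FixSchedule(
                slot_times=parse_slot_times(s["slot_times"]),
                night_slots=frozenset(parse_slot_times(s.get("night_slots", ()))),
            )
        if "cluster" in raw:
            kw["cluster_params"] = ClusterParams(**raw["cluster"])
        if "covariates" in raw:
            kw["covariate_params"] = CovariateParams(**raw["covariates"])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "cluster" in raw:
                sim.setdefault("cluster_params", ClusterParams(**raw["cluster"]))
            kw["simulate"] = SimConfig(**sim)
        return cls(**kw)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def frame_to_clusters(frame: pd.DataFrame, fixes: pd.DataFrame) -> list[Cluster]:
    """Rebuild :class:`Cluster` objects from a ``clusters.csv`` table."""
    out = []
    for _, r in frame.iterrows():
        idx = np.array([int(i) for i in str(r["member_fixes"]).split(";")])
        out.append(
            Cluster(
                cluster_id=str(r["cluster_id"]),
                animal_id=str(r["animal_id"]),
                kind=str(r["kind"]),
                member_index=idx,
                centroid=(float(r["centroid_x"]), float(r["centroid_y"])),
                start=pd.Timestamp(r["start"]),
                end=pd.Timestamp(r["end"]),
            )
        )
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory artifacts.

    Stages: (simulate or load) → truncate → cluster → covariates →
    fit/select → evaluate → predict.  Artifacts are also written as CSV/JSON
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}

    # --- inputs ------------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim: SimData = simulate_dataset(config.simulate)
        fixes, activity, visits = sim.fixes, sim.activity, sim.visits
        schedule = config.simulate.schedule
        cluster_params = config.simulate.cluster_params
        clusters = sim.clusters
        truth = sim.truth
        kio.write_table(fixes.drop(columns=["slot", "slot_dt", "night"]),
                        outdir / "gps_fixes.csv")
        kio.write_table(activity, outdir / "activity.csv")
        kio.write_table(visits, outdir / "visits.csv")
        kio.write_table(truth.kills, outdir / "truth_kills.csv")
    else:
        schedule = config.schedule
        cluster_params = config.cluster_params
        for p in (config.fixes_path, config.activity_path, config.visits_path,
                  config.captures_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        fixes = _stage("read_fixes")(kio.read_gps_fixes)(
            config.fixes_path, schedule
        )
        activity = (
            _stage("read_activity")(kio.read_activity_log)(config.activity_path)
            if config.activity_path
            else None
        )
        visits = (
            _stage("read_visits")(kio.read_visits)(config.visits_path)
            if config.visits_path
            else None
        )
        captures = {}
        if config.captures_path:
            cap = pd.read_csv(config.captures_path)
            captures = {
                str(r["animal_id"]): pd.Timestamp(r["capture_time"])
                for _, r in cap.iterrows()
            }
        fixes = _stage("truncate")(truncate_fixes)(fixes, captures, cluster_params)
        clusters = _stage("cluster")(detect_clusters)(fixes, schedule, cluster_params)

    artifacts["fixes"] = fixes
    artifacts["clusters"] = clusters
    cl_frame = clusters_to_frame(clusters)
    kio.write_table(cl_frame, outdir / "clusters.csv")

    # --- covariates ---------------------------------------------------------
    covars = _stage("covariates")(build_covariate_table)(
        clusters, fixes, activity, visits, schedule, None, config.covariate_params
    )
    artifacts["covariates"] = covars
    kio.write_table(covars, outdir / "covariates.csv")

    # --- fit / select -------------------------------------------------------
    if "FEEDING" not in covars.columns:
        raise RuntimeError("no ground-truthing visits: cannot fit feeding models")
    visited = covars[covars["FEEDING"].notna() & covars["SEARCH_LAG"].notna()]
    if config.spec_name == "components":
        specs = component_candidate_set()
        table, results = _stage("select")(select_models)(specs, visited, on_error="drop")
        best: FeedingResults = results[table["model"].iloc[0]]
        artifacts["selection"] = table
        kio.write_table(table, outdir / "selection.csv")
    else:
        spec = named_spec(config.spec_name)
        table, results = _stage("select")(select_models)([spec], visited)
        best = results[spec.name]
        artifacts["selection"] = table
        kio.write_table(table, outdir / "selection.csv")
    artifacts["results"] = best
    best.to_json(outdir / "model.json")

    # --- evaluate -----------------------------------------------------------
    from .model import complete_cases

    fit_data = complete_cases(visited, [best.spec]).reset_index(drop=True)
    counts = np.bincount(fit_data["FEEDING"].astype(int), minlength=2)
    k = min(config.cv_folds, int(counts.min()))
    if k < config.cv_folds:
        log.warning("reducing CV folds from %d to %d (class counts %s)",
                    config.cv_folds, k, counts.tolist())
    ev: EvalResult = _stage("evaluate")(evaluate_model)(
        fit_data, best.spec, k=k, seed=config.eval_seed
    )
    artifacts["eval"] = ev
    (outdir / "eval.json").write_text(json.dumps(ev.__dict__, indent=2))

    # --- predict ------------------------------------------------------------
    nuisance = config.nuisance_means
    if nuisance is None:
        nuisance = (
            float(visited["SEARCH_LAG"].mean()),
            float(visited["FIELDPROP"].mean()),
        )
    pred_rows = complete_cases(
        covars.assign(SEARCH_LAG=0.0, FIELDPROP=1.0), [best.spec]
    ).index
    all_rows = covars.loc[pred_rows]
    predictions = {}
    for mode in ("corrected", "uncorrected"):
        predictions[mode] = _stage("predict")(count_events)(
            best,
            all_rows,
            ev.cutoff,
            mode=mode,
            n_draws=config.predict_draws,
            seed=config.predict_seed,
            nuisance_means=nuisance,
        )
    artifacts["predictions"] = predictions
    (outdir / "prediction.json").write_text(
        json.dumps({m: p.to_dict() for m, p in predictions.items()}, indent=2)
    )

    if truth is not None:
        labels = truth_join(clusters, truth, cluster_params.radius_m)
        artifacts["truth_labels"] = labels
        kio.write_table(labels.reset_index(), outdir / "truth_labels.csv")

    run_meta = {
        "config_digest": config.digest(),
        "eval_seed": config.eval_seed,
        "predict_seed": config.predict_seed,
        "n_fixes": int(len(fixes)),
        "n_clusters": int(len(clusters)),
        "n_groundtruthed": int(len(visited)),
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "run.json").write_text(json.dumps(run_meta, indent=2))
    artifacts["run_meta"] = run_meta
    return artifacts
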