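"""End-to-end walkway analysis run: simulate -> geometry -> features -> stats.

A run is driven by one :class:`RunConfig` and a single seed; each stage
derives its own child seed by stable hashing, writes its artifacts as CSV
or JSON under the output directory, and is recorded (with content hashes)
in a JSON manifest, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import phenotypes as pheno
from . import stats as st
from . import synthetic as syn
from .geometry import align_frame

log = logging.getLogger("broilerwalk")

STAGES = ["simulate", "geometry", "features", "phenotypes", "stats"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "run_out"
    seed: int = 0
    n_birds: int = 118
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    # optional pre-existing inputs; when set, the simulate stage loads them
    detections_path: str | None = None
    phenotypes_path: str | None = None
    # geometry stage: corridor-rotation self-check on a rendered frame
    corridor_rotation_deg: float = 5.0
    run_calibration: bool = False
    calibration_views: int = 12
    # feature parameters
    fps: float = 11.0
    window: int = 3
    max_gap: int = 5
    walk_direction: int = 1
    fit_against: str = "time"
    # stats parameters
    alpha: float = 0.05
    k_clusters: int = 3
    kmeans_restarts: int = 10

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_jsonable(self.__dict__), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (independent of other stages' draws)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if hasattr(obj, "__dict__") and not isinstance(obj, type):
        return _jsonable(vars(obj))
    return obj


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
        "artifacts": {},
    }

    def emit(name: str, path: str):
        artifacts[name] = path

    timings = {}

    # -- simulate ----------------------------------------------------------
    t0 = time.time()
    try:
        if config.detections_path or config.phenotypes_path:
            for label, path in (("detections", config.detections_path),
                                ("phenotypes", config.phenotypes_path)):
                if not path or not os.path.exists(path or ""):
                    raise PipelineStageError(
                        "simulate", f"missing {label} file: {path!r}")
            det = pd.read_csv(config.detections_path)
            phe = pd.read_csv(config.phenotypes_path)
            gt = None
        else:
            sim_cfg = syn.SimConfig(**{**config.sim.__dict__,
                                       "seed": child_seed(config.seed, "simulate")})
            det, phe, gt = syn.simulate_population(sim_cfg, config.n_birds)
        det_path = os.path.join(config.out_dir, "detections.csv")
        phe_path = os.path.join(config.out_dir, "phenotypes.csv")
        det.to_csv(det_path, index=False)
        phe.to_csv(phe_path, index=False)
        emit("detections", det_path)
        emit("phenotypes", phe_path)
        if gt is not None:
            gt_path = os.path.join(config.out_dir, "ground_truth.csv")
            gt.to_csv(gt_path, index=False)
            emit("ground_truth", gt_path)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("simulate", str(exc)) from exc
    timings["simulate"] = time.time() - t0

    # -- geometry ----------------------------------------------------------
    t0 = time.time()
    try:
        frame = syn.render_corridor_frame(config.corridor_rotation_deg)
        _, alpha = align_frame(frame)
        geom = {"programmed_rotation_deg": config.corridor_rotation_deg,
                "recovered_rotation_deg": alpha}
        if config.run_calibration:
            from .geometry import CameraModel, calibrate_camera

            cam_true = CameraModel(fx=600.0, fy=600.0, cx=320.0, cy=240.0,
                                   k1=-0.1, width=640, height=480)
            views = syn.render_checkerboard_views(
                cam_true, n_views=config.calibration_views,
                seed=child_seed(config.seed, "geometry"))
            cam_est = calibrate_camera(views, min_frames=min(10, config.calibration_views))
            geom["calibration"] = {
                "true_k1": cam_true.k1, "estimated_k1": cam_est.k1,
                "reprojection_error_px": cam_est.reprojection_error,
            }
        geom_path = os.path.join(config.out_dir, "geometry.json")
        with open(geom_path, "w") as fh:
            json.dump(_jsonable(geom), fh, indent=2)
        emit("geometry", geom_path)
    except Exception as exc:
        raise PipelineStageError("geometry", str(exc)) from exc
    timings["geometry"] = time.time() - t0

    # -- features ----------------------------------------------------------
    t0 = time.time()
    try:
        feats, lw = feat.extract_features_table(
            det, fps=config.fps, walk_direction=config.walk_direction,
            max_gap=config.max_gap, window=config.window,
            fit_against=config.fit_against)
        f_path = os.path.join(config.out_dir, "features.csv")
        lw_path = os.path.join(config.out_dir, "lw_ratios.csv")
        feats.to_csv(f_path, index=False)
        lw.to_csv(lw_path, index=False, float_format="%.5f")
        emit("features", f_path)
        emit("lw_ratios", lw_path)
    except Exception as exc:
        raise PipelineStageError("features", str(exc)) from exc
    timings["features"] = time.time() - t0

    # -- phenotypes --------------------------------------------------------
    t0 = time.time()
    try:
        classified = pheno.classify_population(phe)
        c_path = os.path.join(config.out_dir, "classified.csv")
        classified.to_csv(c_path, index=False)
        emit("classified", c_path)
        summary = pheno.summarize_population(classified)
        s_path = os.path.join(config.out_dir, "population_summary.csv")
        summary.to_csv(s_path, index=False, float_format="%.4f")
        emit("population_summary", s_path)
    except Exception as exc:
        raise PipelineStageError("phenotypes", str(exc)) from exc
    timings["phenotypes"] = time.time() - t0

    # -- stats -------------------------------------------------------------
    t0 = time.time()
    try:
        res = st.analyze(feats, classified, seed=child_seed(config.seed, "stats"),
                         k=config.k_clusters)
        res["correlations"].to_csv(
            os.path.join(config.out_dir, "correlations.csv"), index=False,
            float_format="%.6f")
        emit("correlations", os.path.join(config.out_dir, "correlations.csv"))
        fisher = {k: {"p": v["p"], "table": v["table"].to_dict()}
                  for k, v in res["fisher"].items()}
        stats_json = {
            "n_birds": res["n_birds"],
            "fisher": fisher,
            "weight_by_gs_anova": res["weight_by_gs_anova"],
            "weight_by_fpd_anova": res["weight_by_fpd_anova"],
            "weight_by_hb_welch": res["weight_by_hb_welch"],
            "models": {
                col: {cls: {
                    "ls_means": m.ls_means.to_dict(),
                    "ls_se": m.ls_se.to_dict(),
                    "interaction_included": m.interaction_included,
                    "interaction_p": m.interaction_p,
                    "covariate_p": m.covariate_p,
                    "pairwise": m.pairwise.to_dict(orient="records"),
                } for cls, m in per.items()}
                for col, per in res["models"].items()
            },
        }
        st_path = os.path.join(config.out_dir, "stats.json")
        with open(st_path, "w") as fh:
            json.dump(_jsonable(stats_json), fh, indent=2)
        emit("stats", st_path)
        cl = res["clusters"]
        conf_path = os.path.join(config.out_dir, "cluster_confusion.csv")
        cl.confusion.to_csv(conf_path)
        emit("cluster_confusion", conf_path)
        report_path = os.path.join(config.out_dir, "report.txt")
        with open(report_path, "w") as fh:
            fh.write(_render_report(summary, res))
        emit("report", report_path)
    except Exception as exc:
        raise PipelineStageError("stats", str(exc)) from exc
    timings["stats"] = time.time() - t0

    manifest["stages"] = [
        {"name": s, "seconds": round(timings[s], 3)} for s in STAGES
    ]
    manifest["artifacts"] = {k: {"path": os.path.relpath(v, config.out_dir),
                                 "sha256": _sha256(v)}
                             for k, v in artifacts.items()}
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    for s in STAGES:
        log.info("stage %-10s %6.2f s", s, timings[s])
    return manifest


def _render_report(summary: pd.DataFrame, res: dict) -> str:
    lines = ["Walkway analysis report", "=" * 24, ""]
    lines.append("Population summary (per GS class)")
    lines.append(pheno.format_summary(summary))
    lines.append("")
    lines.append("Feature correlations")
    for _, r in res["correlations"].iterrows():
        lines.append(f"  {r.feature_a} vs {r.feature_b}: r={r.r:.2f} "
                     f"[{r.ci_low:.2f}, {r.ci_high:.2f}] P={r.p:.3g} ({r.label})")
    lines.append("")
    lines.append("Fisher exact tests")
    for name, v in res["fisher"].items():
        lines.append(f"  {name}: P={v['p']:.3f}")
    lines.append("")
    lines.append("Feature models (LS means at mean body weight)")
    lines.append(st.format_model_table(res["models"]))
    lines.append("")
    lines.append("K-means clusters vs GS classes (counts; % within GS class)")
    cl = res["clusters"]
    lines.append(cl.confusion.to_string())
    lines.append(cl.confusion_pct.round(1).to_string())
    lines.append("")
    return "\n".join(lines) + "\n"
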