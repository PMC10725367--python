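"""End-to-end pipeline orchestration.

Chains the stages: simulate (or load) -> extract features -> feature stats
-> build graph -> optional anomaly filter -> threshold -> train -> evaluate,
persisting every intermediate table and finishing with a run manifest that
records the config snapshot, seeds and per-stage counts, so every artifact
on disk is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, graph as graphmod, phantoms, stats
from .features import FEATURE_NAMES, build_feature_table
from .nn.model import ModelConfig, train

log = logging.getLogger("lesiongraph")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_benign": 50, "n_malignant": 50, "image_size": 256},
    "features": {"glcm_levels": 8, "glcm_distance": 1, "band_k": 10},
    "stats": {"alpha": 0.05, "density_plots": False},
    "graph": {"threshold": 0.95, "one_based_ids": False},
    "filter": {"enabled": False, "weak_cut": 0.4, "strong_cut": 0.7},
    "model": {},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    n_images: int = 0
    n_feature_rows: int = 0
    n_edges_unthresholded: int = 0
    n_edges_final: int = 0
    filter_report: dict | None = None
    metrics: dict | None = None
    artifacts: dict = field(default_factory=dict)
    version: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML/JSON file and overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        for key, val in loaded.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/latest",
                 cohort=None) -> RunManifest:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    from . import __version__

    cfg = load_config(overrides=config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)

    # --- simulate / load --------------------------------------------------
    stage = "simulate"
    try:
        if cohort is None:
            sim = cfg["simulate"]
            cohort = phantoms.generate_cohort(
                int(sim["n_benign"]), int(sim["n_malignant"]),
                seed=seed, image_size=int(sim.get("image_size", 256)))
        manifest.n_images = len(cohort)
        log.info("stage=%s seed=%d images=%d", stage, seed, len(cohort))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- features ---------------------------------------------------------
    stage = "extract-features"
    try:
        fcfg = cfg["features"]
        table = build_feature_table(
            cohort, glcm_levels=int(fcfg["glcm_levels"]),
            glcm_distance=int(fcfg["glcm_distance"]),
            band_k=int(fcfg["band_k"]))
        fpath = out / "feature_table.csv"
        table.to_csv(fpath, index=False)
        manifest.n_feature_rows = len(table)
        manifest.artifacts["feature_table"] = str(fpath)
        log.info("stage=%s rows=%d cols=%d", stage, *table.shape)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- feature statistics ----------------------------------------------
    stage = "feature-stats"
    try:
        scfg = cfg["stats"]
        tt = stats.test_feature_table(table, alpha=float(scfg["alpha"]))
        tpath = out / "feature_ttest.csv"
        tt.to_csv(tpath, index=False)
        manifest.artifacts["feature_ttest"] = str(tpath)
        if scfg.get("density_plots"):
            paths = stats.plot_feature_densities(table, out / "density")
            manifest.artifacts["density_plots"] = [str(p) for p in paths]
        log.info("stage=%s significant=%d/%d", stage,
                 int(tt["significant"].sum()), len(tt))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- graph ------------------------------------------------------------
    stage = "build-graph"
    try:
        gcfg = cfg["graph"]
        edges = graphmod.build_edge_table(table)
        manifest.n_edges_unthresholded = len(edges)
        epath = out / "edge_table.csv"
        edges.to_frame(one_based=bool(gcfg.get("one_based_ids"))).to_csv(
            epath, index=False)
        manifest.artifacts["edge_table"] = str(epath)
        log.info("stage=%s edges=%d", stage, len(edges))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "filter-graph"
    try:
        if cfg["filter"].get("enabled"):
            labels = table["label"].to_numpy()
            edges, report = filtering.filter_anomalies(
                edges, labels, weak_cut=float(cfg["filter"]["weak_cut"]),
                strong_cut=float(cfg["filter"]["strong_cut"]))
            manifest.filter_report = report.to_dict()
            _write_json(out / "filter_report.json", report.to_dict())
            manifest.artifacts["filter_report"] = str(out / "filter_report.json")
            log.info("stage=%s kept=%d removed=%d", stage, report.final,
                     report.total - report.final)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "threshold"
    try:
        tau = cfg["graph"].get("threshold")
        kept = graphmod.threshold_edges(edges, tau)
        manifest.n_edges_final = len(kept)
        g = graphmod.Graph(
            X=table[FEATURE_NAMES].to_numpy(float),
            labels=table["label"].to_numpy(int),
            edges=kept, adjacency=graphmod.to_adjacency(kept))
        log.info("stage=%s tau=%s edges=%d", stage, tau, len(kept))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- train / evaluate -------------------------------------------------
    stage = "train"
    try:
        mcfg = ModelConfig.from_dict({"seed": seed, **cfg["model"]})
        result = train(g, mcfg)
        cpath = out / "curves.csv"
        result.curves.to_csv(cpath, index=False)
        manifest.artifacts["curves"] = str(cpath)
        log.info("stage=%s epochs=%d final_train_loss=%.4g", stage,
                 mcfg.epochs, result.curves["train_loss"].iloc[-1])
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = "evaluate"
    try:
        rep = result.report
        metrics = {"test": rep.to_dict(),
                   "train": result.train_report.to_dict()}
        if result.val_report is not None:
            metrics["val"] = result.val_report.to_dict()
        _write_json(out / "metrics.json", metrics)
        pd.DataFrame([[rep.tn, rep.fp], [rep.fn, rep.tp]],
                     index=["actual_benign", "actual_malignant"],
                     columns=["pred_benign", "pred_malignant"]).to_csv(
            out / "confusion_matrix.csv")
        manifest.metrics = metrics
        manifest.artifacts["metrics"] = str(out / "metrics.json")
        manifest.artifacts["confusion_matrix"] = str(out / "confusion_matrix.csv")
        log.info("stage=%s test_accuracy=%.2f", stage, rep.accuracy)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # manifest written last, atomically
    mpath = out / "manifest.json"
    tmp = mpath.with_suffix(".json.tmp")
    _write_json(tmp, manifest.to_dict())
    tmp.replace(mpath)
    manifest.artifacts["manifest"] = str(mpath)
    return manifest
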