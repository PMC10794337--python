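"""Seeded end-to-end pipeline orchestration.

Stages run in the fixed order simulate → segment → measure → supertiles
→ train → stats (any prefix may be requested). Every run directory gets
the resolved config (YAML), a config hash stamp on each artifact log
line, and the canonical CSV/JSON artifacts of each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from macromorph import groupstats, modeling, morphometry, segmentation, synthdata
from macromorph.io import MORPHOLOGY_FEATURES, read_feature_table, write_feature_table
from macromorph.supertiles import SuperTileParams, generate_supertiles

logger = logging.getLogger(__name__)

STAGES = ["simulate", "segment", "measure", "supertiles", "train", "stats"]


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # simulate
    n_scenes: int = 2
    cells_per_class_per_scene: int = 3
    cohort_scale: float = 0.25
    scene_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.65
    # segment / measure
    threshold: str | float = "otsu"
    min_area_px: int = 50
    border_policy: str = "drop"
    # supertiles
    tile_t: int = 10
    tile_s: int = 5
    # train
    task: str = "classify"
    predictors: list[str] = field(default_factory=lambda: list(MORPHOLOGY_FEATURES))
    n_trees: int = 100
    cv_folds: int = 10
    test_fraction: float = 0.30
    train_source: str = "supertiles"  # original | supertiles | mixed
    eval_on: str = "original_holdout"  # synthetic_split | original_holdout

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        self.stages = sorted(set(self.stages), key=STAGES.index)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["scene_shape"] = list(d["scene_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scene_shape" in data:
            data["scene_shape"] = tuple(data["scene_shape"])
        return cls(**data)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["scene_shape"] = list(d["scene_shape"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _log_stage(name: str, cfg_hash: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s config=%s elapsed=%.2fs %s", name, cfg_hash, time.time() - t0, extras)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute the requested stage prefix; returns artifact paths.

    Raises FileNotFoundError naming the missing artifact if a stage is
    requested without its upstream input.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_yaml(out / "config.yaml")
    artifacts: dict[str, Path] = {"config": out / "config.yaml"}
    rng_seed = config.seed

    if "simulate" in config.stages:
        t0 = time.time()
        specs = synthdata.dataset1_class_specs(scale=config.cohort_scale)
        cohort = synthdata.make_tabular_cohort(specs, seed=rng_seed)
        write_feature_table(cohort, out / "cohort.csv")
        artifacts["cohort"] = out / "cohort.csv"
        scene_dir = out / "scenes"
        scene_dir.mkdir(exist_ok=True)
        for i in range(config.n_scenes):
            stack, truth = synthdata.make_scene(
                specs,
                seed=rng_seed + i,
                shape=config.scene_shape,
                pixel_size=config.pixel_size,
                n_cells_per_class=config.cells_per_class_per_scene,
            )
            synthdata.write_scene_tiff(scene_dir / f"scene_{i:03d}.tif", stack, truth)
            truth.to_csv(scene_dir / f"scene_{i:03d}_truth.csv")
        artifacts["scenes"] = scene_dir
        _log_stage("simulate", cfg_hash, t0, cells=len(cohort), scenes=config.n_scenes)

    if "segment" in config.stages or "measure" in config.stages:
        scene_dir = Path(artifacts.get("scenes", out / "scenes"))
        if not scene_dir.exists():
            raise FileNotFoundError(
                f"segment stage needs scene TIFFs at {scene_dir}; run the simulate stage first"
            )
        t0 = time.time()
        scene_files = sorted(scene_dir.glob("scene_*.tif"))
        if not scene_files:
            raise FileNotFoundError(
                f"segment stage found no scene TIFFs in {scene_dir}; "
                "run simulate with n_scenes >= 1 first"
            )
        frames = []
        n_cells = 0
        for tif in scene_files:
            stack = synthdata.read_scene_tiff(tif)
            sidecar = json.loads(tif.with_name(tif.stem + "_truth.json").read_text())
            channel_names = sidecar["channel_names"]
            label_map, cells = segmentation.segment_scene(
                stack[0],
                stack[1],
                pixel_size=sidecar["pixel_size"],
                threshold=config.threshold,
                min_area_px=config.min_area_px,
                border_policy=config.border_policy,
            )
            label_map.write_tiff(tif.with_name(tif.stem + "_labels.tif"))
            label_map.to_frame().to_csv(tif.with_name(tif.stem + "_cells.csv"), index=False)
            n_cells += len(cells)
            if "measure" in config.stages:
                markers = {m: stack[i] for i, m in enumerate(channel_names) if i >= 2}
                feats = morphometry.measure_cells(
                    cells, sidecar["pixel_size"], marker_channels=markers
                )
                feats["scene"] = tif.stem
                frames.append(feats)
        _log_stage("segment", cfg_hash, t0, cells=n_cells)
        if "measure" in config.stages:
            measured = pd.concat(frames, ignore_index=True)
            measured["cell_id"] = np.arange(1, len(measured) + 1)
            write_feature_table(measured, out / "measured_features.csv")
            artifacts["measured_features"] = out / "measured_features.csv"
            _log_stage("measure", cfg_hash, t0, rows=len(measured))

    if "supertiles" in config.stages:
        cohort_path = artifacts.get("cohort", out / "cohort.csv")
        if not Path(cohort_path).exists():
            raise FileNotFoundError(
                f"supertiles stage needs the feature table at {cohort_path}; run simulate first"
            )
        t0 = time.time()
        cohort = read_feature_table(cohort_path)
        params = SuperTileParams(t=config.tile_t, s=config.tile_s, seed=rng_seed)
        tiles = generate_supertiles(cohort, params)
        tiles.table.to_csv(out / "supertiles.csv", index=False)
        (out / "supertiles_provenance.json").write_text(
            json.dumps(
                {"t": params.t, "s": params.s, "seed": params.seed, "replace": params.replace,
                 "n_tiles": len(tiles.table), "config": cfg_hash},
                indent=1,
            )
        )
        artifacts["supertiles"] = out / "supertiles.csv"
        _log_stage("supertiles", cfg_hash, t0, tiles=len(tiles.table))

    if "train" in config.stages:
        cohort_path = artifacts.get("cohort", out / "cohort.csv")
        if not Path(cohort_path).exists():
            raise FileNotFoundError(
                f"train stage needs the feature table at {cohort_path}; run simulate first"
            )
        t0 = time.time()
        cohort = read_feature_table(cohort_path)
        mc = modeling.ModelConfig(
            task="classify" if config.task == "classify" else "regress",
            predictors=list(config.predictors),
            n_trees=config.n_trees,
            cv_folds=config.cv_folds,
            test_fraction=config.test_fraction,
            seed=rng_seed,
        )
        if config.task == "classify":
            bundle = modeling.run_experiment(
                cohort,
                "classify_all",
                mc,
                source=config.train_source,
                eval_on=config.eval_on,
                tile_params=SuperTileParams(t=config.tile_t, s=config.tile_s, seed=rng_seed),
            )
        else:
            bundle = modeling.run_experiment(cohort, "regress_il10", mc)
        modeling.save_report(bundle, out / "model_report.json")
        artifacts["model_report"] = out / "model_report.json"
        _log_stage("train", cfg_hash, t0, accuracy=getattr(bundle["report"], "accuracy", None))

    if "stats" in config.stages:
        cohort_path = artifacts.get("cohort", out / "cohort.csv")
        if not Path(cohort_path).exists():
            raise FileNotFoundError(
                f"stats stage needs the feature table at {cohort_path}; run simulate first"
            )
        t0 = time.time()
        cohort = read_feature_table(cohort_path)
        tests = groupstats.kruskal_dunn_table(cohort, feature_cols=MORPHOLOGY_FEATURES)
        tests.to_csv(out / "group_tests.csv", index=False)
        cam = groupstats.class_average_map(cohort, feature_cols=MORPHOLOGY_FEATURES)
        cam.matrix.to_csv(out / "class_means_scaled.csv")
        pd.DataFrame(
            cam.row_linkage, columns=["child_a", "child_b", "height", "n_leaves"]
        ).to_csv(out / "class_linkage.csv", index=False)
        artifacts["group_tests"] = out / "group_tests.csv"
        artifacts["class_means"] = out / "class_means_scaled.csv"
        _log_stage("stats", cfg_hash, t0, features=len(tests))

    return artifacts
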