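"""End-to-end pipeline: simulate -> train -> exemplar features -> NCA
selection -> classification, with per-stage toggles, config hashing and
structured logging.

Every artifact carries the config hash; dimensional contracts between stages
(patch count, vectors per image, feature length, merged width, selected k)
are asserted at stage boundaries.  Re-running with the same config and seed
reproduces all CSV/JSON outputs bit-identically.
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

from brainnext.architecture import ArchSpec, build_brainnext, BrainNeXt
from brainnext.errors import BrainNextError, ConfigurationError
from brainnext.evaluation import ClassifierConfig, cross_validate
from brainnext.nca_selection import NCAConfig, nca_fit, select_top_k
from brainnext.patch_features import dataset_features
from brainnext.phantoms import (PhantomConfig, generate_phantoms,
                                read_image_set, write_image_set)
from brainnext.training import TrainConfig, train

log = logging.getLogger("brainnext")


@dataclass
class PipelineConfig:
    out_root: str = "runs"
    data_root: str | None = None          # existing manifest dir; else simulate
    seed: int = 0
    n_per_class: int = 40
    arch: ArchSpec = field(default_factory=ArchSpec)
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    nca_cfg: NCAConfig = field(default_factory=NCAConfig)
    classifier_cfg: ClassifierConfig = field(default_factory=ClassifierConfig)
    patch_size: int = 32
    grid_size: int = 224
    select_k: int = 100
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "train": True, "features": True,
        "select": True, "evaluate": True})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        top = data.get("pipeline", {})
        for key in ("out_root", "data_root", "seed", "n_per_class",
                    "patch_size", "grid_size", "select_k"):
            if key in top:
                setattr(cfg, key, top[key])
        if "stages" in top:
            cfg.stages.update(top["stages"])
        if "architecture" in data:
            cfg.arch = ArchSpec.from_dict(data["architecture"])
        for section, obj in (("training", cfg.train_cfg),
                             ("nca", cfg.nca_cfg),
                             ("classifier", cfg.classifier_cfg)):
            for k, v in data.get(section, {}).items():
                if not hasattr(obj, k):
                    raise ConfigurationError(f"unknown key {k!r} in "
                                             f"[{section}]")
                setattr(obj, k, v)
        return cfg


def _propagate_seed(cfg: PipelineConfig) -> None:
    cfg.arch.seed = cfg.seed
    cfg.train_cfg.seed = cfg.seed
    cfg.nca_cfg.seed = cfg.seed
    cfg.classifier_cfg.seed = cfg.seed


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages; returns the run directory."""
    _propagate_seed(cfg)
    chash = cfg.config_hash()
    run_dir = Path(cfg.out_root) / f"run-{chash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    echo = cfg.to_dict()
    echo["config_hash"] = chash
    (run_dir / "config.json").write_text(json.dumps(echo, indent=2,
                                                    sort_keys=True))
    stage = "config"
    try:
        image_set = None
        t0 = time.time()
        if cfg.stages.get("simulate", True):
            stage = "simulate"
            pcfg = PhantomConfig(n_per_class=cfg.n_per_class, seed=cfg.seed,
                                 image_size=cfg.grid_size)
            image_set = generate_phantoms(pcfg)
            write_image_set(image_set, run_dir / "data")
            log.info("[%s] %d images in %.1fs (hash %s)", stage,
                     len(image_set), time.time() - t0, chash)
        elif cfg.data_root:
            image_set = read_image_set(Path(cfg.data_root) / "manifest.csv")

        net = None
        if cfg.stages.get("train", True):
            stage = "train"
            if image_set is None:
                raise ConfigurationError("train stage needs data")
            t0 = time.time()
            net = build_brainnext(cfg.arch)
            report = train(net, image_set.subset("train") if any(
                it.split == "test" for it in image_set.items) else image_set,
                cfg.train_cfg, checkpoint_path=run_dir / "checkpoint.npz")
            report.to_json(run_dir / "train_report.json")
            log.info("[%s] best val acc %.2f%% in %.1fs", stage,
                     report.best_val_accuracy, time.time() - t0)

        fm = None
        if cfg.stages.get("features", True):
            stage = "features"
            if net is None:
                ckpt = run_dir / "checkpoint.npz"
                net = (BrainNeXt.load(ckpt) if ckpt.exists()
                       else build_brainnext(cfg.arch))
            if image_set is None:
                raise ConfigurationError("features stage needs data")
            t0 = time.time()
            fm = dataset_features(net, image_set, cfg.patch_size,
                                  cfg.grid_size)
            n_patches = (cfg.grid_size // cfg.patch_size) ** 2
            assert fm.n_vectors == n_patches + 1
            assert fm.width == fm.feature_len * fm.n_vectors
            fm.to_csv(run_dir / "features.csv")
            log.info("[%s] %d x %d matrix in %.1fs", stage,
                     fm.values.shape[0], fm.width, time.time() - t0)

        selected = sel_idx = None
        if cfg.stages.get("select", True):
            stage = "select"
            if fm is None:
                raise ConfigurationError("select stage needs features")
            t0 = time.time()
            # selection is fitted on training-split rows only, then applied
            # to every row (avoids test leakage into the ranking)
            train_rows = np.array([it.split != "test"
                                   for it in image_set.items])
            res = nca_fit(fm.values[train_rows], fm.labels[train_rows],
                          cfg.nca_cfg)
            res.to_csv(run_dir / "selection.csv")
            selected, sel_idx = select_top_k(res, fm.values, cfg.select_k)
            assert selected.shape[1] == cfg.select_k
            log.info("[%s] top-%d of %d in %.1fs", stage, cfg.select_k,
                     fm.width, time.time() - t0)

        if cfg.stages.get("evaluate", True):
            stage = "evaluate"
            if selected is None:
                raise ConfigurationError("evaluate stage needs selection")
            t0 = time.time()
            report = cross_validate(selected, fm.labels, cfg.classifier_cfg,
                                    class_names=list(image_set.class_names))
            report.to_json(run_dir / "eval_report.json")
            np.savetxt(run_dir / "confusion.csv", report.confusion,
                       fmt="%d", delimiter=",")
            log.info("[%s] accuracy %.2f%% in %.1fs", stage,
                     100 * report.accuracy, time.time() - t0)
    except BrainNextError:
        log.exception("stage %s failed; artifacts kept in %s", stage, run_dir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return run_dir
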