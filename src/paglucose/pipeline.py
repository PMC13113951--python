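"""End-to-end pipeline: simulate -> features -> calibrate -> classify -> EGA.

Every run writes its intermediate artifacts (spectra CSV, features CSV,
calibration JSON, classifier reports, EGA reports) plus a manifest with the
resolved configuration, seed, package versions, and a SHA-256 content hash
per artifact, so two runs of the same (config, seed) can be compared
byte-wise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import GlucoseCalibration
from .classify import (
    KNNConfig,
    WideNetConfig,
    build_feature_matrix,
    cross_validate,
    holdout_evaluate,
)
from .ega import confusion_to_ega
from .io import dump_config, write_features_csv, write_json, write_spectra_csv
from .prep import extract_features
from .synth import DatasetConfig, simulate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("paglucose")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    band: tuple[float, float] = (22.0, 24.0)
    center_khz: float = 23.05
    half_width: int = 4
    n_folds: int = 10
    knn: KNNConfig = field(default_factory=KNNConfig)
    widenet: WideNetConfig = field(default_factory=WideNetConfig)
    holdout: str | float = "one-per-class"
    ml_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset.to_dict(),
            "band": list(self.band),
            "center_khz": self.center_khz,
            "half_width": self.half_width,
            "n_folds": self.n_folds,
            "knn": {"k": self.knn.k},
            "widenet": self.widenet.__dict__ | {},
            "holdout": self.holdout,
            "ml_seed": self.ml_seed,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, func, manifest: dict):
    t0 = time.perf_counter()
    try:
        result = func()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    log.info("stage %-10s done in %.2f s", name, dt)
    manifest["stages"][name] = {"wall_time_s": round(dt, 4)}
    return result


def run_pipeline(config: PipelineConfig | None = None, outdir: str | Path = "pipeline_out") -> dict:
    """Execute all stages and write the artifact bundle under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    cfg = config or PipelineConfig()
    if cfg.n_folds < 2:
        raise ValueError("cross_validate requires n_folds >= 2")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "paglucose",
        "version": __version__,
        "seed": cfg.dataset.noise.seed,
        "ml_seed": cfg.ml_seed,
        "config": cfg.to_dict(),
        "stages": {},
        "artifacts": {},
    }

    dataset = _stage("simulate", lambda: simulate_dataset(cfg.dataset), manifest)
    write_spectra_csv(dataset, out / "spectra.csv")

    features = _stage(
        "features",
        lambda: extract_features(dataset, cfg.band, cfg.center_khz, cfg.half_width),
        manifest,
    )
    write_features_csv(features, out / "features.csv")

    calib = _stage("calibrate", lambda: GlucoseCalibration(features).fit(), manifest)
    write_json(calib.to_dict(), out / "calibration.json")

    matrix = build_feature_matrix(dataset)
    classes = matrix.classes
    reports = {}
    for name, clf_cfg in (("knn", cfg.knn), ("widenet", cfg.widenet)):
        report = _stage(
            f"classify_{name}",
            lambda c=clf_cfg: cross_validate(matrix, c, cfg.n_folds, cfg.ml_seed),
            manifest,
        )
        holdout_rep = holdout_evaluate(matrix, clf_cfg, cfg.holdout, cfg.ml_seed)
        write_json(
            {"cv": report.to_dict(), "holdout": holdout_rep.to_dict()},
            out / f"report_{name}.json",
        )
        np.savetxt(
            out / f"confusion_{name}.csv",
            report.confusion,
            fmt="%d",
            delimiter=",",
            header=",".join(str(int(c)) for c in classes),
        )
        ega = _stage(
            f"ega_{name}",
            lambda r=report: confusion_to_ega(r.confusion, classes),
            manifest,
        )
        write_json(ega.to_dict(), out / f"ega_{name}.json")
        reports[name] = {"cv": report, "holdout": holdout_rep, "ega": ega}

    dump_config(cfg.dataset, out / "config.yaml")
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
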