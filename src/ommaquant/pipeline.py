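"""End-to-end batch pipeline: ingest (or simulate) → segment → featurize →
split → grid search → train → evaluate → IREG, with manifest-driven I/O,
skip-and-log failure handling and full provenance (config hash + seed)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import (ClassifierSpec, cv_grid_search, evaluate,
                       stratified_split, train_classifier)
from .errors import OmmaquantError, StageError
from .hog import FeatureMatrix, HOGParams, featurize_dataset
from .images import load_image
from .ireg import ireg_batch
from .roi import SegmentationParams, segment_eye


@dataclass
class PipelineConfig:
    """Every knob of one reproducible run; a single seed drives the split,
    the CV folds and the learners."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    hog: HOGParams = field(default_factory=HOGParams)
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("svm_rbf"))
    train_frac: float = 0.75
    cv_folds: int = 10
    grid: dict | None = None
    seed: int = 0
    # either a manifest CSV of (path, class) rows, or simulate n per class
    manifest: str | None = None
    simulate_n_per_class: int | None = None
    illumination: str = "diffuse"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "hog" in kwargs:
            kwargs["hog"] = HOGParams(**kwargs["hog"])
        if "classifier" in kwargs:
            c = kwargs["classifier"]
            kwargs["classifier"] = ClassifierSpec(c["kind"], c.get("hyperparameters", {}))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _iter_inputs(config: PipelineConfig, failures: list):
    """Yield (image, label, path) one item at a time, from a manifest or
    the simulator; unreadable files are logged into ``failures``."""
    if config.manifest is not None:
        mf = pd.read_csv(config.manifest)
        for _, row in mf.iterrows():
            try:
                img = load_image(row["path"])
            except (OmmaquantError, OSError, FileNotFoundError) as exc:
                failures.append({"path": str(row["path"]), "stage": "load",
                                 "error": str(exc)})
                continue
            yield img, str(row["class"]), str(row["path"])
        return
    if config.simulate_n_per_class is None:
        raise ValueError("config must provide a manifest or simulate_n_per_class")
    base = dataclasses.replace(synthetic.EyeSpec(), illumination=config.illumination)
    for k, li in enumerate(synthetic.iter_labeled_set(
            config.simulate_n_per_class, base, config.seed)):
        yield li.image, li.class_label, f"synthetic:{k}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return a JSON-serializable report.

    Images failing segmentation are logged and skipped rather than
    aborting the batch.  Full-resolution frames are processed one at a
    time; only the (much smaller) ROI patches are accumulated.
    """
    failures: list = []
    n_input = 0
    patches, kept_labels = [], []
    for img, lab, path in _iter_inputs(config, failures):
        n_input += 1
        try:
            patch = segment_eye(img, config.segmentation, source_path=path)
        except StageError as exc:
            failures.append({"path": path, "stage": exc.stage, "error": str(exc.cause)})
            continue
        patches.append(patch)
        kept_labels.append(lab)
    if n_input == 0:
        raise ValueError("no readable input images")
    if not patches:
        raise ValueError("segmentation failed on every input image")

    feats = featurize_dataset(patches, kept_labels, config.hog)
    split = stratified_split(feats.labels, config.train_frac, config.seed)
    train = FeatureMatrix(X=feats.X[split.train],
                          labels=[feats.labels[i] for i in split.train])
    test = FeatureMatrix(X=feats.X[split.test],
                         labels=[feats.labels[i] for i in split.test])

    k = min(config.cv_folds,
            min(np.unique(train.labels, return_counts=True)[1]))
    best, cv_table = cv_grid_search(train, config.classifier, config.grid,
                                    k=int(k), seed=config.seed)
    spec = config.classifier.with_params(**best)
    model = train_classifier(train, spec, config.seed)
    report_eval = evaluate(model, test)

    test_patches = [patches[i] for i in split.test]
    summary = ireg_batch(model, test_patches,
                         [kept_labels[i] for i in split.test], config.hog)

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_input": n_input,
        "n_segmented": len(patches),
        "n_train": len(train), "n_test": len(test),
        "failures": failures,
        "cv_best_params": best,
        "cv_table": [{"params": p, "accuracy": a} for p, a in cv_table],
        "evaluation": report_eval.as_dict(),
        "ireg": {g: s for g, s in summary.stats.items()},
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
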