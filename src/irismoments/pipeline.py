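"""End-to-end orchestration: enroll (train) and identify eye images.

The full path for one image is segment → unwrap → moment feature vector;
training standardizes the signed-log features with training-set
statistics, fits k-means with one cluster per enrolled class, and
calibrates the four confidence thresholds from within-cluster training
distances.  Everything is reproducible from a config and its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .clustering import (
    ClusterModel,
    MatchResult,
    calibrate_thresholds,
    classify,
    kmeans_fit,
    FeatureScaler,
)
from .moments import feature_vector
from .segmentation import SegmentationConfig, SegmentationError, segment_iris
from .unwrap import unwrap_annulus

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "extract_features",
    "train_model",
    "evaluate_split",
    "load_labeled_dir",
    "run_pipeline",
]

log = logging.getLogger("irismoments")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline; serializes losslessly to YAML/JSON."""

    median_iterations: int = 3
    median_window: int = 3
    edge_method: str = "canny"
    canny_sigma: float = 2.0
    canny_low: float = 50.0
    canny_high: float = 80.0
    sobel_threshold: float = 150.0
    n_triplets: int = 50
    trim_fraction: float = 0.2
    n_theta: int = 96
    n_r: int = 64
    max_iter: int = 300
    percentiles: tuple[float, float, float, float] = (50.0, 75.0, 90.0, 99.0)
    seed: int = 0

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            median_iterations=self.median_iterations,
            median_window=self.median_window,
            edge_method=self.edge_method,
            canny_sigma=self.canny_sigma,
            canny_low=self.canny_low,
            canny_high=self.canny_high,
            sobel_threshold=self.sobel_threshold,
            n_triplets=self.n_triplets,
            trim_fraction=self.trim_fraction,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentiles"] = list(d["percentiles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def extract_features(image: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Segment, unwrap and featurize one eye image; returns the feature vector."""
    cfg = config or PipelineConfig()
    annulus = segment_iris(image, cfg.segmentation())
    canvas = unwrap_annulus(image, annulus, n_theta=cfg.n_theta, n_r=cfg.n_r)
    return feature_vector(canvas).features


def train_model(
    images: Sequence[np.ndarray],
    labels: Sequence[Hashable],
    config: PipelineConfig | None = None,
) -> ClusterModel:
    """Enroll labelled images: features → standardize → k-means → thresholds."""
    cfg = config or PipelineConfig()
    if len(images) == 0:
        raise ValueError("no training images")
    X = np.stack([extract_features(img, cfg) for img in images])
    scaler = FeatureScaler.fit(X)
    Xs = scaler.transform(X)
    model, _ = kmeans_fit(Xs, labels, max_iter=cfg.max_iter)
    model.scaler = scaler
    calibrate_thresholds(model, Xs, percentiles=cfg.percentiles)
    return model


def identify(image: np.ndarray, model: ClusterModel, config: PipelineConfig | None = None) -> MatchResult:
    """Classify one eye image against a trained model."""
    return classify(extract_features(image, config), model)


@dataclass
class PipelineReport:
    accuracy: float
    results: pd.DataFrame
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "results": self.results.to_dict(orient="records"),
            "confusion": {
                "labels": [str(c) for c in self.confusion.columns],
                "matrix": self.confusion.to_numpy().tolist(),
            },
        }


def evaluate_split(
    train_images: Sequence[np.ndarray],
    train_labels: Sequence[Hashable],
    test_images: Sequence[np.ndarray],
    test_labels: Sequence[Hashable],
    config: PipelineConfig | None = None,
    test_names: Sequence[str] | None = None,
) -> tuple[ClusterModel, PipelineReport]:
    """Train on one labelled set, classify another, and tabulate the outcome.

    The confusion matrix has one row per true class and one column per
    predicted class (plus a ``rejected`` column for level-4 no-matches);
    accuracy counts an image as correct only when a class is reported and
    it equals the true class.
    """
    cfg = config or PipelineConfig()
    model = train_model(train_images, train_labels, cfg)
    rows = []
    names = list(test_names) if test_names is not None else [
        f"test_{i}" for i in range(len(test_images))
    ]
    for name, img, truth in zip(names, test_images, test_labels):
        res = identify(img, model, cfg)
        rows.append(
            {
                "image": name,
                "true_label": truth,
                "predicted_label": res.label,
                "distance": res.distance,
                "level": res.level,
                "correct": res.label == truth,
            }
        )
    results = pd.DataFrame(rows)
    accuracy = float(results["correct"].mean()) if len(results) else float("nan")

    classes = sorted(set(map(str, train_labels)))
    pred = results["predicted_label"].map(lambda v: "rejected" if v is None else str(v))
    confusion = pd.crosstab(
        results["true_label"].map(str), pred, rownames=["true"], colnames=["predicted"]
    )
    confusion = confusion.reindex(
        index=classes, columns=classes + ["rejected"], fill_value=0
    )
    return model, PipelineReport(accuracy=accuracy, results=results, confusion=confusion)


def load_labeled_dir(root: str | Path) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Load ``<root>/<class>/*.png|pgm`` as (images, labels, names).

    Unreadable files are skipped with a warning; an empty class directory
    is an error.
    """
    root = Path(root)
    images: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] = []
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    for cdir in class_dirs:
        found = 0
        for path in sorted(cdir.glob("*")):
            if path.suffix.lower() not in {".png", ".pgm"}:
                continue
            try:
                img = np.asarray(iio.imread(path))
            except Exception as exc:  # unreadable file: skip, keep going
                log.warning("skipping unreadable image %s (%s)", path, exc)
                continue
            if img.ndim == 3:
                img = img[..., 0]
            images.append(img)
            labels.append(cdir.name)
            names.append(str(path.relative_to(root)))
            found += 1
        if found == 0:
            raise ValueError(f"empty training class directory {cdir}")
    return images, labels, names


def run_pipeline(
    config: PipelineConfig,
    train_dir: str | Path,
    test_dir: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Train on ``train_dir``, classify ``test_dir``, optionally write reports.

    Emits ``report.json`` (accuracy + per-image results + confusion
    matrix), ``results.csv`` and ``confusion.csv`` under ``out_dir``.
    """
    tr_imgs, tr_labels, _ = load_labeled_dir(train_dir)
    te_imgs, te_labels, te_names = load_labeled_dir(test_dir)
    _, report = evaluate_split(
        tr_imgs, tr_labels, te_imgs, te_labels, config, test_names=te_names
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.results.to_csv(out / "results.csv", index=False)
        report.confusion.to_csv(out / "confusion.csv")
    return report
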