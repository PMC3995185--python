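"""k-means training and distance-based identification with confidence levels.

Training alternates the two classic steps — assignment of every feature
vector to the nearest mean (ties to the lowest cluster index, so each
vector lands in exactly one cluster) and recomputation of each mean as
the centroid of its assigned vectors — until no assignment changes.  The
number of clusters equals the number of enrolled classes and each cluster
is initialized from one sample of its class, which makes the cluster →
class map well defined.

Identification measures the Euclidean distance of a feature vector to
every centroid; the nearest centroid's class is reported together with a
confidence level 0–4 obtained by banding the distance against four
calibrated thresholds t0 < t1 < t2 < t3 (level 0 = closest match, level 4
= no confident match, no class reported).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "FeatureScaler",
    "KMeansResult",
    "ClusterModel",
    "MatchResult",
    "kmeans_fit",
    "objective",
    "calibrate_thresholds",
    "classify",
]

# floor used when every training distance is zero (degenerate calibration)
MIN_THRESHOLD_SCALE = 1e-9


@dataclass(frozen=True)
class FeatureScaler:
    """Per-component standardization frozen at training time."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std > 1e-12, std, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclass
class KMeansResult:
    centroids: np.ndarray
    assignments: np.ndarray
    objective: float
    objective_history: list[float]
    n_iter: int
    converged: bool


@dataclass
class ClusterModel:
    """Trained centroids with the scaling and thresholds needed to classify."""

    centroids: np.ndarray
    label_map: list
    scaler: FeatureScaler | None = None
    thresholds: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.centroids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centroids": np.asarray(self.centroids).tolist(),
            "label_map": list(self.label_map),
            "scaler": None
            if self.scaler is None
            else {"mean": self.scaler.mean.tolist(), "std": self.scaler.std.tolist()},
            "thresholds": None
            if self.thresholds is None
            else np.asarray(self.thresholds).tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        payload = json.loads(Path(path).read_text())
        scaler = None
        if payload["scaler"] is not None:
            scaler = FeatureScaler(
                mean=np.asarray(payload["scaler"]["mean"], dtype=float),
                std=np.asarray(payload["scaler"]["std"], dtype=float),
            )
        thresholds = (
            None
            if payload["thresholds"] is None
            else np.asarray(payload["thresholds"], dtype=float)
        )
        return cls(
            centroids=np.asarray(payload["centroids"], dtype=float),
            label_map=payload["label_map"],
            scaler=scaler,
            thresholds=thresholds,
        )


@dataclass(frozen=True)
class MatchResult:
    """Nearest-centroid identification of one feature vector."""

    cluster: int | None
    label: Hashable | None
    distance: float
    level: int


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # squared Euclidean; argmin breaks ties toward the lowest cluster index
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def objective(centroids: np.ndarray, X: np.ndarray, assignments: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances."""
    X = np.asarray(X, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    a = np.asarray(assignments)
    return float(((X - centroids[a]) ** 2).sum())


def kmeans_fit(
    X: np.ndarray,
    labels: Sequence[Hashable],
    init: np.ndarray | None = None,
    max_iter: int = 300,
) -> tuple[ClusterModel, KMeansResult]:
    """Fit k-means with one cluster per distinct label.

    ``init`` supplies one starting mean per class (rows ordered by sorted
    label); by default the first sample of each class is used, mirroring
    the scheme where an enrolled image's own moment vector seeds its
    cluster.  Iteration stops when an assignment pass changes nothing (or
    at ``max_iter``, flagged via ``converged=False``).  A cluster emptied
    mid-run is re-seeded with the vector farthest from its previous mean.
    The objective is recorded after every assignment and update half-step
    and is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty (n, d) feature matrix")
    labels = list(labels)
    if len(labels) != len(X):
        raise ValueError("labels must match the number of feature vectors")
    classes = sorted(set(labels))
    k = len(classes)
    if init is None:
        first = {}
        for lab, row in zip(labels, X):
            first.setdefault(lab, row)
        init = np.stack([first[c] for c in classes])
    init = np.asarray(init, dtype=float)
    if init.shape != (k, X.shape[1]):
        raise ValueError(f"init must be ({k}, {X.shape[1]}), got {init.shape}")

    centroids = init.copy()
    assignments = _assign(X, centroids)
    history = [objective(centroids, X, assignments)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_centroids = centroids.copy()
        for i in range(k):
            members = X[assignments == i]
            if len(members):
                new_centroids[i] = members.mean(axis=0)
            else:
                far = np.argmax(((X - centroids[i]) ** 2).sum(axis=1))
                new_centroids[i] = X[far]
        centroids = new_centroids
        history.append(objective(centroids, X, assignments))
        new_assignments = _assign(X, centroids)
        history.append(objective(centroids, X, new_assignments))
        if np.array_equal(new_assignments, assignments):
            converged = True
            assignments = new_assignments
            break
        assignments = new_assignments

    model = ClusterModel(centroids=centroids, label_map=list(classes))
    result = KMeansResult(
        centroids=centroids,
        assignments=assignments,
        objective=history[-1],
        objective_history=history,
        n_iter=n_iter,
        converged=converged,
    )
    return model, result


DEFAULT_GAP_FRACTIONS = (0.15, 0.30, 0.45, 0.60)


def calibrate_thresholds(
    model: ClusterModel,
    X: np.ndarray,
    percentiles: Sequence[float] = (50.0, 75.0, 90.0, 99.0),
    loo_correction: bool = True,
    gap_fractions: Sequence[float] | None = DEFAULT_GAP_FRACTIONS,
) -> np.ndarray:
    """Set t0 < t1 < t2 < t3 from within-cluster training distances.

    Thresholds are the given percentiles of every training vector's
    Euclidean distance to its nearest centroid.  Two corrections make the
    bands cover held-out genuine samples, not just the (optimistically
    small) training distances:

    * ``loo_correction`` rescales each distance by n_i/(n_i − 1), the
      exact leave-one-out identity |x − mean(S \\ x)| = |x − mean(S)| ·
      n/(n − 1), undoing the shrinkage a vector exerts on its own
      centroid;
    * ``gap_fractions`` floors each t_j at the given fraction of the
      median inter-centroid distance, so the accept bands scale with the
      geometry of the enrolled classes rather than with the handful of
      enrollment samples (rejection still triggers beyond 60% of the
      typical centroid gap by default).

    Strict increase is enforced by an epsilon jitter, and an all-zero
    distance distribution (every vector on its centroid, single cluster)
    falls back to a documented minimum scale so exact matches still
    classify at level 0.
    """
    if len(percentiles) != 4:
        raise ValueError("exactly four percentiles are required")
    X = np.asarray(X, dtype=float)
    a = _assign(X, model.centroids)
    d = np.sqrt(((X - model.centroids[a]) ** 2).sum(axis=1))
    if loo_correction:
        counts = np.bincount(a, minlength=model.k).astype(float)
        factor = np.where(counts[a] > 1, counts[a] / np.maximum(counts[a] - 1, 1), 1.0)
        d = d * factor
    t = np.percentile(d, percentiles).astype(float)
    if gap_fractions is not None and model.k >= 2:
        if len(gap_fractions) != 4:
            raise ValueError("exactly four gap fractions are required")
        c = model.centroids
        pair_d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
        gap = float(np.median(pair_d[np.triu_indices(model.k, k=1)]))
        t = np.maximum(t, np.asarray(gap_fractions, dtype=float) * gap)
    if t[-1] <= 0.0:
        t = MIN_THRESHOLD_SCALE * np.array([1.0, 2.0, 3.0, 4.0])
    eps = max(1e-12, 1e-9 * t[-1])
    for i in range(1, 4):
        t[i] = max(t[i], t[i - 1] + eps)
    model.thresholds = t
    return t


def classify(vector: np.ndarray, model: ClusterModel) -> MatchResult:
    """Identify a feature vector by its nearest centroid.

    ``vector`` is in the same (unstandardized) feature space the model
    was trained from when the model carries a scaler; the scaler is
    applied here.  The confidence level is the smallest j with
    distance <= t_j, else 4; at level 4 no class is reported.
    """
    if model.thresholds is None:
        raise ValueError("model thresholds not calibrated")
    v = np.asarray(vector, dtype=float).ravel()
    if v.shape[0] != model.centroids.shape[1]:
        raise ValueError(
            f"feature dimension {v.shape[0]} does not match model "
            f"dimension {model.centroids.shape[1]}"
        )
    if model.scaler is not None:
        v = model.scaler.transform(v[None, :])[0]
    d = np.sqrt(((model.centroids - v[None, :]) ** 2).sum(axis=1))
    i = int(np.argmin(d))  # tie -> lowest index
    dist = float(d[i])
    level = int(np.searchsorted(model.thresholds, dist, side="left"))
    if dist > model.thresholds[-1]:
        level = 4
    if level >= 4:
        return MatchResult(cluster=i, label=None, distance=dist, level=4)
    return MatchResult(cluster=i, label=model.label_map[i], distance=dist, level=level)
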