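"""Division-type classification.

K-means (k = 3, Lloyd's algorithm with random restarts) clusters the weighted
standardized division features; a small set of manually annotated anchor
divisions attaches the SR / A / SC labels to the clusters by per-cluster
majority; new divisions are assigned by nearest centroid ("1-NN to the
cluster centroids").  Nearest-centroid is used deliberately instead of 1-NN
over training points: centroids are the class prototypes.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .features import (FEATURE_NAMES, FeatureScaling, N_FEATURES,
                       apply_scaling, standardize)

LABELS = ("SR", "A", "SC")


@dataclass(frozen=True)
class AnchorSet:
    """Manually annotated divisions used to label the clusters.

    ``labels`` maps row indices of the training matrix to ground-truth
    division types.  At least one anchor per class is needed to label all
    three clusters.
    """

    labels: Mapping[int, str]

    def __post_init__(self) -> None:
        for idx, lab in self.labels.items():
            if lab not in LABELS:
                raise ValueError(f"anchor {idx}: unknown label {lab!r}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class DivisionClassifier:
    """k=3 centroids in scaled feature space plus the cluster -> label map."""

    centroids: np.ndarray            # (k, 38), scaled space
    scaling: FeatureScaling
    label_map: dict[int, str]
    seed: int = 0
    restarts: int = 50
    wss: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.centroids.shape[0]
        if sorted(self.label_map) != list(range(k)):
            raise ValueError("label map must cover every cluster index")
        if len(set(self.label_map.values())) != k:
            raise ValueError("label map must be a bijection onto the labels")

    def to_dict(self) -> dict:
        return {"centroids": self.centroids.tolist(),
                "scaling": self.scaling.to_dict(),
                "label_map": {str(k): v for k, v in self.label_map.items()},
                "seed": self.seed, "restarts": self.restarts, "wss": self.wss,
                "metadata": self.metadata}

    @classmethod
    def from_dict(cls, d: dict) -> "DivisionClassifier":
        return cls(np.asarray(d["centroids"], dtype=np.float64),
                   FeatureScaling.from_dict(d["scaling"]),
                   {int(k): v for k, v in d["label_map"].items()},
                   seed=d.get("seed", 0), restarts=d.get("restarts", 50),
                   wss=d.get("wss", float("nan")),
                   metadata=d.get("metadata", {}))


# --------------------------------------------------------------------------- #
# Lloyd's algorithm
# --------------------------------------------------------------------------- #

def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd's run from a random-point initialization.

    An emptied cluster is re-seeded at the point farthest from its assigned
    centroid.
    """
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assign = _assign(X, centroids)
    for _ in range(max_iter):
        for c in range(k):
            members = X[assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
            else:
                d2 = ((X - centroids[assign]) ** 2).sum(axis=1)
                centroids[c] = X[int(d2.argmax())]
        new_assign = _assign(X, centroids)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    wss = float(((X - centroids[assign]) ** 2).sum())
    return centroids, assign, wss


def kmeans(X: np.ndarray, k: int, restarts: int = 50,
           seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``restarts`` Lloyd's k-means (lowest within-cluster SS)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < k:
        raise ValueError(f"need >= {k} rows for k={k}")
    rng = np.random.default_rng(seed)
    best: Optional[tuple[np.ndarray, np.ndarray, float]] = None
    for _ in range(max(restarts, 1)):
        cand = _lloyd(X, k, rng)
        if best is None or cand[2] < best[2]:
            best = cand
    assert best is not None
    return best


# --------------------------------------------------------------------------- #
# training and prediction
# --------------------------------------------------------------------------- #

def _label_clusters(assign: np.ndarray, anchors: AnchorSet, k: int) -> dict[int, str]:
    """Per-cluster anchor majority; every failure mode is named explicitly."""
    votes = {c: Counter() for c in range(k)}
    for idx, lab in sorted(anchors.labels.items()):
        votes[int(assign[idx])][lab] += 1
    empty = [c for c in range(k) if not votes[c]]
    if empty:
        raise ValueError(f"unlabelable cluster(s) {empty}: no anchors assigned")
    label_map: dict[int, str] = {}
    for c in range(k):
        top = votes[c].most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            raise ValueError(
                f"within-cluster anchor tie in cluster {c}: {dict(votes[c])}")
        label_map[c] = top[0][0]
    if len(set(label_map.values())) != k:
        dupes = [lab for lab, n in Counter(label_map.values()).items() if n > 1]
        raise ValueError(f"ambiguous label map: clusters share majority {dupes}")
    return label_map


def train(matrix: np.ndarray, anchors: AnchorSet, k: int = 3,
          restarts: int = 50, seed: int = 0,
          weights: Optional[np.ndarray] = None) -> DivisionClassifier:
    """Train the division-type classifier.

    Standardizes (and weights) the raw feature matrix, clusters it with
    best-of-restarts k-means, and labels each cluster by the majority of its
    anchors.  Deterministic for a fixed seed.
    """
    X = np.asarray(matrix, dtype=np.float64)
    for idx in anchors.labels:
        if not (0 <= idx < X.shape[0]):
            raise ValueError(f"anchor index {idx} outside the training matrix")
    Xs, scaling = standardize(X, weights)
    centroids, assign, wss = kmeans(Xs, k, restarts=restarts, seed=seed)
    label_map = _label_clusters(assign, anchors, k)
    return DivisionClassifier(centroids, scaling, label_map, seed=seed,
                              restarts=restarts, wss=wss,
                              metadata={"n_train": int(X.shape[0]),
                                        "n_anchors": len(anchors), "k": k})


def predict(clf: DivisionClassifier, vectors: np.ndarray) -> np.ndarray:
    """Nearest-centroid label(s) for raw-scale feature vector(s).

    Euclidean distance in scaled space; exact ties go to the lowest cluster
    index.  Accepts a single 38-vector or an (n, 38) matrix.
    """
    X = np.asarray(vectors, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected feature dimension {N_FEATURES}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    Xs = apply_scaling(X, clf.scaling)
    assign = _assign(Xs, clf.centroids)   # argmin takes the lowest index on ties
    labels = np.array([clf.label_map[int(c)] for c in assign])
    return labels[0] if single else labels


def elbow_curve(matrix: np.ndarray, k_range: Sequence[int], restarts: int = 20,
                seed: int = 0, weights: Optional[np.ndarray] = None
                ) -> dict[int, float]:
    """Within-cluster sum of squares per k (same seed protocol for every k)."""
    X = np.asarray(matrix, dtype=np.float64)
    Xs, _ = standardize(X, weights)
    out: dict[int, float] = {}
    for k in k_range:
        if not (1 <= k <= X.shape[0]):
            raise ValueError(f"k={k} outside [1, {X.shape[0]}]")
        out[int(k)] = kmeans(Xs, k, restarts=restarts, seed=seed)[2]
    return out


def write_classifier(clf: DivisionClassifier, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(clf.to_dict(), fh, indent=2)


def read_classifier(path: str | Path) -> DivisionClassifier:
    with open(path) as fh:
        return DivisionClassifier.from_dict(json.load(fh))


def select_anchors(labels: Sequence[str], matrix: np.ndarray,
                   n_per_class: int = 4) -> AnchorSet:
    """Deterministically pick 'obvious' anchor divisions from annotated rows.

    Mirrors manual annotation of unambiguous divisions: for each class the
    rows with the most extreme daughter-commitment geometry are chosen —
    lowest daughter commitment for SR, highest for SC, largest
    daughter-commitment contrast for A (features daughter_high/low final
    commitment and contrast).
    """
    i_hi = FEATURE_NAMES.index("daughter_high_final_commit")
    i_lo = FEATURE_NAMES.index("daughter_low_final_commit")
    i_con = FEATURE_NAMES.index("daughter_commit_mean_contrast")
    lab = np.asarray(labels)
    X = np.asarray(matrix)
    chosen: dict[int, str] = {}
    for cls in LABELS:
        idx = np.where(lab == cls)[0]
        if idx.size == 0:
            continue
        if cls == "SR":
            score = -(X[idx, i_hi] + X[idx, i_lo])   # both daughters low
        elif cls == "SC":
            score = X[idx, i_hi] + X[idx, i_lo]      # both daughters high
        else:
            score = X[idx, i_con]                    # maximal contrast
        order = idx[np.argsort(-score, kind="stable")]
        for i in order[:n_per_class]:
            chosen[int(i)] = cls
    return AnchorSet(chosen)


__all__ = ["LABELS", "AnchorSet", "DivisionClassifier", "kmeans", "train",
           "predict", "elbow_curve", "select_anchors", "write_classifier",
           "read_classifier"]
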