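"""CART decision tree separating fat vacuoles from other holes.

A classification tree fits this problem well: the candidate feature space
is low-dimensional, the discriminating rules are axis-aligned by nature
(droplets are round and collagen-free, lumens large and collagen-walled,
nuclei dim but not signal-free) and, unlike margin- or distance-based
classifiers, an axis-aligned tree needs no feature pre-normalization — its
splits are invariant to any monotone rescaling of a feature column.

The tree is grown greedily on Gini impurity with deterministic
tie-breaking (lowest threshold, then lowest feature index), stopped by
``max_depth`` / ``min_samples_leaf`` / purity, unpruned. Leaves predict
their majority class; ties go to ``non_fat`` because a false fat call
inflates every steatosis parameter downstream.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import VacuoleCandidate

FAT = "fat"
NON_FAT = "non_fat"

#: Frozen feature order; serialized with every model.
FEATURE_NAMES = (
    "mean_tpef_intensity",
    "area_um2",
    "circularity",
    "solidity",
    "length_width_ratio",
    "collagen_annulus_fraction",
)

SCHEMA_VERSION = 1


def feature_vector(c: VacuoleCandidate) -> np.ndarray:
    """Candidate features in the frozen model order."""
    return np.array(
        [
            c.mean_tpef_intensity,
            c.area_um2,
            c.circularity,
            c.solidity,
            c.length_width_ratio,
            c.collagen_annulus_fraction,
        ],
        dtype=np.float64,
    )


def feature_matrix(candidates: Sequence[VacuoleCandidate]) -> np.ndarray:
    if len(candidates) == 0:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.stack([feature_vector(c) for c in candidates])


@dataclass
class TrainingSet:
    """Labeled feature vectors; labels are ``"fat"`` / ``"non_fat"``."""

    features: np.ndarray
    labels: np.ndarray
    origin: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (n_samples, n_features)")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        bad = set(np.unique(self.labels)) - {FAT, NON_FAT}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")


def gini_impurity(labels: Sequence) -> float:
    """Gini impurity 1 - sum(p_i^2) of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini_impurity of empty input is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p**2))


def _gini_from_counts(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        p = pos / n
        return 1.0 - p**2 - (1.0 - p) ** 2


def _best_split_column(
    x: np.ndarray, y: np.ndarray, min_samples_leaf: int = 1
) -> tuple[float | None, float]:
    """Best threshold (midpoint between distinct sorted values) and the
    weighted Gini decrease it achieves; ties broken by lowest threshold."""
    n = x.size
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order].astype(np.float64)
    boundaries = np.nonzero(xs[:-1] < xs[1:])[0]  # split after index i
    if boundaries.size == 0:
        return None, 0.0
    left_n = boundaries + 1.0
    right_n = n - left_n
    ok = (left_n >= min_samples_leaf) & (right_n >= min_samples_leaf)
    if not ok.any():
        return None, 0.0
    boundaries = boundaries[ok]
    left_n, right_n = left_n[ok], right_n[ok]
    cum_pos = np.cumsum(ys)
    left_pos = cum_pos[boundaries]
    total_pos = cum_pos[-1]
    parent = _gini_from_counts(np.array(total_pos), np.array(float(n)))
    child = (
        left_n * _gini_from_counts(left_pos, left_n)
        + right_n * _gini_from_counts(total_pos - left_pos, right_n)
    ) / n
    decrease = float(parent) - child
    # lowest threshold among (float-tolerant) ties for the best decrease
    best = int(np.argmax(decrease >= decrease.max() - 1e-12))
    if decrease[best] <= 0:
        return None, 0.0
    i = boundaries[best]
    threshold = float((xs[i] + xs[i + 1]) / 2.0)
    return threshold, float(decrease[best])


def best_split(column: Sequence[float], labels: Sequence) -> tuple[float | None, float]:
    """Best Gini split of one feature column (no leaf-size constraint)."""
    x = np.asarray(column, dtype=np.float64)
    y = np.asarray(labels)
    if x.size < 2:
        raise ValueError("best_split needs >= 2 samples")
    if x.size != y.size:
        raise ValueError("column and labels must have equal length")
    classes = np.unique(y)
    if classes.size > 2:
        raise ValueError("best_split supports binary labels only")
    return _best_split_column(x, y == classes[-1])


@dataclass
class _Node:
    feature: int | None = None
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    klass: str | None = None
    counts: tuple[int, int] = (0, 0)  # (n_fat, n_non_fat)

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None


@dataclass
class CartTree:
    """A trained, serializable binary classification tree."""

    root: _Node
    feature_names: tuple[str, ...] = FEATURE_NAMES
    max_depth: int = 5
    min_samples_leaf: int = 5
    n_training: int = 0

    def predict_one(self, fv: Sequence[float]) -> str:
        fv = np.asarray(fv, dtype=np.float64)
        if fv.shape != (len(self.feature_names),):
            raise ValueError(
                f"feature vector length {fv.size} != model arity "
                f"{len(self.feature_names)}"
            )
        node = self.root
        while not node.is_leaf:
            node = node.left if fv[node.feature] <= node.threshold else node.right
        return node.klass

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return np.array([self.predict_one(fv) for fv in features])

    def depth(self) -> int:
        def _d(node: _Node) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    # -- serialization ----------------------------------------------------
    def _node_to_dict(self, node: _Node) -> dict:
        if node.is_leaf:
            return {"class": node.klass, "counts": list(node.counts)}
        return {
            "feature": node.feature,
            "feature_name": self.feature_names[node.feature],
            "threshold": node.threshold,
            "left": self._node_to_dict(node.left),
            "right": self._node_to_dict(node.right),
        }

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "feature_names": list(self.feature_names),
            "hyperparams": {
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "impurity": "gini",
            },
            "n_training": self.n_training,
            "root": self._node_to_dict(self.root),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @staticmethod
    def _node_from_dict(d: dict) -> _Node:
        if "class" in d:
            return _Node(klass=d["class"], counts=tuple(d["counts"]))
        return _Node(
            feature=d["feature"],
            threshold=d["threshold"],
            left=CartTree._node_from_dict(d["left"]),
            right=CartTree._node_from_dict(d["right"]),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CartTree":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        hp = d.get("hyperparams", {})
        return cls(
            root=cls._node_from_dict(d["root"]),
            feature_names=tuple(d["feature_names"]),
            max_depth=hp.get("max_depth", 5),
            min_samples_leaf=hp.get("min_samples_leaf", 5),
            n_training=d.get("n_training", 0),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CartTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _leaf(y: np.ndarray) -> _Node:
    n_fat = int(y.sum())
    n_non = int(y.size - n_fat)
    # majority vote; tie -> non_fat (false fat inflates every readout)
    klass = FAT if n_fat > n_non else NON_FAT
    return _Node(klass=klass, counts=(n_fat, n_non))


def _grow(
    x: np.ndarray, y: np.ndarray, depth: int, max_depth: int, msl: int
) -> _Node:
    if depth >= max_depth or y.size < 2 * msl or y.all() or not y.any():
        return _leaf(y)
    best_feat, best_thr, best_dec = None, None, 0.0
    for j in range(x.shape[1]):
        thr, dec = _best_split_column(x[:, j], y, msl)
        if thr is not None and dec > best_dec + 1e-15:
            best_feat, best_thr, best_dec = j, thr, dec
    if best_feat is None:
        return _leaf(y)
    go_left = x[:, best_feat] <= best_thr
    return _Node(
        feature=best_feat,
        threshold=best_thr,
        left=_grow(x[go_left], y[go_left], depth + 1, max_depth, msl),
        right=_grow(x[~go_left], y[~go_left], depth + 1, max_depth, msl),
    )


def train_cart(
    ts: TrainingSet, max_depth: int = 5, min_samples_leaf: int = 5
) -> CartTree:
    """Grow a CART tree by greedy recursive Gini partitioning.

    Deterministic for a fixed training set: split ties resolve to the
    lowest threshold, then the lowest feature index.
    """
    y = ts.labels == FAT
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    n_features = ts.features.shape[1]
    names = (
        FEATURE_NAMES
        if n_features == len(FEATURE_NAMES)
        else tuple(f"feature_{i}" for i in range(n_features))
    )
    root = _grow(ts.features, y, 0, max_depth, min_samples_leaf)
    return CartTree(
        root=root,
        feature_names=names,
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        n_training=int(y.size),
    )


def make_training_set(
    candidates: Sequence[VacuoleCandidate],
    truth,
    iou_min: float = 0.5,
) -> TrainingSet:
    """Label candidates against phantom ground truth.

    A candidate is ``fat`` iff its best-overlapping truth object is a fat
    vacuole with IoU >= ``iou_min``; anything else (vessel, nucleus,
    spurious) is ``non_fat``. Labels do not depend on candidate order.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates to label")
    raster = truth.label_raster
    by_id = {o.id: o for o in truth.objects}
    feats = feature_matrix(candidates)
    labels = []
    for c in candidates:
        ids = raster[c.bbox][c.mask]
        ids = ids[ids > 0]
        label = NON_FAT
        if ids.size:
            counts = np.bincount(ids)
            best = int(np.argmax(counts))
            inter = int(counts[best])
            obj = by_id[best]
            union = int(c.mask.sum()) + obj.area_px - inter
            if obj.cls == "fat" and inter / union >= iou_min:
                label = FAT
        labels.append(label)
    origin = [f"candidate:{c.id}" for c in candidates]
    return TrainingSet(feats, np.array(labels), origin)
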