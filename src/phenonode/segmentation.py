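"""Decision-tree pixel segmentation into stem / leaf / background.

A CART classifier over the 15 color features assigns every pixel one of
three classes.  The fitted tree is snapshotted into plain arrays so it
can be persisted as JSON and applied with pure numpy, independent of the
training library.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from phenonode.color_features import N_FEATURES, image_color_features

# Class codes; also the palette of label-mask PNGs.
BACKGROUND = 0
STEM = 1
LEAF = 2

CLASS_NAMES = {BACKGROUND: "background", STEM: "stem", LEAF: "leaf"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class SegmentationTree:
    """Axis-aligned binary decision tree with Gini splits.

    Arrays follow the usual flat layout: element ``i`` describes node
    ``i``; ``children_left[i] == -1`` marks a leaf carrying class
    ``leaf_class[i]``.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray
    classes: list = field(default_factory=list)

    def __post_init__(self):
        internal = self.children_left >= 0
        feats = self.feature[internal]
        if feats.size and (feats.min() < 0 or feats.max() >= N_FEATURES):
            raise ValueError("internal node references an invalid feature index")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class code for each row of an (n, 15) feature matrix."""
        X = np.asarray(X, dtype=np.float64)
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.children_left[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] >= 0
        return self.leaf_class[node]

    def to_json(self, path) -> None:
        payload = {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "classes": [int(c) for c in self.classes],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SegmentationTree":
        d = json.loads(Path(path).read_text())
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.int64),
            classes=d["classes"],
        )


def train_dtsm(
    features: np.ndarray,
    labels: np.ndarray,
    max_depth: int = 10,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> SegmentationTree:
    """Fit the segmentation tree on labeled pixels.

    Parameters
    ----------
    features : (n, 15) color feature matrix
    labels : (n,) class codes in {0 background, 1 stem, 2 leaf}
    max_depth, min_samples_leaf : CART stopping rules (Gini impurity)
    seed : tie-break seed for equal-gain splits
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.size == 0 or labels.size == 0:
        raise ValueError("empty training set")
    if features.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {features.shape[1]}")
    if np.unique(labels).size < 2:
        warnings.warn("single-class training set: degenerate single-leaf tree", stacklevel=2)
    clf = DecisionTreeClassifier(
        criterion="gini",
        max_depth=max_depth,
        min_samples_leaf=min_samples_leaf,
        random_state=seed,
    )
    clf.fit(features, labels)
    t = clf.tree_
    leaf_class = clf.classes_[np.argmax(t.value[:, 0, :], axis=1)]
    return SegmentationTree(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        leaf_class=leaf_class.astype(np.int64),
        classes=[int(c) for c in clf.classes_],
    )


def segment(tree: SegmentationTree, image: np.ndarray) -> np.ndarray:
    """Per-pixel class map for an RGB image; same height/width as the image."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    feats = image_color_features(image)
    h, w, _ = feats.shape
    pred = tree.predict(feats.reshape(-1, N_FEATURES))
    return pred.reshape(h, w).astype(np.uint8)


def extract_stem_mask(class_map: np.ndarray) -> np.ndarray:
    """Binary mask that is 1 exactly where the class map says stem."""
    return (np.asarray(class_map) == STEM).astype(np.uint8)
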