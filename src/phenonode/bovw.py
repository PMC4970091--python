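"""Bag-of-visual-words classification of candidate node patches.

Each surviving candidate is judged from the 40x40 grayscale patch
centered on it: Harris corners give keypoints, a 128-dimensional
gradient-orientation descriptor is computed at each keypoint at a fixed
scale, descriptors are quantized against a k-means vocabulary (k=10)
into an L1-normalized word histogram, and a random forest decides node
vs non-node.  A patch with no keypoints is declared non-node outright —
bare stem and background are nearly textureless, true node regions are
corner-rich.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import corner_peaks, structure_tensor
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from phenonode.skeleton import Candidate, STATUS_ACCEPTED, STATUS_REMOVED_BOVW

PATCH_SIZE = 40
DESCRIPTOR_DIM = 128
NODE = "node"
NON_NODE = "non_node"

# Harris settings: Gaussian integration window sigma=1, Harris k=0.04,
# keypoints are local maxima above 0.01 x the max response.
HARRIS_SIGMA = 1.0
HARRIS_K = 0.04
HARRIS_REL_THRESHOLD = 0.01

# Descriptor support: 4x4 spatial cells of `_CELL` px, 8 orientation bins,
# fixed orientation 0 (patches are upright crops, no dominant-orientation
# normalization) and fixed scale (cell width 4 px).
_CELL = 4
_GRID = 4
_N_ORI = 8
_CLIP = 0.2


def extract_patch(image: np.ndarray, center: tuple[int, int], size: int = PATCH_SIZE) -> np.ndarray:
    """Square crop centered at (x, y); out-of-bounds filled by edge replication."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    x, y = center
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"patch center {(x, y)} outside image of shape {(h, w)}")
    half = size // 2
    pad = [(half, half), (half, half)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="edge")
    return padded[y : y + size, x : x + size]


def to_gray(patch: np.ndarray) -> np.ndarray:
    """Float grayscale in [0, 1] from uint8 RGB or grayscale input."""
    patch = np.asarray(patch)
    if patch.ndim == 3:
        patch = 0.299 * patch[..., 0] + 0.587 * patch[..., 1] + 0.114 * patch[..., 2]
    patch = patch.astype(np.float64)
    if patch.max() > 1.0:
        patch = patch / 255.0
    return patch


def harris_response(gray: np.ndarray) -> np.ndarray:
    """Harris corner response det(A) - k tr(A)^2 from the structure tensor.

    Edge-replicating boundary handling, so constant patches score zero
    everywhere instead of sprouting phantom border corners.
    """
    arr, arc, acc = structure_tensor(gray, sigma=HARRIS_SIGMA, mode="nearest", order="rc")
    return arr * acc - arc**2 - HARRIS_K * (arr + acc) ** 2


def detect_keypoints(patch: np.ndarray) -> np.ndarray:
    """Harris corner keypoints as an (n, 2) array of (x, y); may be empty."""
    gray = to_gray(patch)
    response = harris_response(gray)
    if response.max() <= 0:
        return np.empty((0, 2), dtype=np.int64)
    peaks = corner_peaks(
        response,
        min_distance=1,
        threshold_rel=HARRIS_REL_THRESHOLD,
        threshold_abs=0.0,
    )
    if peaks.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return peaks[:, ::-1].copy()  # (row, col) -> (x, y)


def describe(patch: np.ndarray, keypoints: np.ndarray) -> np.ndarray:
    """128-dim gradient-orientation descriptors at the given keypoints.

    The classic 4x4-cell x 8-orientation-bin layout with Gaussian spatial
    weighting, clipping at 0.2 and renormalization, computed at a single
    fixed scale and orientation.
    """
    keypoints = np.asarray(keypoints)
    if keypoints.size == 0:
        return np.empty((0, DESCRIPTOR_DIM), dtype=np.float64)
    gray = to_gray(patch)
    half = _CELL * _GRID // 2  # 8 px support radius
    padded = np.pad(gray, half + 1, mode="edge")
    gy, gx = np.gradient(padded)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), 2 * np.pi)

    # Gaussian spatial weight over the 16x16 support.
    coords = np.arange(2 * half) - (half - 0.5)
    wy, wx = np.meshgrid(coords, coords, indexing="ij")
    weight = np.exp(-(wx**2 + wy**2) / (2 * (half) ** 2))

    descs = np.zeros((len(keypoints), DESCRIPTOR_DIM), dtype=np.float64)
    cell_idx = (np.arange(2 * half) // _CELL)
    cy_idx, cx_idx = np.meshgrid(cell_idx, cell_idx, indexing="ij")
    for i, (x, y) in enumerate(keypoints):
        r0 = int(y) + 1  # padded offset minus half support
        c0 = int(x) + 1
        m = mag[r0 : r0 + 2 * half, c0 : c0 + 2 * half] * weight
        o = ori[r0 : r0 + 2 * half, c0 : c0 + 2 * half]
        obin = np.minimum((o / (2 * np.pi) * _N_ORI).astype(int), _N_ORI - 1)
        flat_bin = (cy_idx * _GRID + cx_idx) * _N_ORI + obin
        hist = np.bincount(flat_bin.ravel(), weights=m.ravel(), minlength=DESCRIPTOR_DIM)
        norm = np.linalg.norm(hist)
        if norm > 0:
            hist = np.minimum(hist / norm, _CLIP)
            norm2 = np.linalg.norm(hist)
            if norm2 > 0:
                hist = hist / norm2
        descs[i] = hist
    return descs


@dataclass
class VisualVocabulary:
    """k-means centroids in descriptor space (the visual words)."""

    centroids: np.ndarray
    inertia: float
    seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "seed": self.seed,
        }))

    @classmethod
    def from_json(cls, path) -> "VisualVocabulary":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["centroids"], dtype=np.float64), d["inertia"], d["seed"])


def build_vocabulary(descriptors: np.ndarray, k: int = 10, seed: int = 0) -> VisualVocabulary:
    """Quantize descriptor space with k-means (k-means++ init, 10 restarts)."""
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if descriptors.shape[0] < k:
        raise ValueError(f"need at least k={k} descriptors, got {descriptors.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    km.fit(descriptors)
    return VisualVocabulary(
        centroids=km.cluster_centers_.copy(), inertia=float(km.inertia_), seed=seed
    )


def encode(descriptors: np.ndarray, vocab: VisualVocabulary) -> tuple[np.ndarray, bool]:
    """L1-normalized word histogram; (zeros, empty=True) when no descriptors.

    Each descriptor goes to its nearest centroid in Euclidean distance;
    ties resolve to the lowest centroid index.
    """
    descriptors = np.asarray(descriptors, dtype=np.float64)
    hist = np.zeros(vocab.k, dtype=np.float64)
    if descriptors.shape[0] == 0:
        return hist, True
    d2 = ((descriptors[:, None, :] - vocab.centroids[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    counts = np.bincount(assign, minlength=vocab.k).astype(np.float64)
    return counts / counts.sum(), False


@dataclass
class PatchClassifier:
    forest: RandomForestClassifier
    oob_score: float | None
    seed: int

    def predict(self, histograms: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.atleast_2d(histograms))


def train_patch_classifier(
    histograms: np.ndarray,
    labels,
    n_trees: int = 500,
    seed: int = 0,
) -> PatchClassifier:
    """Fit the node / non-node random forest on word histograms."""
    histograms = np.asarray(histograms, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("patch classifier needs both node and non-node examples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB on tiny sets warns about missing votes
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=seed,
        )
        forest.fit(histograms, labels)
        oob = float(forest.oob_score_)
    return PatchClassifier(forest=forest, oob_score=oob, seed=seed)


def classify_candidate(
    image: np.ndarray,
    candidate: Candidate,
    vocab: VisualVocabulary,
    classifier: PatchClassifier,
    patch_size: int = PATCH_SIZE,
) -> str:
    """Run the patch pipeline for one active candidate and set its status.

    Empty-keypoint patches are non-node without consulting the forest.
    Accepted candidates keep the candidate pixel as the detection
    location (the patch's center of gravity).
    """
    if candidate.status != "active":
        raise ValueError(f"candidate has status {candidate.status!r}, expected active")
    patch = extract_patch(image, (candidate.x, candidate.y), size=patch_size)
    keypoints = detect_keypoints(patch)
    descs = describe(patch, keypoints)
    hist, empty = encode(descs, vocab)
    if empty:
        candidate.transition(STATUS_REMOVED_BOVW, "no keypoints in patch")
        return NON_NODE
    label = classifier.predict(hist[None, :])[0]
    if label == NODE:
        candidate.transition(STATUS_ACCEPTED, "bovw classified node")
        return NODE
    candidate.transition(STATUS_REMOVED_BOVW, "bovw classified non-node")
    return NON_NODE
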