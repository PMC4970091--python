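"""Skeletonization of the stem mask and branch/cross-point candidates.

Thinning reduces the stem silhouette to a one-pixel-wide,
topology-preserving skeleton; pixels with three or more skeleton
8-neighbors are junctions (branch or cross points) and become candidate
node locations.  Thinning can emit small clusters of adjacent junction
pixels at one anatomical junction, so touching junction pixels are
merged to their rounded centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

STATUS_ACTIVE = "active"
STATUS_REMOVED_MAINSTEM = "removed_mainstem"
STATUS_REMOVED_BOVW = "removed_bovw"
STATUS_ACCEPTED = "accepted"

_FORWARD = {
    STATUS_ACTIVE: {STATUS_REMOVED_MAINSTEM, STATUS_REMOVED_BOVW, STATUS_ACCEPTED},
}


@dataclass
class Candidate:
    """One candidate node pixel with its keep/remove audit trail."""

    x: int
    y: int
    status: str = STATUS_ACTIVE
    reason: str = ""

    def transition(self, status: str, reason: str = "") -> None:
        if status not in _FORWARD.get(self.status, set()):
            raise ValueError(f"illegal status transition {self.status} -> {status}")
        self.status = status
        self.reason = reason


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide skeleton (Zhang–Suen scheme)."""
    mask = np.asarray(mask).astype(bool)
    if mask.size == 0 or not mask.any():
        return np.zeros_like(mask, dtype=np.uint8)
    return _skimage_skeletonize(mask, method="zhang").astype(np.uint8)


def neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Foreground 8-neighbor count at every pixel of a binary skeleton."""
    skel = np.asarray(skel).astype(np.uint8)
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    return ndimage.convolve(skel, kernel, mode="constant", cval=0)


def find_branch_points(skel: np.ndarray, merge_adjacent: bool = True) -> list[Candidate]:
    """Junction pixels (>=3 skeleton 8-neighbors) as active candidates.

    With ``merge_adjacent`` (default), 8-connected clusters of junction
    pixels collapse to one candidate at their rounded centroid.
    """
    skel = np.asarray(skel).astype(bool)
    junction = skel & (neighbor_counts(skel) >= 3)
    if not junction.any():
        return []
    if not merge_adjacent:
        ys, xs = np.nonzero(junction)
        return [Candidate(x=int(x), y=int(y)) for y, x in zip(ys, xs)]
    labels, n = ndimage.label(junction, structure=np.ones((3, 3), dtype=int))
    cands = []
    for cy, cx in ndimage.center_of_mass(junction, labels, range(1, n + 1)):
        cands.append(Candidate(x=int(round(cx)), y=int(round(cy))))
    cands.sort(key=lambda c: (c.y, c.x))
    return cands
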