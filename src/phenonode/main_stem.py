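"""Main-stem line fit and distance-based candidate filtering.

The tallest connected stem component is summarized by an ordinary
least-squares line x(y) = a*y + b (x regressed on y, since the stem is
near-vertical), and candidates whose horizontal distance from the line
at their own row exceeds a fixed threshold (default 50 px) are removed
as off-stem false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from phenonode.skeleton import Candidate, STATUS_REMOVED_MAINSTEM


@dataclass
class MainStemLine:
    """x(y) = slope * y + intercept over the main stem component."""

    slope: float
    intercept: float
    r_squared: float

    def x_at(self, y) -> float:
        return self.slope * np.asarray(y, dtype=float) + self.intercept


@dataclass
class MainStemConfig:
    distance_threshold_px: float = 50.0

    def __post_init__(self):
        if self.distance_threshold_px <= 0:
            raise ValueError("distance threshold must be positive")


def select_main_component(mask: np.ndarray) -> np.ndarray:
    """Connected component (8-connectivity) spanning the most rows.

    Ties on bounding-box height break toward the larger pixel area.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("no stem found: mask is empty")
    labeled = label(mask, connectivity=2)
    best = max(
        regionprops(labeled),
        key=lambda r: (r.bbox[2] - r.bbox[0], r.area),
    )
    return (labeled == best.label).astype(np.uint8)


def fit_main_stem_line(component: np.ndarray) -> MainStemLine:
    """OLS of x on y over all foreground pixels of the component."""
    ys, xs = np.nonzero(np.asarray(component))
    if ys.size < 2:
        raise ValueError("need at least 2 pixels to fit the main stem line")
    if np.unique(ys).size < 2:
        raise ValueError("all pixels on one row: stem cannot be horizontal")
    y = ys.astype(float)
    x = xs.astype(float)
    slope, intercept = np.polyfit(y, x, 1)
    resid = x - (slope * y + intercept)
    ss_tot = np.sum((x - x.mean()) ** 2)
    # Perfectly vertical stem: zero x variance, fit is exact.
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return MainStemLine(slope=float(slope), intercept=float(intercept), r_squared=float(r2))


def filter_by_main_stem(
    candidates: list[Candidate],
    line: MainStemLine,
    config: MainStemConfig | None = None,
) -> list[Candidate]:
    """Remove candidates farther than the threshold from the line.

    Distance is horizontal, measured at the candidate's row; the
    threshold is inclusive (distance exactly at the threshold keeps the
    candidate).  Statuses are updated in place and the same list is
    returned.
    """
    config = config or MainStemConfig()
    for cand in candidates:
        if cand.status != "active":
            continue
        dist = abs(cand.x - line.x_at(cand.y))
        if dist > config.distance_threshold_px:
            cand.transition(
                STATUS_REMOVED_MAINSTEM,
                f"horizontal distance {dist:.1f} px > {config.distance_threshold_px:g} px",
            )
    return candidates
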