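"""Internode lengths from adjacent node lines, in pixels and mm.

The internode between orders i and i+1 at time t is the vertical
distance between their node lines, y_i(t) - y_{i+1}(t) (order i sits
lower, so larger y).  The series for a pair starts only once node i+1
has appeared — its cluster's earliest detection timestamp.  Pixel
lengths convert to millimetres with a rig calibration factor
(default 0.41 mm/px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from phenonode.node_order import NodeLine, node_y_at


@dataclass
class ScaleConfig:
    mm_per_px: float = 0.41

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


@dataclass
class InternodeSeries:
    pair: tuple[int, int]  # (i, i+1) node orders
    timestamps: list[float]
    lengths_px: list[float]
    lengths_mm: list[float]
    defined_from: float  # appearance time of node i+1

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.lengths_mm))


def internode_length_px(lines: list[NodeLine], i: int, t: float) -> float:
    """Vertical distance in px between node lines i and i+1 at time t.

    Requires t at or after the appearance of node i+1; a negative value
    means the fitted lines cross at t (warned, returned as-is).
    """
    by_order = {line.order: line for line in lines}
    if i not in by_order or i + 1 not in by_order:
        raise ValueError(f"node lines {i} and {i + 1} must both exist")
    upper = by_order[i + 1]
    if t < upper.appearance_time:
        raise ValueError(
            f"t={t} precedes appearance of node {i + 1} at {upper.appearance_time}"
        )
    length = node_y_at(by_order[i], t) - node_y_at(upper, t)
    if length < 0:
        warnings.warn(f"node lines {i} and {i + 1} cross at t={t}", stacklevel=2)
    return length


def px_to_mm(length_px: float, config: ScaleConfig | None = None) -> float:
    config = config or ScaleConfig()
    return length_px * config.mm_per_px


def internode_series(
    lines: list[NodeLine],
    capture_times,
    config: ScaleConfig | None = None,
) -> list[InternodeSeries]:
    """Per-pair internode length series over the capture times.

    Entries exist only for capture times at or after the appearance of
    the upper node of the pair.
    """
    config = config or ScaleConfig()
    if len(lines) < 2:
        warnings.warn("fewer than 2 node lines: no internodes to measure", stacklevel=2)
        return []
    capture_times = sorted(float(t) for t in capture_times)
    by_order = {line.order: line for line in lines}
    series = []
    for i in range(1, len(lines)):
        upper = by_order[i + 1]
        times = [t for t in capture_times if t >= upper.appearance_time]
        px = [internode_length_px(lines, i, t) for t in times]
        series.append(InternodeSeries(
            pair=(i, i + 1),
            timestamps=times,
            lengths_px=px,
            lengths_mm=[px_to_mm(v, config) for v in px],
            defined_from=upper.appearance_time,
        ))
    return series
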