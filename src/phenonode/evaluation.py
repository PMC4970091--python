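"""Detection and length-estimation metrics, and the cross-validation protocol.

A detection is a true positive when its center of gravity lies inside a
ground-truth node rectangle (boundary inclusive); matching is one-to-one
and greedy by center distance, so a second detection inside an already
matched rectangle counts as a false positive.  Recall = TP/(TP+FN),
precision = TP/(TP+FP).  Internode length estimates are scored by the
relative error of the summed series against the observed series,
|Σ l̂ − Σ l| / Σ l × 100 — equal to the error of the means when the
series lengths match, so summary-table means are valid inputs.
Seedlings are evaluated leave-one-seedling-out: train on one sequence,
test on all the others, rotating the training sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Rect:
    """Axis-aligned ground-truth node region."""

    x_min: float
    y_min: float
    width: float
    height: float
    order: int | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle dimensions must be positive")

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x <= self.x_min + self.width
                and self.y_min <= y <= self.y_min + self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP, self.FN + other.FN)


def greedy_matches(detections, rects: list[Rect]) -> list[tuple[int, int]]:
    """One-to-one (detection, rectangle) matches, closest-center first.

    Only pairs where the detection center lies inside the rectangle are
    eligible; boundary inclusive.
    """
    pairs = []
    for di, (x, y) in enumerate(detections):
        for gi, rect in enumerate(rects):
            if rect.contains(x, y):
                cx, cy = rect.center
                pairs.append((np.hypot(x - cx, y - cy), di, gi))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_d, used_g, matches = set(), set(), []
    for _, di, gi in pairs:
        if di in used_d or gi in used_g:
            continue
        used_d.add(di)
        used_g.add(gi)
        matches.append((di, gi))
    return matches


def match_detections(detections, rects: list[Rect]) -> ConfusionCounts:
    """TP/FP/FN for one frame under one-to-one greedy center matching."""
    matches = greedy_matches(detections, rects)
    tp = len(matches)
    return ConfusionCounts(TP=tp, FP=len(list(detections)) - tp, FN=len(rects) - tp)


def recall(counts: ConfusionCounts) -> float:
    if counts.TP + counts.FN == 0:
        raise ValueError("recall undefined: no ground-truth nodes (TP+FN=0)")
    return counts.TP / (counts.TP + counts.FN)


def precision(counts: ConfusionCounts) -> float:
    if counts.TP + counts.FP == 0:
        raise ValueError("precision undefined: no detections (TP+FP=0)")
    return counts.TP / (counts.TP + counts.FP)


def relative_error(observed, predicted) -> float:
    """Relative error in percent between two length series of equal length."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise ValueError("observed and predicted series must be equal-length, non-empty")
    total = observed.sum()
    if total <= 0:
        raise ValueError("observed series must have positive sum")
    return float(abs(predicted.sum() - total) / total * 100.0)


@dataclass
class FoldResult:
    """Metrics for one cross-validation fold (one training seedling)."""

    train_id: str
    per_seedling: dict = field(default_factory=dict)  # id -> {"overall", "per_order"}

    def overall(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for res in self.per_seedling.values():
            total = total + res["overall"]
        return total


def evaluate_frames(frame_detections, frame_rects) -> tuple[ConfusionCounts, dict]:
    """Aggregate confusion counts over frames, overall and per node order."""
    overall = ConfusionCounts()
    per_order: dict[int, ConfusionCounts] = {}
    for dets, rects in zip(frame_detections, frame_rects):
        matches = greedy_matches(dets, rects)
        matched_g = {gi for _, gi in matches}
        overall = overall + ConfusionCounts(
            TP=len(matches), FP=len(list(dets)) - len(matches), FN=len(rects) - len(matches)
        )
        for gi, rect in enumerate(rects):
            order = rect.order if rect.order is not None else 0
            c = per_order.setdefault(order, ConfusionCounts())
            if gi in matched_g:
                c.TP += 1
            else:
                c.FN += 1
    return overall, per_order


def leave_one_seedling_out(dataset: dict, fold_fn) -> list[FoldResult]:
    """Rotate the training seedling over the dataset.

    ``fold_fn(dataset, train_id, test_ids)`` must return a
    :class:`FoldResult`; with three seedlings each is tested exactly
    twice.
    """
    if len(dataset) < 2:
        raise ValueError("leave-one-seedling-out needs at least 2 seedlings")
    ids = sorted(dataset)
    return [fold_fn(dataset, train_id, [s for s in ids if s != train_id])
            for train_id in ids]


def summarize_folds(folds: list[FoldResult]):
    """Table-shaped summary: per-seedling per-order recall plus All rows.

    Returns a pandas DataFrame with columns
    (seedling, node_order, recall, precision, n_nodes); precision is
    reported on the All rows (false positives carry no node order).
    Percent-like values are rounded to two decimals.
    """
    import pandas as pd

    pooled: dict[str, dict] = {}
    for fold in folds:
        for sid, res in fold.per_seedling.items():
            agg = pooled.setdefault(sid, {"overall": ConfusionCounts(), "per_order": {}})
            agg["overall"] = agg["overall"] + res["overall"]
            for order, c in res["per_order"].items():
                prev = agg["per_order"].setdefault(order, ConfusionCounts())
                prev.TP += c.TP
                prev.FN += c.FN
                prev.FP += c.FP
    rows = []
    grand = ConfusionCounts()
    for sid in sorted(pooled):
        agg = pooled[sid]
        for order in sorted(agg["per_order"]):
            c = agg["per_order"][order]
            rows.append({
                "seedling": sid, "node_order": str(order),
                "recall": round(recall(c), 2), "precision": float("nan"),
                "n_nodes": c.TP + c.FN,
            })
        c = agg["overall"]
        grand = grand + c
        rows.append({
            "seedling": sid, "node_order": "All",
            "recall": round(recall(c), 2),
            "precision": round(precision(c), 2) if c.TP + c.FP else float("nan"),
            "n_nodes": c.TP + c.FN,
        })
    rows.append({
        "seedling": "All", "node_order": "All",
        "recall": round(recall(grand), 2),
        "precision": round(precision(grand), 2) if grand.TP + grand.FP else float("nan"),
        "n_nodes": grand.TP + grand.FN,
    })
    return pd.DataFrame(rows)
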