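"""End-to-end orchestration: train -> detect -> track -> measure -> evaluate.

Detection runs the four-stage funnel per frame (pixel segmentation,
skeleton branch points, main-stem distance filter, bag-of-visual-words
patch classification); tracking pools detections over the sequence,
clusters them into node orders and fits node lines; measurement turns
adjacent node lines into internode length series in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phenonode.bovw import (
    PatchClassifier,
    VisualVocabulary,
    build_vocabulary,
    classify_candidate,
    describe,
    detect_keypoints,
    encode,
    train_patch_classifier,
)
from phenonode.evaluation import (
    FoldResult,
    evaluate_frames,
    leave_one_seedling_out,
    relative_error,
)
from phenonode.internode import InternodeSeries, ScaleConfig, internode_series
from phenonode.main_stem import (
    MainStemConfig,
    filter_by_main_stem,
    fit_main_stem_line,
    select_main_component,
)
from phenonode.node_order import APConfig, cluster_by_y, fit_node_lines
from phenonode.segmentation import SegmentationTree, extract_stem_mask, segment, train_dtsm
from phenonode.skeleton import STATUS_ACCEPTED, STATUS_ACTIVE, find_branch_points, skeletonize_mask
from phenonode.synthetic import SequenceGroundTruth, make_patch_training_set, make_pixel_training_set


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the reference operating point."""

    seg_max_depth: int = 10
    seg_min_samples_leaf: int = 5
    use_mainstem_filter: bool = True
    mainstem_threshold_px: float = 50.0
    use_bovw: bool = True
    patch_size: int = 40
    k: int = 10
    n_trees: int = 500
    damping: float = 0.5
    preference: float | None = None
    mm_per_px: float = 0.41
    seed: int = 0


@dataclass
class Models:
    tree: SegmentationTree
    vocab: VisualVocabulary | None
    classifier: PatchClassifier | None


def train_from_sequence(
    frames: list[np.ndarray],
    gt: SequenceGroundTruth,
    config: PipelineConfig | None = None,
    pixel_counts: dict | None = None,
    n_node_patches: int = 200,
    n_non_node_patches: int = 250,
) -> Models:
    """Fit segmentation tree + BoVW vocabulary/classifier on one sequence."""
    config = config or PipelineConfig()
    feats, labels = make_pixel_training_set(frames, gt, counts=pixel_counts, seed=config.seed)
    tree = train_dtsm(feats, labels, max_depth=config.seg_max_depth,
                      min_samples_leaf=config.seg_min_samples_leaf, seed=config.seed)
    if not config.use_bovw:
        return Models(tree=tree, vocab=None, classifier=None)
    patches, patch_labels = make_patch_training_set(
        frames, gt, n_node=n_node_patches, n_non_node=n_non_node_patches,
        patch_size=config.patch_size, seed=config.seed,
    )
    per_patch_descs = [describe(p, detect_keypoints(p)) for p in patches]
    all_descs = np.concatenate([d for d in per_patch_descs if d.shape[0] > 0])
    vocab = build_vocabulary(all_descs, k=config.k, seed=config.seed)
    hists = np.stack([encode(d, vocab)[0] for d in per_patch_descs])
    clf = train_patch_classifier(hists, patch_labels, n_trees=config.n_trees, seed=config.seed)
    return Models(tree=tree, vocab=vocab, classifier=clf)


def detect_frame(
    image: np.ndarray,
    models: Models,
    config: PipelineConfig | None = None,
):
    """Run the detection funnel on one frame.

    Returns (detections, candidates, stage_counts) where detections is a
    list of (x, y) and stage_counts logs the per-stage funnel.
    """
    config = config or PipelineConfig()
    class_map = segment(models.tree, image)
    stem_mask = extract_stem_mask(class_map)
    if stem_mask.sum() == 0:
        raise ValueError("no stem pixels in frame")
    skel = skeletonize_mask(stem_mask)
    candidates = find_branch_points(skel)
    counts = {"candidates": len(candidates)}

    if config.use_mainstem_filter:
        component = select_main_component(stem_mask)
        line = fit_main_stem_line(component)
        filter_by_main_stem(candidates, line,
                            MainStemConfig(distance_threshold_px=config.mainstem_threshold_px))
    counts["after_mainstem"] = sum(c.status == STATUS_ACTIVE for c in candidates)

    if config.use_bovw:
        if models.vocab is None or models.classifier is None:
            raise ValueError("BoVW stage enabled but models missing")
        for cand in candidates:
            if cand.status == STATUS_ACTIVE:
                classify_candidate(image, cand, models.vocab, models.classifier,
                                   patch_size=config.patch_size)
        accepted = [c for c in candidates if c.status == STATUS_ACCEPTED]
    else:
        accepted = [c for c in candidates if c.status == STATUS_ACTIVE]
    counts["accepted"] = len(accepted)
    return [(c.x, c.y) for c in accepted], candidates, counts


def run_detection(
    frames: list[np.ndarray],
    timestamps: list[float],
    models: Models,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Detect nodes in every frame; one row per accepted detection.

    Frames with no stem pixels are skipped with a warning.
    """
    config = config or PipelineConfig()
    rows, funnel = [], []
    for frame_id, (image, t) in enumerate(zip(frames, timestamps)):
        try:
            detections, _, counts = detect_frame(image, models, config)
        except ValueError as exc:
            warnings.warn(f"frame {frame_id} skipped: {exc}", stacklevel=2)
            funnel.append({"frame_id": frame_id, "skipped": True})
            continue
        counts["frame_id"] = frame_id
        funnel.append(counts)
        for x, y in detections:
            rows.append({"frame_id": frame_id, "timestamp": float(t), "x": x, "y": y})
    df = pd.DataFrame(rows, columns=["frame_id", "timestamp", "x", "y"])
    return df, funnel


def run_tracking_and_measurement(
    detections: pd.DataFrame,
    config: PipelineConfig | None = None,
):
    """Cluster detections into node orders, fit node lines, measure internodes.

    Returns (node_lines, clustering, internode series list).  The result
    is invariant to the row order of the detections table.
    """
    config = config or PipelineConfig()
    if len(detections) == 0:
        raise ValueError("no detections to track")
    det = detections.sort_values(["timestamp", "y", "x"], kind="mergesort").reset_index(drop=True)
    y = det["y"].to_numpy(dtype=float)
    t = det["timestamp"].to_numpy(dtype=float)
    clustering = cluster_by_y(y, APConfig(damping=config.damping, preference=config.preference))
    lines = fit_node_lines(t, y, clustering)
    series = internode_series(lines, sorted(set(t)), ScaleConfig(mm_per_px=config.mm_per_px))
    return lines, clustering, series


def node_lines_frame(lines) -> pd.DataFrame:
    return pd.DataFrame([
        {"order": ln.order, "slope": ln.slope, "intercept": ln.intercept,
         "appearance_time": ln.appearance_time, "n_members": ln.n_members}
        for ln in lines
    ])


def internode_frame(series: list[InternodeSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, px, mm in zip(s.timestamps, s.lengths_px, s.lengths_mm):
            rows.append({"pair": f"{s.pair[0]}-{s.pair[1]}", "timestamp": t,
                         "length_px": px, "length_mm": mm})
    return pd.DataFrame(rows, columns=["pair", "timestamp", "length_px", "length_mm"])


def internode_summary(series: list[InternodeSeries]) -> pd.DataFrame:
    return pd.DataFrame([
        {"pair": f"{s.pair[0]}-{s.pair[1]}", "mean_mm": round(s.mean_mm, 1),
         "n_times": len(s.timestamps)}
        for s in series
    ])


def detection_fold(dataset: dict, train_id: str, test_ids: list[str],
                   config: PipelineConfig | None = None) -> FoldResult:
    """One cross-validation fold: train on one seedling, test on the rest."""
    config = config or PipelineConfig()
    frames, gt = dataset[train_id]
    models = train_from_sequence(frames, gt, config)
    result = FoldResult(train_id=train_id)
    for sid in test_ids:
        t_frames, t_gt = dataset[sid]
        det, _ = run_detection(t_frames, t_gt.timestamps, models, config)
        per_frame_dets = [
            list(zip(det[det.frame_id == i].x, det[det.frame_id == i].y))
            for i in range(len(t_frames))
        ]
        rects = [fgt.rects for fgt in t_gt.frames]
        overall, per_order = evaluate_frames(per_frame_dets, rects)
        result.per_seedling[sid] = {
            "overall": overall,
            "per_order": per_order,
            "detections": det,
        }
    return result


def internode_errors(detections: pd.DataFrame, gt: SequenceGroundTruth,
                     config: PipelineConfig | None = None) -> dict:
    """Per-pair relative error (%) of estimated vs ground-truth internodes.

    Estimated series come from tracking the detections; observed series
    are the generator's exact lengths at the same capture times.  Pairs
    are matched by node order.
    """
    config = config or PipelineConfig()
    lines, _, series = run_tracking_and_measurement(detections, config)
    time_index = {t: i for i, t in enumerate(gt.timestamps)}
    errors = {}
    for s in series:
        observed, predicted = [], []
        for t, mm in zip(s.timestamps, s.lengths_mm):
            fgt = gt.frames[time_index[t]]
            if s.pair in fgt.internode_mm:
                observed.append(fgt.internode_mm[s.pair])
                predicted.append(mm)
        if observed:
            errors[s.pair] = relative_error(observed, predicted)
    return errors


def cross_validate(dataset: dict, config: PipelineConfig | None = None):
    """Leave-one-seedling-out over the dataset.

    Returns (fold results, internode relative errors keyed by
    (train_id, test_id, pair)).
    """
    config = config or PipelineConfig()
    folds = leave_one_seedling_out(
        dataset, lambda ds, tr, te: detection_fold(ds, tr, te, config)
    )
    errors = {}
    for fold in folds:
        for sid, res in fold.per_seedling.items():
            if len(res["detections"]) == 0:
                continue
            _, gt = dataset[sid]
            for pair, err in internode_errors(res["detections"], gt, config).items():
                errors[(fold.train_id, sid, pair)] = err
    return folds, errors
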