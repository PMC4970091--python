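"""On-disk formats: frames, manifests, ground truth, model bundles."""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from phenonode.bovw import PatchClassifier, VisualVocabulary
from phenonode.evaluation import Rect
from phenonode.segmentation import SegmentationTree
from phenonode.synthetic import FrameGroundTruth, SequenceGroundTruth


def write_sequence(out_dir, frames, gt: SequenceGroundTruth) -> None:
    """Frames as PNG, manifest CSV (frame_id, timestamp, path), GT as JSON
    plus palette class-map PNGs (0=background, 1=stem, 2=leaf)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    gt_frames = []
    for i, (frame, fgt, t) in enumerate(zip(frames, gt.frames, gt.timestamps)):
        name = f"frame_{i:04d}.png"
        Image.fromarray(frame).save(out / name)
        Image.fromarray(fgt.class_map).save(out / f"class_map_{i:04d}.png")
        rows.append({"frame_id": i, "timestamp": t, "path": name})
        gt_frames.append({
            "frame_id": i,
            "timestamp": t,
            "rectangles": [
                {"x_min": r.x_min, "y_min": r.y_min, "width": r.width,
                 "height": r.height, "order": r.order}
                for r in fgt.rects
            ],
            "nodes": [[x, y, o] for x, y, o in fgt.nodes],
            "internode_mm": {f"{i0}-{i1}": v for (i0, i1), v in fgt.internode_mm.items()},
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(
        {"mm_per_px": gt.mm_per_px, "frames": gt_frames}, indent=1))


def read_sequence(data_dir):
    """Load (frames, timestamps, ground truth or None) from a sequence dir."""
    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.csv").sort_values("frame_id")
    frames = [np.asarray(Image.open(data / p).convert("RGB")) for p in manifest["path"]]
    timestamps = manifest["timestamp"].tolist()
    gt = None
    gt_path = data / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        gt_frames = []
        for i, f in enumerate(payload["frames"]):
            cm_path = data / f"class_map_{i:04d}.png"
            cm = np.asarray(Image.open(cm_path)) if cm_path.exists() else None
            gt_frames.append(FrameGroundTruth(
                class_map=cm,
                nodes=[tuple(n) for n in f.get("nodes", [])],
                rects=[Rect(**r) for r in f["rectangles"]],
                internode_mm={
                    tuple(int(v) for v in k.split("-")): val
                    for k, val in f.get("internode_mm", {}).items()
                },
            ))
        gt = SequenceGroundTruth(timestamps=timestamps, frames=gt_frames,
                                 mm_per_px=payload.get("mm_per_px", 0.41))
    return frames, timestamps, gt


def save_models(model_dir, models) -> None:
    out = Path(model_dir)
    out.mkdir(parents=True, exist_ok=True)
    models.tree.to_json(out / "segmentation_tree.json")
    if models.vocab is not None:
        models.vocab.to_json(out / "vocabulary.json")
    if models.classifier is not None:
        (out / "patch_classifier.pkl").write_bytes(pickle.dumps(models.classifier))


def load_models(model_dir):
    from phenonode.pipeline import Models

    d = Path(model_dir)
    tree = SegmentationTree.from_json(d / "segmentation_tree.json")
    vocab = clf = None
    if (d / "vocabulary.json").exists():
        vocab = VisualVocabulary.from_json(d / "vocabulary.json")
    if (d / "patch_classifier.pkl").exists():
        clf = pickle.loads((d / "patch_classifier.pkl").read_bytes())
    return Models(tree=tree, vocab=vocab, classifier=clf)
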