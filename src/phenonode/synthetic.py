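"""Synthetic seedling image sequences with exact ground truth.

Renders a time series of a single young seedling: a near-vertical stem
band whose internodes elongate linearly in time, nodes as stem/petiole
junctions with a textured leaf blob attached (so corner detectors have
signal), and class-separable color distributions for stem, leaf and
background.  Capture times follow a nightly cadence (five captures per
night by default).  Every frame comes with its exact class map, node
centers with orders, ground-truth rectangles and per-pair internode
lengths in mm, so each pipeline stage can be validated without any
external imagery.

The generator deliberately keeps growth linear in time, which makes the
downstream per-order linear node-line model exactly correct on clean
renders; a curvature knob bends the stem for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, line

from phenonode.color_features import image_color_features
from phenonode.evaluation import Rect
from phenonode.segmentation import BACKGROUND, LEAF, STEM

_DAY = 86400.0


def nightly_timestamps(
    start: float = 1404936000.0,  # 2014-07-09 20:00 UTC
    nights: int = 8,
    per_night: int = 5,
    hours_between: float = 2.0,
) -> list[float]:
    """Capture times: ``per_night`` shots per night at fixed intervals."""
    times = []
    for night in range(nights):
        t0 = start + night * _DAY
        times.extend(t0 + i * hours_between * 3600.0 for i in range(per_night))
    return times


@dataclass
class SeedlingSpec:
    """Everything that defines one rendered seedling sequence."""

    width: int = 640
    height: int = 480
    timestamps: list[float] = field(default_factory=nightly_timestamps)
    n_nodes: int = 4
    initial_lengths_mm: list[float] | None = None  # per internode, at appearance
    elongation_rates_mm_per_day: list[float] | None = None
    appearance_times: list[float] | None = None  # per node; default: last node late
    stem_tilt: float = 5.0  # px of x-drift per 100 px of y
    curvature: float = 0.0  # px per (100 px)^2, bends the stem; 0 = straight
    stem_width: int = 6
    petiole_length: float = 20.0
    leaf_radius: int = 22
    texture_amplitude: float = 60.0
    color_means: dict = field(default_factory=lambda: {
        STEM: (150, 180, 110),
        LEAF: (40, 110, 45),
        BACKGROUND: (195, 193, 205),
    })
    color_sigma: float = 8.0
    base_y_margin: int = 30
    base_internode_px: float = 60.0
    apex_extension_px: float = 25.0
    cotyledons: bool = False
    mm_per_px: float = 0.41
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        n_inter = self.n_nodes - 1
        # Older (lower) internodes are longer and near-mature, younger ones
        # shorter and still elongating; sustained fast elongation of every
        # internode at once smears the y-tracks and is not what a seedling
        # past peak elongation does.
        if self.initial_lengths_mm is None:
            self.initial_lengths_mm = [max(10.0, 32.0 - 6.0 * i) for i in range(n_inter)]
        if self.elongation_rates_mm_per_day is None:
            self.elongation_rates_mm_per_day = [0.4 + 0.2 * i for i in range(n_inter)]
        if len(self.initial_lengths_mm) != n_inter:
            raise ValueError("need one initial length per internode")
        if len(self.elongation_rates_mm_per_day) != n_inter:
            raise ValueError("need one elongation rate per internode")
        if any(r < 0 for r in self.elongation_rates_mm_per_day):
            raise ValueError("elongation rates must be >= 0")
        if self.appearance_times is None:
            t0, t_end = self.timestamps[0], self.timestamps[-1]
            times = [t0] * self.n_nodes
            # The youngest node emerges partway through the sequence so the
            # appearance-gating of its internode is exercised.
            times[-1] = t0 + 0.4 * (t_end - t0)
            self.appearance_times = times
        if len(self.appearance_times) != self.n_nodes:
            raise ValueError("need one appearance time per node")


@dataclass
class FrameGroundTruth:
    class_map: np.ndarray  # (H, W) uint8 of class codes
    nodes: list[tuple[float, float, int]]  # (x, y, order), order 1 lowest
    rects: list[Rect]
    internode_mm: dict  # (i, i+1) -> exact mm length


@dataclass
class SequenceGroundTruth:
    timestamps: list[float]
    frames: list[FrameGroundTruth]
    mm_per_px: float


def _internode_mm(spec: SeedlingSpec, i: int, t: float) -> float:
    """Exact mm length of internode (i, i+1) at time t (1-based orders)."""
    appear = spec.appearance_times[i]  # node i+1, 0-based index i
    dt_days = max(0.0, t - appear) / _DAY
    return spec.initial_lengths_mm[i - 1] + spec.elongation_rates_mm_per_day[i - 1] * dt_days


def node_positions(spec: SeedlingSpec, t: float) -> list[tuple[float, float, int]]:
    """(x, y, order) of every node present at time t."""
    base_y = spec.height - spec.base_y_margin
    base_x = spec.width / 2.0

    def stem_x(y: float) -> float:
        rise = (base_y - y) / 100.0
        return base_x + spec.stem_tilt * rise + spec.curvature * rise**2

    present = [k for k in range(spec.n_nodes) if spec.appearance_times[k] <= t]
    nodes = []
    y = base_y - spec.base_internode_px
    for k in present:
        order = k + 1
        if k > 0:
            y -= _internode_mm(spec, k, t) / spec.mm_per_px
        nodes.append((stem_x(y), y, order))
    return nodes


def _draw_line_thick(canvas, r0, c0, r1, c1, width, value):
    rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    h, w = canvas.shape
    half = max(1, width // 2)
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            r = np.clip(rr + dr, 0, h - 1)
            c = np.clip(cc + dc, 0, w - 1)
            canvas[r, c] = value


def _render_label_map(spec: SeedlingSpec, t: float) -> tuple[np.ndarray, FrameGroundTruth, np.random.Generator]:
    h, w = spec.height, spec.width
    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    nodes = node_positions(spec, t)
    if not nodes:
        raise ValueError("no nodes present at requested time")
    top_y = min(y for _, y, _ in nodes) - spec.apex_extension_px
    if top_y < 5:
        raise ValueError("spec outgrows canvas")

    base_y = h - spec.base_y_margin
    base_x = w / 2.0

    def stem_x(y: float) -> float:
        rise = (base_y - y) / 100.0
        return base_x + spec.stem_tilt * rise + spec.curvature * rise**2

    # Leaves go down first; petioles and the stem band are drawn on top so
    # the stem mask keeps a petiole branch at every node (the leaf blade
    # otherwise swallows the petiole and no skeleton junction forms).
    petioles = []  # (y0, x0, y1, x1, width)
    leaf_centers = []
    for x, y, order in nodes:
        side = -1 if order % 2 == 1 else 1
        px = x + side * spec.petiole_length
        py = y - 0.55 * spec.petiole_length
        petioles.append((y, x, py, px, 3))
        leaf_centers.append((py, px))
    if spec.cotyledons:
        cy = base_y - spec.base_internode_px * 0.45
        for side in (-1, 1):
            cx = stem_x(cy)
            px = cx + side * spec.petiole_length * 0.8
            py = cy - 3
            petioles.append((cy, cx, py, px, 2))
            leaf_centers.append((py, px))
    for (py, px) in leaf_centers:
        rr, cc = disk((py, px), spec.leaf_radius, shape=labels.shape)
        labels[rr, cc] = LEAF
    for (y0, x0, y1, x1, width) in petioles:
        _draw_line_thick(labels, y0, x0, y1, x1, width, STEM)

    # Stem band, one row at a time from base to a little above the top node.
    half_w = spec.stem_width // 2
    for y in range(int(round(top_y)), int(round(base_y)) + 1):
        cx = int(round(stem_x(y)))
        labels[y, max(0, cx - half_w): min(w, cx + half_w + 1)] = STEM

    rng = np.random.default_rng(spec.seed)  # reseeded per frame by caller
    rects = []
    internode = {}
    for x, y, order in nodes:
        rects.append(Rect(x_min=x - 20, y_min=y - 20, width=40, height=40, order=order))
    orders = sorted(o for _, _, o in nodes)
    for o in orders:
        if o + 1 in orders:
            internode[(o, o + 1)] = _internode_mm(spec, o, t)
    gt = FrameGroundTruth(class_map=labels, nodes=nodes, rects=rects, internode_mm=internode)
    return labels, gt, rng


def _colorize(labels: np.ndarray, spec: SeedlingSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = labels.shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    for cls, mean in spec.color_means.items():
        img[labels == cls] = mean
    img += rng.normal(0.0, spec.color_sigma, size=img.shape)
    # High-frequency texture on leaves gives the corner detector signal.
    leaf = labels == LEAF
    img[leaf] += rng.uniform(-spec.texture_amplitude, spec.texture_amplitude,
                             size=(int(leaf.sum()), 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def render_sequence(spec: SeedlingSpec) -> tuple[list[np.ndarray], SequenceGroundTruth]:
    """Render all frames of the sequence; deterministic for a given seed."""
    frames = []
    gts = []
    for idx, t in enumerate(spec.timestamps):
        labels, gt, _ = _render_label_map(spec, t)
        rng = np.random.default_rng((spec.seed, idx))
        frames.append(_colorize(labels, spec, rng))
        gts.append(gt)
    return frames, SequenceGroundTruth(
        timestamps=list(spec.timestamps), frames=gts, mm_per_px=spec.mm_per_px
    )


def study_specs(seed: int = 0) -> dict[str, SeedlingSpec]:
    """Three-seedling benchmark: 640x480 frames, 40 nightly captures.

    Mirrors a small glasshouse trial: two four-node seedlings and one
    five-node seedling, with differing stem tilts and color noise.
    """
    return {
        "A": SeedlingSpec(n_nodes=4, stem_tilt=5.0, seed=seed * 10 + 1),
        "B": SeedlingSpec(n_nodes=4, stem_tilt=-3.0, color_sigma=10.0, seed=seed * 10 + 2),
        "C": SeedlingSpec(n_nodes=5, stem_tilt=2.0, seed=seed * 10 + 3),
    }


def make_pixel_training_set(
    frames: list[np.ndarray],
    gt: SequenceGroundTruth,
    counts: dict | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified labeled pixel sample over all frames.

    Default class counts follow the usual labeling effort split:
    25,000 stem / 5,000 leaf / 25,000 background.  Returns (features,
    labels) with features the 15-component color vectors.
    """
    counts = counts or {STEM: 25000, LEAF: 5000, BACKGROUND: 25000}
    rng = np.random.default_rng(seed)
    feats_per_frame = [image_color_features(f) for f in frames]
    all_feats, all_labels = [], []
    for cls, n_wanted in counts.items():
        locs = []
        for fi, fgt in enumerate(gt.frames):
            ys, xs = np.nonzero(fgt.class_map == cls)
            locs.append(np.column_stack([np.full(ys.size, fi), ys, xs]))
        locs = np.concatenate(locs)
        if locs.shape[0] == 0:
            raise ValueError(f"class {cls} absent from the sequence")
        pick = rng.choice(locs.shape[0], size=min(n_wanted, locs.shape[0]), replace=False)
        for fi, y, x in locs[pick]:
            all_feats.append(feats_per_frame[fi][y, x])
            all_labels.append(cls)
    return np.asarray(all_feats), np.asarray(all_labels)


def make_patch_training_set(
    frames: list[np.ndarray],
    gt: SequenceGroundTruth,
    n_node: int = 200,
    n_non_node: int = 250,
    patch_size: int = 40,
    min_distance: float = 30.0,
    jitter: int = 3,
    seed: int = 0,
):
    """Labeled 40x40 patch centers for the patch classifier.

    Node patches center on ground-truth node centers (jitter <= 3 px);
    non-node patches sample leaf interiors and bare stem at least 30 px
    from any node center.  Returns (patches, labels) with labels in
    {"node", "non_node"}.
    """
    from phenonode.bovw import NODE, NON_NODE, extract_patch

    rng = np.random.default_rng(seed)
    half = patch_size // 2
    h, w = gt.frames[0].class_map.shape

    node_locs = []
    for fi, fgt in enumerate(gt.frames):
        for x, y, _ in fgt.nodes:
            node_locs.append((fi, int(round(x)), int(round(y))))
    if not node_locs:
        raise ValueError("no ground-truth nodes available")

    patches, labels = [], []
    for _ in range(n_node):
        fi, x, y = node_locs[rng.integers(len(node_locs))]
        jx = int(x + rng.integers(-jitter, jitter + 1))
        jy = int(y + rng.integers(-jitter, jitter + 1))
        jx, jy = np.clip(jx, 0, w - 1), np.clip(jy, 0, h - 1)
        patches.append(extract_patch(frames[fi], (jx, jy), size=patch_size))
        labels.append(NODE)

    # Eligible non-node spots: leaf or stem pixels away from every node.
    eligible = []
    for fi, fgt in enumerate(gt.frames):
        cm = fgt.class_map
        ys, xs = np.nonzero((cm == LEAF) | (cm == STEM))
        centers = np.array([(x, y) for x, y, _ in fgt.nodes])
        d2 = ((xs[:, None] - centers[None, :, 0]) ** 2
              + (ys[:, None] - centers[None, :, 1]) ** 2).min(axis=1)
        ok = d2 >= min_distance**2
        keep = rng.choice(np.flatnonzero(ok), size=min(200, int(ok.sum())), replace=False)
        eligible.extend((fi, int(xs[i]), int(ys[i])) for i in keep)
    if len(eligible) < n_non_node:
        raise ValueError("insufficient eligible non-node locations")
    for i in rng.choice(len(eligible), size=n_non_node, replace=False):
        fi, x, y = eligible[i]
        patches.append(extract_patch(frames[fi], (x, y), size=patch_size))
        labels.append(NON_NODE)
    return patches, labels
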