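# Methods

`phenonode` estimates internode lengths of a young seedling from a
time series of RGB images of the plant. The measurement chain has three
parts — per-frame **node detection**, sequence-level **node-order
estimation**, and **internode length estimation** — plus a synthetic
sequence generator that supplies imagery with exact ground truth.

## Node detection

Each frame passes through a four-stage funnel. Stages only remove
candidates, never add them, so per-frame counts are monotone
(candidates ≥ after main-stem filter ≥ accepted).

**1. Pixel segmentation.** Every pixel is described by 15 color
features — plain RGB channels scaled to [0, 1]; HSV with hue in degrees;
CIELAB and CIELUV (sRGB transfer, D65 white point); and full-range
BT.601 YCbCr scaled to [0, 1] — and classified into
{stem, leaf, background} by a CART decision tree (Gini impurity,
default `max_depth=10`, `min_samples_leaf=5`, seeded tie-breaking).
The tree is trained on labeled pixels; the default sampling effort is
25,000 stem / 5,000 leaf / 25,000 background pixels. Achromatic pixels
get hue 0 by convention. No morphological cleanup is applied to the
resulting class map. The alternative reading of "r, g, b" as chromatic
coordinates R/(R+G+B) was rejected in favor of plain scaled channels;
with both HSV and Lab present the tree loses nothing either way.

**2. Candidate extraction.** The stem class map becomes a binary "stem
image", thinned to a one-pixel skeleton (Zhang–Suen). Skeleton pixels
with ≥3 foreground 8-neighbors are branch/cross points and become node
candidates. Thinning can emit 2–3-pixel junction clusters at one
anatomical junction; 8-connected clusters of junction pixels are merged
to their rounded centroid so one junction yields one candidate.
Skeleton spurs are deliberately not pruned; spur junctions are left for
the later filters.

**3. Main-stem distance filter.** The connected stem component with the
tallest bounding box (ties broken toward larger pixel area) is
summarized by an ordinary least-squares line of **x on y** — the stem is
near-vertical, so regressing y on x would be degenerate. Candidates
whose horizontal distance from the line at their own row exceeds
50 px (inclusive boundary; configurable) are removed. When the
component is perfectly vertical, x has zero variance and the fit is
exact; r² is defined as 1 in that case.

**4. Bag-of-visual-words patch filter.** A 40×40 grayscale patch is
cropped around each surviving candidate (edge replication at borders).
Harris corners (structure tensor with Gaussian window σ=1, k=0.04,
local maxima above 0.01× the maximum response, edge-replicating
boundary handling so flat patches score zero) give keypoints; at each
keypoint a 128-dimensional gradient-orientation descriptor (4×4 spatial
cells × 8 orientation bins, Gaussian weighting, 0.2 clipping,
renormalization) is computed at a single fixed scale and orientation —
there is no scale-space detection, description only. Descriptors are
quantized against a k-means vocabulary (k=10, k-means++, 10 restarts,
fixed seed) into an L1-normalized word histogram, and a 500-tree random
forest decides node vs non-node. A patch with no keypoints is declared
non-node without consulting the forest: bare stem and background are
nearly textureless while true node regions are corner-rich. Accepted
candidates keep the candidate pixel as the detection coordinate.

## Node-order estimation

Detections from all frames are pooled and clustered **on their y
coordinate only** with affinity propagation: similarity is the negative
squared difference of y values, the preference defaults to the median
similarity, and the cluster count — the number of nodes — emerges from
the message passing rather than being supplied. Clusters are ranked
into node orders by decreasing mean y (order 1 is lowest on the plant);
exact ties break toward the cluster with the earlier first detection.
Each order then gets a "node line": OLS of y on capture time (UNIX
seconds; times are centered before solving so UNIX-scale abscissae do
not cost precision). Singleton clusters get a constant line. The node
line interpolates missed detections and averages out spurious ones.

Damping defaults to 0.5. At that value the message updates can
oscillate on 1-D data with many near-tied similarities — the iteration
then never converges and its final state is a meaningless
fragmentation. Because damping only stabilizes the iteration and does
not change the algorithm's fixed point, `cluster_by_y` escalates
damping to 0.7 and then 0.9 (with a warning) when a run fails to
converge; the escalated runs reproduce the exemplar set found by
exhaustive net-similarity maximization on small instances. If no run
converges the detections are treated as a single cluster, with a
warning.

## Internode length estimation

The internode between orders i and i+1 at time t is the vertical
distance between their node lines, yᵢ(t) − yᵢ₊₁(t); the stem is assumed
near-vertical and parallel to the image plane, so only the y component
is measured. A pair's series starts once node i+1 has appeared (its
cluster's earliest detection). Crossing node lines produce a negative
length and a warning. Pixel lengths are multiplied by a rig calibration
factor, default 0.41 mm/px; this constant is camera- and
distance-specific and must be recalibrated for any other rig.

## Evaluation

A detection is a true positive when its center lies inside a
ground-truth node rectangle, boundary inclusive. Matching is one-to-one
and greedy by center distance, so a second detection in an already
matched rectangle counts as a false positive; an allow-duplicates
reading would only raise TP, so the greedy rule is the conservative
choice. Recall = TP/(TP+FN), precision = TP/(TP+FP). Internode series
are scored by relative error, |Σ l̂ − Σ l| / Σ l × 100; when both series
have the same length this equals the error of the means, so summary
means are valid inputs. Cross-validation is leave-one-seedling-out:
train segmentation and BoVW on one sequence, test on all others, rotate
— with three seedlings each is tested exactly twice.

## Synthetic sequences

The generator renders a single seedling: a tilted stem band (default
6 px wide, tilt 5 px of x-drift per 100 px of height, optional
curvature, default 0), petioles as short stem-colored stubs alternating
sides, and textured leaf disks at the petiole tips. Leaves are drawn
first and petioles/stem on top, so the stem mask keeps a petiole branch
at every node and thinning produces a junction there. Class colors are
Gaussian around well-separated means (σ=8 by default) with
high-frequency uniform texture (±60 grey levels) on leaves only — this
is what gives the corner detector signal on leaves and nodes but not on
bare stem. Capture times follow the nightly cadence of glasshouse
imaging: five captures per night, 2 h apart, over 8 nights (40 frames).

Internode i grows linearly: length(t) = initial_i + rate_i · Δt, with
Δt measured in days from the appearance of node i+1. Linear growth
makes the node-line model exactly correct on clean renders, which is
what lets the interpolation and telescoping properties be asserted
exactly. Defaults place the seedling past peak elongation: initial
lengths taper 32, 26, 20, 14 mm from the oldest internode and rates
rise 0.4, 0.6, 0.8, 1.0 mm/day toward the youngest, and the youngest
node emerges 40 % into the sequence. Under these conditions the pooled
y-tracks stay separated by at least ~5× their within-track spread,
which is the regime in which pooled affinity propagation recovers the
node count; if every internode instead elongates rapidly for the whole
window, the cumulative drift of upper nodes smears the tracks and the
clustering genuinely splits them (the net-similarity optimum itself
splits, not just the solver) — handling that regime would need windowed
clustering, which is out of scope. Ground-truth rectangles are 40×40 px
around each node center, within the 28–80 × 28–82 px range used for
manual annotation.

What the generator does **not** emulate: occlusion of nodes by leaves,
curved or non-parallel stems (beyond the curvature knob), cotyledon
confusion (a cotyledon toggle exists but is off by default), lighting
changes, and background clutter. Passing tests therefore demonstrate
the correctness of the pipeline's logic and its behavior in the
method's intended operating regime, not performance on glasshouse
imagery.

## Problem sizes and defaults

The three-seedling benchmark (`study_specs`) uses 640×480 frames,
40 captures, two four-node seedlings and one five-node seedling with
differing tilts and color noise. The test suite trains its fixtures on
a 320×400 canvas with reduced sample counts (100-tree forest, ~11k
training pixels) — the geometry is unchanged, only the effort is
smaller. The cluster-recovery experiment uses 20 detection sets (7 with
3 nodes, 7 with 4, 6 with 5) sampled from ground-truth tracks with a
28 % miss rate and 1.5 px detection jitter, matching the detection
accuracy the full pipeline achieves on rendered frames.

## Known limitations

- The main stem is modeled as a straight line; strongly curved stems
  violate both the 50 px filter and the y-only internode definition.
- Pooled clustering assumes node y-tracks do not overlap in time;
  fast-growing or stress-shortened internodes break this.
- The 0.41 mm/px scale assumes fixed camera distance.
- The patch classifier is only as good as its training seedling; the
  empty-patch rule makes textureless false candidates cheap to reject
  but also rejects true nodes whose patch happens to be blurred flat.
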