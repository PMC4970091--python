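# phenonode

Node detection and internode length estimation for seedling image time
series.

Internode length — the distance between adjoining nodes on the main
stem — is a sensitive indicator of seedling vigor in tomato and other
fruit vegetables: water shortage, night heat, low light and excess
nitrogen all leave their mark on it. `phenonode` measures it from a
fixed camera's nightly image series of a single seedling, with no
per-image threshold tuning, for plant phenotyping and horticultural
research use.

The method has three steps:

1. **Node detection** (per frame): pixels are classified into
   stem/leaf/background by a CART decision tree over 15 color features
   from five color spaces (RGB, HSV, L\*a\*b\*, L\*u\*v\*, YCbCr); the
   stem mask is thinned to a skeleton whose branch points become node
   candidates; candidates further than 50 px horizontally from the
   fitted main-stem line x(y) = a·y + b are dropped; finally a
   bag-of-visual-words classifier (Harris keypoints → 128-d gradient
   descriptors → k-means vocabulary, k = 10 → word histograms → random
   forest) rejects the remaining false positives, mostly on leaves.
2. **Node order estimation** (per sequence): detections pooled over
   time are clustered on y by affinity propagation (damping 0.5,
   similarity −(yᵢ−yⱼ)²), which chooses the number of clusters n — the
   node count — by itself. Clusters are ordered 1…n by decreasing mean
   y, and each order gets a **node line**, the linear regression of y
   on capture time (UNIX s), which interpolates missed detections.
3. **Internode length estimation**: the internode between orders i and
   i+1 at time t is yᵢ(t) − yᵢ₊₁(t), reported from the appearance of
   node i+1 onward and converted at 0.41 mm/px (configurable rig
   calibration).

Detections are scored against ground-truth rectangles (a detection
inside a rectangle is a true positive; recall = TP/(TP+FN), precision =
TP/(TP+FP)), and length series by relative error
|Σ l̂ − Σ l|/Σ l × 100, under leave-one-seedling-out cross-validation.

A synthetic seedling renderer ships with the package: every stage can
be trained, run and validated against exact ground truth without any
external imagery. See `docs/methods.md` for the model details and for
what the renderer does and does not emulate.

## Worked example

```sh
# render two synthetic seedlings (40 nightly frames each, 640x480)
phenonode simulate --out seqA --seed 11
phenonode simulate --out seqB --seed 12

# train segmentation tree + BoVW models on seedling A
phenonode train --data seqA --models models

# detect nodes in seedling B, then track and measure
phenonode detect --data seqB --models models --out det.csv
phenonode track --detections det.csv --out tracks
phenonode evaluate --detections det.csv --data seqB --out metrics.json
```

On this pair of sequences the run prints:

```
wrote 40 frames to seqA
models saved to models (patch classifier OOB: 0.9933333333333333)
wrote 40 frames to seqB
148 detections from 149 candidates -> det.csv
4 node orders, 3 internode series -> tracks
{"TP": 145, "FP": 3, "FN": 0, "recall": 1.0, "precision": 0.98,
 "per_order_recall": {"1": 1.0, "2": 1.0, "3": 1.0, "4": 1.0}}
```

and `tracks/internode_summary.csv` holds the per-pair mean lengths:

```
pair,mean_mm,n_times
1-2,33.6,40
2-3,28.1,40
3-4,21.8,25
```

Reading: the detector accepted 148 of 149 skeleton branch points and
covered all 145 annotated node instances (three frames contributed a
duplicate detection, counted as false positives under one-to-one
matching); affinity propagation found the 4 node orders on its own;
the three internode series average 33.6, 28.1 and 21.8 mm, with the
youngest internode measured only over the 25 frames after its upper
node appeared. The generator's true mean lengths over the same frames
are 33.5, 28.2 and 21.8 mm — well under 1 % relative error.

The library mirrors the CLI: `phenonode.pipeline.train_from_sequence`,
`run_detection`, `run_tracking_and_measurement` and
`phenonode.evaluation.leave_one_seedling_out` are the main entry
points.

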