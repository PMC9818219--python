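# uroscreen

A whole-slide-image (WSI) screening pipeline for urine liquid-based cytology
(LBC), classifying slides as **negative** vs **neoplastic**. The pipeline
covers the full chain:

1. **synthetic_slides** — seed-reproducible synthetic LBC-like slides with
   paired polygon annotations and a manifest CSV, so every downstream stage
   is testable without any real data.
2. **slide_io** — slide reading (pyramidal/plain TIFF, PNG), Otsu tissue
   masking on a grayscale thumbnail, stride-lattice tile grids restricted to
   tissue, and tile extraction with scan→working magnification resampling
   (×20 scans read at ×10 by default).
3. **annotation** — the five-tier cytology class system (I–II negative,
   III–V neoplastic), the three per-cell labels (atypical / LGUC / HGUC, all
   grouped to neoplastic), GeoJSON annotation I/O, and the positive-area
   polygon–tile intersection rule.
4. **training** — fully supervised training with balanced interleaved
   batches and false-positive hard mining of negative slides, and weakly
   supervised training that alternates inference and learning via per-slide
   top-k tile selection into a fixed-capacity buffer (defaults k=8, N=256,
   batch 32). Adam (lr 0.001, 0.95 decay every 2 epochs), photometric
   augmentation, optional partial fine-tuning (normalisation affine + head
   only) and early stopping on slide-level validation loss.
5. **inference** — sliding-window heatmaps (stride = half tile), max-probability
   slide scoring, and jet-colormap overlays.
6. **evaluation** — ROC/AUC by threshold sweep, log loss, accuracy /
   sensitivity / specificity, percentile-bootstrap 95% CIs (1000 iterations),
   and equal-balance (1:1) / clinical-balance (10:1) test-split builders.

The classifier backbone is pluggable (`uroscreen.backbone.TileClassifier`).
A small pure-numpy CNN (`TinyCNN`) with hand-written backprop is bundled so
the whole pipeline runs on one CPU without a deep-learning framework; any
backbone exposing the same contract (per-tile probabilities + a parameter
inventory partitioned into normalisation-affine / head / other) can be
swapped in.

## Tests

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` with one test per acceptance
criterion, including an end-to-end weakly supervised run on a synthetic
cohort (30 train / 10 validation / 40 test slides at 1024² px, 128-px tiles)
that must reach held-out slide-level AUC ≥ 0.9; the full suite takes
roughly 7 minutes on one CPU.

## CLI

```bash
# generate a synthetic cohort
uroscreen simulate --n-negative 10 --n-neoplastic 10 --out data/ --seed 0

# train (config.yaml mirrors TrainConfig fields)
uroscreen train --manifest data/manifest.csv --annotations-dir data/annotations \
    --mode ws --config config.yaml --out run/

# sliding-window inference
uroscreen predict --manifest data/manifest.csv --checkpoint run/checkpoint.npz \
    --out preds/ --tile-size 128 --overlay

# metrics with bootstrap CIs
uroscreen evaluate --predictions preds/predictions.csv --manifest data/manifest.csv \
    --threshold 0.5 --bootstrap 1000 --seed 0 --out report.json

# test-split construction
uroscreen split --manifest data/manifest.csv --design clinical --n-neoplastic 50 \
    --ratio 10 --seed 0 --out test_split.csv
```

## Layout

```
src/uroscreen/        package (one module per pipeline stage + backbone, cli)
tests/                pytest suite; test_acceptance.py holds the criteria
scripts/acceptance.py acceptance report generator
```
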