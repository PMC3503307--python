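# lungmorph

Automatic histomorphometry of airspace enlargement in H&E-stained lung
sections, with the companion micro-CT density descriptors and a classifier
evaluation harness.

The toolset segments bona-fide airspaces from calibrated RGB section
rasters — excluding blood vessels and bronchioles — and computes four
enlargement descriptors per section: the mean linear intercept (Lm) and the
weighted equivalent-diameter moments D0, D1, D2. Higher-order moments weight
large airspaces more heavily, so D2 detects heterogeneous enlargement that
barely moves Lm. A parallel job queue processes whole directories of
sections; group statistics (median/IQR, Mann-Whitney U) and an RBF-SVM
harness (grid search, stratified 60/40 split, ROC/AUC/f1 against a
D2-derived gold standard) compare descriptor sets.

## Segmentation pipeline

1. Extract the 8-bit green channel (greatest contrast between background
   and red-blue stained tissue).
2. Threshold with the maximum-deviation (corner) rule for unimodal
   histograms; tissue = intensity at or below the threshold.
3. Invert the mask and label luminal structures by connected components;
   border-connected components are slide background.
4. Erode the tissue mask (7×7 structuring element by default) so only the
   thickest walls — vessels and bronchioles — survive.
5. Compute the convex hull of each surviving wall component on a 4×
   OR-downsampled raster.
6. Remove every labeled lumen whose centroid falls inside or on a hull;
   descriptors are then computed at full resolution.

## Command line

```sh
# generate a synthetic section and segment it
lungmorph simulate scene --out scene --n-airspaces 20 --n-vessels 2 --seed 1
lungmorph segment scene.png --pixel-size-um 0.725 --out-prefix out/scene
lungmorph descriptors scene.png --pixel-size-um 0.725

# batch a directory tree with 4 workers (results CSV + manifest JSON)
lungmorph batch images/ --out results.csv --pixel-size-um 0.725 --workers 4

# micro-CT density features from a HU volume + lung mask (TIFF stacks)
lungmorph simulate volume --out vol --fraction-below 0.05 --mean-hu -450
lungmorph ct-features vol_hu.tif vol_mask.tif

# cohort statistics and classifier evaluation
lungmorph simulate cohort --out cohort.csv --effect D2=60 --effect VBT=10
lungmorph stats cohort.csv --feature D2
lungmorph classify cohort.csv --features VBT,MLVI --all-combinations
lungmorph roc cohort.csv --features VBT --out roc.csv --plot roc.png
```

Key options: `--pixel-size-um` (µm/pixel calibration; never read from image
metadata), `--threshold` (fixed threshold instead of automatic),
`--se-size` (erosion element, default 7), `--downsample` (hull-stage
factor, default 4), `--workers`, `--seed`.

## Layout

- `lungmorph.synthetic` — scene/volume/cohort generators with ground truth
- `lungmorph.segmentation` — the six-stage airspace segmentation
- `lungmorph.descriptors` — Lm, D0, D1, D2
- `lungmorph.ct_features` — MLVI and VBT (below −900 HU) from a lung mask
- `lungmorph.stats` — median/IQR, Mann-Whitney U, gold-standard labels,
  RBF-SVM grid-search harness, feature-subset ranking
- `lungmorph.pipeline` / `lungmorph.cli` — job queue and CLI
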