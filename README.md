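# segrefine

A toolkit for the unglamorous computational core of refining cell
segmentation in high-resolution spatial transcriptomics. Sub-micron
platforms (Stereo-seq, Visium HD, Seq-Scope) capture RNA at pixel-level
spots; to get single-cell expression, a nuclear or membrane staining image
must be segmented into an **instance mask** (one unique integer label per
cell, 0 = background), and every expression point (gene, x, y, count) then
binned into the cell whose mask pixel it lands on. Pre-trained deep
segmentation models work well in sparse, high-contrast tissue but fail in
dense, low-contrast regions, so practical workflows fine-tune them on a
handful of annotated patches and iterate: segment → evaluate → annotate a
few more patches → re-fit **from the original base weights** → re-evaluate.

`segrefine` implements everything around that loop that does not require a
deep-learning backend, plus a classical watershed baseline so the loop runs
end-to-end on its own:

- **patchkit** — crop fixed-size training patches from whole-tissue images
  (with slide-coordinate traceability), mirror-pad 256×256 patches to
  512×512 without altering cell morphology, convert binary annotation
  masks to instance masks, and build seeded train/validation trainset
  lists grouped by sample (SN).
- **evalkit** — instance-level evaluation by one-to-one IoU matching
  (threshold 0.5): TP/FP/FN and precision, recall, F1, Jaccard, Dice,
  per image and aggregated. At the instance level F1 ≡ Dice and
  Jaccard ≡ Dice/(2 − Dice); the test suite proves both exhaustively.
- **morphkit** — six mask morphometrics that explain *why* a region is
  hard to segment: mean nearest-neighbour distance, compactness
  ((mean distance)²/mean area), density (N/A_total), distribution
  (coefficient of variation of local densities 3/D_i,3), shape complexity
  (mean(P²)/mean(A), exactly 16 for squares under the pixel-edge perimeter
  convention), and Sobel edge contrast (μ_cell/μ_bg).
- **cellbin** — parse GEM spot tables (plain or gzipped), assign points to
  mask labels by exact pixel lookup, aggregate counts into a sparse
  cells × genes matrix with per-cell centroids/areas, and write it as
  open MatrixMarket + TSV sidecars (optionally AnnData).
- **synthkit** — a deterministic generator of paired (image, mask,
  expression) fixtures in two regimes, dense/low-contrast vs
  sparse/high-contrast, with planted ground truth and controlled mask
  perturbations (drops, splits, shifts) for known-answer evaluation.
- **refine_loop** — the segment → evaluate → extend → re-fit loop against
  a pluggable `SegmenterAdapter` contract (always re-fitting from the base
  state to avoid catastrophic forgetting), with an Otsu + distance-
  transform watershed baseline segmenter built in.

## Worked example

```sh
segrefine simulate --regime dense_lowcontrast --n-cells 80 --seed 4 --out-dir fx
segrefine segment  --image fx/image.tif --out pred.tif
mkdir gt pred && cp fx/mask.tif gt/region.tif && cp pred.tif pred/region.tif
segrefine evaluate --gt-dir gt --pred-dir pred --out metrics.csv
segrefine morph    --image fx/image.tif --mask fx/mask.tif --out morphology.csv
segrefine cellbin  --gem fx/expr.gem --mask fx/mask.tif --out-dir cells
```

prints

```
fixture with 80 cells → fx
80 instances → pred.tif
statistic  precision  recall  f1  jaccard  dice
     mean        1.0     1.0 1.0      1.0   1.0
{
  "n_cells": 80,
  "mean_distance": 17.94993664383181,
  "compactness": 2.8809677032978733,
  "density": 0.001220703125,
  "distribution": 0.1930135640755353,
  "shape_complexity": 20.86241198166983,
  "edge_contrast": 2.9328143903733586
}
80 cells × 20 genes, total count 1778 → cells
```

Reading it: the watershed baseline recovered all 80 planted cells at
IoU ≥ 0.5 (every matching metric 1.0 — synthetic nuclei are far easier than
tissue). The morphometrics describe a dense, low-contrast region: cells
~18 px apart with an edge-contrast ratio of only ~2.9. The binning step
conserves counts exactly: the 1778 total equals the sum of all in-cell
expression points. The same library calls are available in Python
(`segrefine.synthkit`, `segrefine.refine_loop`, …); the CLI is a thin
wrapper.

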