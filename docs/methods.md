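# Methods

## Problem setting

High-resolution spatial transcriptomics assigns RNA counts to pixel-level
spots; single-cell analysis requires partitioning the staining image into
cell instances and binning spots into cells. Segmentation quality varies
strongly with tissue architecture: densely packed, weakly stained regions
(hippocampus-like in brain sections) defeat pre-trained models that do
well in sparse, high-contrast regions. The practical remedy is iterative
small-sample fine-tuning; this package implements the surrounding
machinery — training-set preparation, instance evaluation, morphometric
diagnosis, expression binning, and the loop itself — with fully synthetic,
ground-truth-planted fixtures so every step is testable without data
downloads or GPU training.

## Patch preparation (patchkit)

Patches are cropped on a regular grid at a configurable stride; partial
windows at the right/bottom edge are dropped rather than padded, keeping
every patch exactly `patch_size²` and trivially traceable to slide
coordinates (`{sn}_r{row}_c{col}`, 0-based row/col origin top-left).
Whether patches may overlap is a user choice via the stride.

Mirror padding uses reflection *excluding* the border pixel
(`[1,2,3] → [3,2,1,2,3,2,1]`), which avoids a two-pixel-wide artifact at
the seam; the centre of the output is bit-identical to the input. When a
label mask is padded, every mirrored copy of a cell is a distinct object
and receives a fresh label — otherwise one label would span disconnected
components, breaking the instance-mask invariant.

Semantic→instance conversion labels connected foreground components
(8-connectivity by default, standard for nuclei blobs; 4 available) and
renumbers them 1..K in raster order of each component's first pixel, so
the labelling is reproducible across library versions.

Train/validation splitting is per sample group (SN): each group
contributes round-half-up(group size × val_fraction) validation entries,
chosen by a seeded shuffle. Group sizes are invariant to the seed; the
assignment is reproducible given the seed.

## Instance evaluation (evalkit)

The IoU table is computed on pixel sets via a label-pair contingency
count. Matching is greedy in descending IoU with ties broken by ascending
(gt_label, pred_label). For IoU strictly above 0.5 the partner is unique
(two predictions cannot each overlap more than half of the union with the
same truth cell), so greedy equals the optimal assignment; the test suite
verifies this against a maximum-bipartite-matching oracle on perturbed
fixtures.

Degenerate counts are defined, never NaN: both masks empty → all five
metrics 1.0 (there was nothing to get wrong); one side empty → precision
and recall 0. This keeps batch aggregates (unweighted per-image means)
well defined. Reports are CSV by default with an optional xlsx writer.
Aggregation is per image, not pooled over instances; the two conventions
differ when images carry different cell counts, and per-image means match
how batch evaluations are usually reported.

## Morphometrics (morphkit)

Connected-region analysis yields per-cell area A_i (pixel count),
perimeter P_i and centroid (mean pixel coordinate). The perimeter
convention is the count of pixel edges between the cell and any non-cell
pixel, image border included: an s×s square has perimeter exactly 4s and
a single pixel 4. This makes the closed forms exact (shape complexity
mean(P²)/mean(A) = 16 for any population of squares) at the cost of
overestimating the geometric perimeter of diagonal boundaries; smoothed
estimators exist but would trade testability for no benefit here.

The six metrics: mean nearest-neighbour centroid distance; compactness
(mean distance)²/Ā; density N/A_total where A_total is the *full image*
pixel count (tissue-area masking is out of scope); distribution, the
coefficient of variation (population σ, divisor N) of the local densities
3/D_i,3 with D_i,3 the sum of the three smallest neighbour distances of
cell i; shape complexity as above; and edge contrast, the ratio of the
mean 3×3-Sobel gradient magnitude on cell-boundary pixels (cells with a
4-neighbour of a different label) to that on background pixels. The
background excludes a 2-pixel city-block ring around cells so boundary
gradients do not bleed into the background estimate; Sobel borders are
mirror-padded and RGB images are converted to luminance first. Metrics
with insufficient support (fewer than 2 cells for distances, 4 for
distribution, zero background gradient for contrast) are reported as
`None` with a reason flag, never silently zero.

## Expression binning (cellbin)

GEM tables are tab-delimited (gene, x, y, count) with `MIDCount`/
`UMICount` and `geneID`/`gene` synonyms, optional `#` comments, and
optional gzip. Coordinates are 0-based pixels with x = column in the mask
frame (a `--one-based` flag shifts exports whose origin is (1,1)); rows
with non-integer coordinates or count < 1 are rejected with their file
line numbers. Assignment is exact pixel lookup — no interpolation, no
boundary heuristics. Points on background are excluded, not
redistributed, so matrix total + background total = input total holds as
an identity. Cells with no points are still emitted (with zero rows) so
the per-cell metadata (centroid, area) is complete; a flag drops them.
More than half of the points falling outside the mask aborts with a
coordinate-frame hint. Output is MatrixMarket + `genes.tsv` + `cells.tsv`
— open, diffable, and round-trip-lossless — rather than a binary HDF5
dialect; an AnnData export is provided for downstream toolchains.

## Synthetic fixtures (synthkit)

The generator plants elliptical cells (axes uniform in `radius_range`,
default 4–8 px; orientation uniform) by rejection sampling against the
occupancy mask, renders intensity as background 40 + a foreground gap +
clipped additive Gaussian noise (sd 8 on the 0–255 scale), and returns
the exact geometry of the rendered mask as ground truth. Two regimes
bracket easy and hard tissue:

| regime | canvas | min gap | fg/bg gap |
|---|---|---|---|
| dense_lowcontrast | 256² | 2 px | 3 × noise sd |
| sparse_highcontrast | 384² | 10 px | 10 × noise sd |

Density is N/A_total, so "denser at matched cell count" means a smaller
canvas; the default canvases (256² vs 384²) encode that, and at the
default 60 cells the regimes reproduce the qualitative ordering seen in
real dense-vs-sparse tissue comparisons: smaller mean distance, higher
density and lower edge contrast in the dense regime. The generator makes
no attempt at staining texture, cell-interior structure, uneven
illumination or touching cells (unless `overlap_allowed`); passing tests
therefore demonstrate correctness of the *measurement and bookkeeping*
code on known geometry, not segmentation performance on real tissue.

Mask perturbation produces known errors for evaluation cross-checks:
dropping ⌊f·N⌋ cells creates exactly that many false negatives; splitting
a cell in half along its longer axis creates exactly one extra prediction
whose larger half still matches at IoU ≥ 0.5, hence one false positive
per split; small random shifts stress the matcher without changing the
ledger. One seeded RNG per artifact keeps image, mask and expression
independently reproducible.

## Refinement loop (refine_loop)

The `SegmenterAdapter` contract is two pure functions plus an opaque base
state: `segment(image, state) → mask` (deterministic given the state) and
`finetune(entries, base_state) → state`. The loop always passes the
*original* base state to `finetune` — re-fitting from a fine-tuned
checkpoint compounds drift toward the most recent patches (catastrophic
forgetting), so the contract forbids it and a spy adapter in the tests
asserts it. Each round adds the next batch of annotated patches to a
cumulative (monotone) training set, re-fits, evaluates mean F1 on
held-out pairs, and logs to an append-only `rounds.jsonl` plus per-round
metric CSVs in a `run_YYYYMMDD_HHMMSS` directory; the loop stops at a
target F1 or a round cap — an explicit operationalisation of the informal
"add annotations until it looks good" practice. Deep-learning backends
are integration points only; the shipped baseline is Otsu thresholding
(between-class variance maximisation) on a σ=1 Gaussian-smoothed image,
instance splitting by watershed from distance-transform peaks
(min peak distance 5 px), and removal of components under `min_area_px`
(default 9 px², ~a 3×3 nucleus fragment). Its `finetune` fits the one
thing a classical segmenter can learn from labels: the minimum-area prior
(half the 10th-percentile annotated cell area).

## Problem sizes and determinism

Tests and the acceptance script run on fixtures from 64² (200 matching-
oracle pairs) through 512² with 200 cells (end-to-end pipeline); the full
suite completes in well under a minute on one CPU. All randomness flows
through `numpy.random.default_rng` seeds; hypothesis-based property tests
are derandomised. Known limitations: no overlapping/touching-cell
regime for the matcher beyond synthetic splits, no tissue-region masking
for density, no photorealistic staining, and the greedy matcher's
optimality argument holds only for thresholds ≥ 0.5 (lower thresholds
would need true assignment optimisation).
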