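# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `mitdet`, and what the synthetic test-bed does and does
not establish.

## Problem and pipeline

Mitotic figures in H&E-stained breast tissue are sparse (a handful per
high-power field), morphologically heterogeneous across the four division
phases, and closely mimicked by apoptotic and hyperchromatic interphase
nuclei. Benchmark annotations give only a centroid pixel per mitosis. The
pipeline therefore works in phases: weak labels are upgraded to instance
masks, a tissue-level detector over-calls candidate regions (high recall,
low precision), blob analysis removes fragments, and a cell-level classifier
restores precision. Evaluation follows the challenge convention: a
prediction within 30 px (Euclidean, inclusive) of a ground-truth mitosis is
a true positive, and the two lobes of a telophase figure count as one
mitosis.

## Stain model and normalization

Dyes attenuate light multiplicatively, so images are analysed in optical
density, `OD = -log10(I / I0)` with `I0` the per-channel background
intensity and an intensity floor of 1 (0–255 scale) keeping OD finite.
Base-10 logarithm is used throughout the OD pipeline; the detection and
classification losses use the natural logarithm (the standard cross-entropy
convention) — the two conventions are independent and deliberate.

Basis estimation (Macenko): tissue pixels are those with OD vector norm
above `od_threshold` (default 0.15); the top-2 eigenvectors of their
covariance span the stain plane; the 1st/99th percentile angles within that
plane give the two stain vectors. The vector with the larger blue-channel
component is labelled haematoxylin. Since the stain matrix `V` is 3×2, the
per-pixel concentrations solve `OD = V·S` via the Moore–Penrose
pseudoinverse (the only well-defined reading of an "inverse" of a
non-square matrix). Normalization re-expresses non-negative concentrations
in a target basis, optionally matching 99th-percentile concentrations; the
identity transform reproduces the input within 1 intensity level
(quantisation only). Standardization `(x − μ)/σ` is per-channel by default
(a global-scalar switch exists); dataset statistics are computed on the
training set only and reused at inference.

## Weak-label refinement

A mask may explain a centroid if the centroid lies inside it (distance 0),
or if the mask centroid is within 30 px — the evaluation radius is reused
because the refiner's own matching criterion is otherwise unspecified.
Assignment is greedy nearest-first with lexicographic tie-breaks, which the
matching oracle (below) shows is equivalent to optimal assignment at
realistic densities. Unmatched centroids receive a circular pseudo-label
with integer radius drawn uniformly from 10–16 px (the distribution is
otherwise unspecified; uniform over integers is the minimal choice and is
seeded). Pseudo circles colliding with an existing instance are *clipped*
rather than re-drawn, keeping instances pixel-disjoint for COCO export; the
annotated centroid pixel is always retained so no instance can vanish.

## Candidate detection

Anchors: one box per (scale, ratio) with `w = s√r`, `h = s/√r` (area
preserved, rounded to integers); the full-scale configuration is 4 scales
× 3 ratios = 12 anchors per position. Proposals are kept when their best
IoU against ground truth is ≥ 0.7 ("at least" ⇒ inclusive); detection
output is kept when confidence is strictly above 0.5 ("more than" ⇒
strict).

The three-part loss is the unweighted sum of (i) `−ln p` of the true class
(probabilities clamped at 1e−7), (ii) smooth-L1 on box parameters with the
transition at |d| = 1 on raw coordinate differences, boxes encoded as
(centre, log-size), and (iii) mean binary cross-entropy over the proposal's
pixels. The printed form of the mask term lacks a leading minus sign, which
would make the "loss" non-positive; standard negative BCE is implemented.

The reference detector exists because a full ResNet101-FPN instance
segmentation network is out of scope on one CPU: a two-stride-2-block conv
trunk (stride 4), 1×1-conv objectness and box-offset heads over a grid of
anchors (desk-scale defaults 16/24/32 px, square), and a small conv mask
head applied to the image crop of each region (resized to 20 px,
nearest-neighbour). 128 proposals are sampled per step (≤ 50% positive;
positive ≥ 0.5 IoU plus each ground truth's best anchor, negative < 0.3),
and training uses SGD with momentum 0.9 and cosine-annealed rate. External
detectors plug in as any object with `predict(image) -> [CandidateRegion]`
or a callable returning `{box, score, mask}` dicts.

## Blob analysis

Connected components use 8-connectivity — the permissive choice that avoids
splitting the thin chromatin bridge of a telophase figure. The area filter
is strict (`area > min_area`; 600 px at full 40× scale, 60 at the ~4×-
reduced synthetic scale). The representative point of a prediction is the
mask centroid when a mask exists, else the box centre (both supported).
Distance-tie matching resolves by lowest (row, col).

## MitosRes-CNN

The published architecture table is executable: `MITOSRES_SHAPES` freezes
the expected (C, H, W) after every named stage, and the builder propagates
shapes through the constructed layers, refusing to build on any
disagreement. Three of the table's hyperparameter cells contradict its own
input/output columns; the shape columns are taken as authoritative:

- Block 1's first 1×1 convolution prints padding 1 (would give 62×62, not
  60×60) → padding 0.
- Block 3's average pool prints padding 1 (would give 8×8, not 7×7) →
  padding 0.
- Block 3's stride-2 1×1 projection skip maps 15×15 to 8×8, not the printed
  7×7 → the projection is followed by a corner crop to the main path's
  spatial size.

Channel schedule 32→96→288→512 follows the table even though the
accompanying description ("maps tripled at each block end") breaks at
288→512. Batch normalization precedes the leaky ReLU (slope 0.01) inside
blocks, matching the row ordering; dropout (p = 0.5) sits before and after
the first dense layer. Weight init default is the literal printed rule
`W ~ U[−1/z, 1/z]` with `z` = fan-in; the standard Glorot bound
`√(6/(fan_in+fan_out))` is available behind a switch — the discrepancy is
documented, not resolved. Biases start at 0. The 4×4 adaptive pool over a
7×7 map necessarily uses unequal bins; bin i spans
`[floor(i·H/o), ceil((i+1)·H/o))` (the PyTorch convention), a documented
choice rather than a claim about the original.

Training: cross-entropy, SGD momentum 0.9, learning rate 1e−3 with plain
cosine annealing (no restarts — the restart schedule belongs to the
detector), weight decay 1e−5, batch 16 (6 for adapted backbones), 250
epochs at full scale. The best-validation-F checkpoint is kept, with ties
resolved toward the *later* epoch so early untrained states can never win.
Oversampling draws each batch element from the positive class with the
target probability (default 0.5); a target equal to the prevalence (or
`None`) degenerates to plain shuffling. Validation/test sets are never
oversampled or augmented, and train/validation patient sets must be
disjoint (checked, error on overlap). Colour-jitter magnitudes are ±10%
(unstated in the source setup; configurable).

A reduced preset (same three-block topology, channels 8–32, 40 px inputs,
2×2 pool) trains in minutes on one CPU and is what the end-to-end synthetic
run uses.

## Matching and metrics

Ground-truth telophase lobes sharing a group id are merged into one target
before matching; the distance from a prediction to a target is the minimum
over the target's member centroids, so a hit near either lobe counts — once.
Matching is greedy distance-ascending one-to-one. Surplus predictions
within 30 px of an already-matched target are suppressed (neither TP nor
FP) by default — they do lie within the radius of a true mitosis — with a
strict mode counting them as FP. Greedy matching was chosen over optimal
assignment for determinism and speed; against a Hungarian oracle it is
exact on 200 random instances at real HPF density and within 2 TP in
pathologically dense point clouds (both tested). PR curves sweep the unique
scores with full re-matching per threshold; the AUC uses the step-wise
rectangle rule over recall (conservative; no trapezoid interpolation).
F is guarded to 0 when TP = 0.

## Synthetic scenes: what they do and do not establish

The generator states a world with the pipeline-relevant structure: two-stain
OD mixing through known unit vectors (so basis recovery has a ground
truth), star-convex spiculated mitoses with high haematoxylin concentration
(hyperchromatic chromatin), bilobed telophase figures (two discs plus a
≥3 px bridge, one centroid, one instance), elliptical interphase nuclei with
moderate staining, eosin-dominant smoothed stroma texture (nearly pure
eosin pixels, required for percentile-based basis estimation), Gaussian
intensity noise (σ = 2), and photometric/position perturbations. Geometry
is ≈4× smaller than real 40× patches (nuclei 10–26 px across in a 192 px
field) so that everything trains on one CPU; area and patch-size parameters
scale accordingly (blob cut 60 px², 40 px cell patches).

Objects are placed by rejection sampling with minimum centre distance =
sum of radii + 2 px, bounded at 1000 retries (explicit error beyond).
Coordinates are 0-based (row, col), row increasing downward, everywhere.
Border patches are reflect-padded — constant padding would give the
classifier a trivial border cue.

What a green end-to-end test establishes: every stage composes, learns
from its own upstream outputs, and the detector+classifier combination
separates the stated mitosis/non-mitosis contrast (F ≥ 0.9 held-out, F =
1.0 at the pinned seed; across other seeds observed F 0.86–1.0). What it
does not establish: performance on real tissue — real chromatin texture,
overlapping nuclei, necrosis, stain artefacts and scanner-specific optics
are all absent, and the synthetic contrast is far cleaner than the real
class boundary.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.Generator` seeds; identical
  seed+input ⇒ bit-identical outputs (scenes, training histories, reports).
- Losses clamp probabilities to [1e−7, 1−1e−7]; degenerate boxes, empty
  masks, zero-σ standardization, single-class manifests, out-of-range
  pseudo radii and rank-deficient stain clouds all raise typed errors.
- Tiling stride is `floor(size·(1−overlap))` (512/15% ⇒ 435); edge tiles
  are shifted inward, not padded, keeping all tiles equal-sized for the
  detector; a 2000 px axis yields origins 0/435/870/1305/1488.
- Centroid CSVs are `row,col`, 0-based, with a header comment; a
  `one_based` flag shifts by exactly 1 for datasets using 1-based indices.
- COCO segmentation defaults to uncompressed RLE (column-major counts),
  which round-trips masks pixel-exactly without external COCO tooling;
  polygon export (angular boundary trace, adequate for star-convex nuclei)
  is approximate and provided for interoperability.

## Known limitations

- The NumPy networks are CPU-bound and desk-scale; the full-width
  MitosRes-CNN builds and runs but is not trained at the published
  250-epoch scale here.
- The reference detector's mask head reads image crops rather than trunk
  features; it is a stand-in for a production instance-segmentation model,
  exposed behind the provider interface so one can be slotted in.
- Consensus fusion is implemented and tested against an argmax oracle, but
  the end-to-end synthetic run uses a single classifier; fusing several
  trained networks is left to the caller.
- The telophase merge rule (group-id merge, minimum member distance) is one
  concrete reading of "counted once"; the original counting protocol's
  exact bookkeeping is not public.
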