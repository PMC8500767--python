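# Methods

`pyrascreen` implements a coarse-to-fine screening framework for
multiresolution pathology images: a quadtree search over the slide pyramid
locates candidate cancer regions cheaply, a shared convolution/deconvolution
backbone provides both patch confidence and density regression, an
LSTM-fused per-patch encoder refines tumor-mass counts across patch
sequences, a Gaussian-density cell detector resolves the smallest lesions,
and a TNM-style classifier stages the slide.  This note records the model,
its assumptions, the numerical choices, and what the synthetic benchmarks
do and do not demonstrate.

## The pyramid model

A slide is an ordered stack of RGB levels, level 0 finest; level *l+1*
halves both dimensions of level *l* (ceil on odd dims) and doubles the
physical pixel size.  Coordinates are 0-based `(row, col)`, half-open
intervals, and map between levels by multiplication with `2^(l-l')`
(floor when coarsening).  Downsampling is 2x2 mean pooling; ground-truth
masks coarsen with the any-positive rule, which makes mask evidence
monotone across levels — the property that quadtree pruning relies on.

Tissue is separated from glass by Otsu's threshold on the HSV saturation
channel (H&E tissue is chromatic, background is achromatic white) followed
by a radius-2 disk closing.  Contour annotations rasterize with the
even-odd rule on pixel centers, boundary centers counting as inside.
Color equalization is per-channel histogram matching to a reference patch;
it is a replaceable stand-in for any standard stain-equalization method.
Classical augmentation (random crop, colour jitter, scaling, rotation) is
seeded and defaults to interpolation-free right-angle rotations.

## The DeconvNet backbone

Three blocks of 3x3 convolution + ReLU + 2x2 max pooling, then three blocks
of x2 upsampling + 3x3 convolution + ReLU, then a final convolution to a
single-channel density map at input resolution.  Filter widths double per
down block (desk-scale default 8 -> 16 -> 32; channel counts are free
parameters of the architecture).  Upsampling is nearest-neighbour by
default; a zero-stuffing mode turns each up block into a stride-2
transposed convolution, which fits sharp mask edges noticeably better and
is used where exact memorization matters.  The classifier head is global
average pooling + a fully connected layer + a logistic squashing on the
last convolutional features, giving a patch cancer confidence C(x) in
[0, 1].

All training uses MSE loss (including the classifier on {0, 1} targets,
with a cross-entropy switch) and Adam, the learning rate decayed linearly
in the epoch index from an initial to a final value.  The backbone is fully
convolutional: any input whose dims are divisible by `2^3 = 8` is accepted,
and the density head preserves spatial dims exactly.

The engine behind these networks is a small NumPy layer library with
hand-written reverse-mode gradients (`pyrascreen.nn`), gradient-checked
against central differences in the test suite.  Desk-scale models (tens of
thousands of parameters, 64x64 patches) train in seconds to minutes on one
CPU core.

Density targets are scaled by `target_scale = 100` inside
`DensityRegressor` (unit-mass Gaussian kernels peak near 0.02, far below a
useful float32 MSE working range) and predictions divided back; the public
interface stays in true density units throughout.

## Sequence fusion (channel FCN + LSTM)

For a row-major sequence of N patches, the shared density network (the
"channel FCN") produces per-patch maps F_i.  A dimension-shuffle layer pools
each map over a 4x4 grid of near-equal cells into a 16-vector whose sum
equals the map integral; the descriptor sequence feeds a single-layer LSTM
(10 cells) with a dense readout emitting a per-patch residual count R_i.
The integrated mass is T_i = R_i + sum_p F_i(p).  Losses:

    L_t    = 1/(2N) * sum_i sum_p (F_i(p) - F0_i(p))^2
    L_lstm = 1/(2N) * sum_i (T_i - T0_i)^2
    L      = L_t + alpha * L_lstm

Ground-truth densities F0 are 0/1 lesion masks, so T0 is the lesion mass in
pixels (mask mass, not cell count — the two readings are both defensible;
mask mass matches the per-patch indexing of L_lstm).  Backpropagation runs
through the LSTM over the full sequence; at desk scale (sequences of at
most 16 patches) no truncation window is needed.

Two numerical choices matter here:

- **Descriptor normalization.** Grid-cell sums of a mask-scale 64x64 map
  reach ~250 and saturate the LSTM gates; descriptors are multiplied by
  `(grid cells)/(h*w)` before the LSTM (and the same factor at predict
  time).  The public `dimension_shuffle` keeps the exact sum-equals-integral
  contract.
- **The residual weight alpha.** The per-pixel gradient of L_t is
  O(err/N) while L_lstm contributes alpha * (T - T0)/N to *every* pixel,
  and T - T0 aggregates h*w pixel errors.  Balancing the two terms gives
  alpha ~ 1/(h*w) ~ 2.4e-4 for 64x64 patches, which is the training
  default of `SequenceDensityCounter`'s benchmark; with alpha = 0.1 the
  count term dominates early training and the encoder collapses to
  predicting mean masses.  The loss-weight dataclass itself defaults to
  alpha = 0.1 as a neutral choice for the bare loss function; the weight is
  explicitly a quantity to be tuned.

With alpha = 0 the composite loss carries *exactly* zero gradient into the
LSTM and readout parameters (asserted in tests).

## Quadtree search with location codes

The search starts from a dense grid of fixed-size patches (default 32 px)
at a coarse start level (default: the coarsest level).  Each patch scored
at or above threshold t (default 0.5) becomes an RoI and enqueues its four
quadrant children at the next finer level; sub-threshold patches are pruned
with their whole subtree; the walk stops at `stop_level` (default 1).
Positions are addressed by location-code information (LCI): a string over
{0, 1, 2, 3} (NW, NE, SW, SE), one symbol per descended level, anchored at
a root patch origin.  Encoding and decoding are exact inverses (tested
exhaustively for all 341 codes of length <= 4).

Pruning is lossless when the classifier is monotone (a positive child
implies a positive parent), which holds for the ground-truth-mask oracle
under any-positive mask coarsening; the pruned search then reproduces a
brute-force full tiling of the stop level exactly, with at most
`tiles(start) + 4 * (RoIs above stop)` classifier evaluations.  Real
(non-monotone) classifiers can miss lesions that look benign when coarse;
a `safety_margin` option lowers t at coarse levels as a documented
mitigation.

## Cell-level detection

Point labels rasterize to density maps by stamping the bivariate Gaussian
`(2 pi)^(-D/2) |Sigma|^(-1/2) exp(-1/2 (x-mu)^T Sigma^-1 (x-mu))`
(default isotropic sigma = 3 px), truncated at 3 sigma and rescaled
post-truncation to unit mass, so the map integral equals the point count
exactly for interior points.  A `peak_normalized` mode renders 0-1 peak
maps instead (counting must then go through peak enumeration, since the
integral is no longer a count).

Non-maximum suppression returns pixels that dominate their radius
neighbourhood (default radius = sigma) and exceed a minimum height
(default 0.1 x the theoretical single-kernel peak); exact ties resolve to
the lexicographically smallest coordinate, and constant plateaus produce
no peaks.  On *regressed* maps a light Gaussian pre-filter
(`smooth_sigma = 1.5`) suppresses spurious shallow maxima caused by
upsampling ripple; exact rasterized densities need none, and the default
leaves smoothing off.

Detected points cluster into candidate regions by single linkage: two
points share a region iff a chain of pairwise distances <= 50 um connects
them (equal to connected components of the distance graph; verified
against a union-find oracle).  Region diameter is the maximum pairwise
member distance.

## Staging

Clinical TNM node-lesion conventions, all configurable: macrometastasis
when the largest 4-connected RoI component at the decision level (level 2)
has Feret extent >= 2.0 mm; micrometastasis when a cell region reaches
0.2 mm or more than 200 cells; isolated tumor cells (ITC) when any cancer
cells are detected below those bounds; negative when the search never
reaches below the decision level ("breaks early") or finds no cells.
Larger classes win when regions disagree.  Feret (maximum caliper)
diameter is used for the mm cut-offs, matching the clinical definition;
areas are also reported.  Extents of large regions use a convex-hull
reduction before the pairwise maximum.

The cell-level stage runs only on slides that the tissue-level evidence
does not already settle (negative or macro), mirroring the clinical
escalation path and keeping oracle screening of macro slides cheap.

## The synthetic-slide generator

The generator emulates the *structure* of scanned H&E lymph-node slides,
not their appearance: a chromatic pink tissue blob (smoothly perturbed
disk) on near-white glass, Perlin-like multiscale texture, nuclei as dark
purple ellipses of radius 3-5 px with exact point/bbox labels, and planted
lesions rendered darker and purpler with 3x nuclei density.  Ground truth
is complete: per-level lesion masks (any-positive coarsening), nuclei
points with tumor flags, and a true staging label derived from the planted
lesions.  Everything is bit-reproducible from `(spec, seed)`; the tissue
shape and texture depend only on the spec's `background_seed`, so the same
anatomy can carry different nuclei draws.

Defaults: pixel size 0.25 um at level 0 (the physical range of modern
scanners is 0.23-0.26 um), 6 levels desk-scale (real slides have ~10),
nuclei density 1000 per mm^2 of tissue (real H&E sections run a few
thousand; the value keeps desk-scale rendering fast while giving cluster
analysis realistic spacings).  Lesion-class frequencies are parameters, not
constants — real cohort mixes vary and no canonical mix exists.

The staging benchmarks use pixel size 1.0 um (top of the supported range)
with 3072 px bases so that millimetre-scale TNM lesions fit a desk-scale
canvas (~3.1 mm across); lesion diameters keep a safety margin from the
2.0 mm and 0.2 mm cut-offs so patch-grid quantization cannot flip a class.
ITC lesions are specified by cell count (<= 200), planted exactly.

What passing these benchmarks shows: the search, coding, staging and
counting machinery is correct, and the learning components can extract the
planted signal at desk scale.  What it does not show: performance on real
H&E appearance — stain variability, nuclear pleomorphism, overlapping
cells, scanner artefacts and ambiguous histology are all absent from the
generator.

## Benchmark problem sizes

Chosen as the package's desk-scale study conditions:

- tissue classifier: 200 patches of 64x64 (100 tumor / 100 normal), 70/30
  split, 50 epochs, Adam 1e-3 -> 1e-5;
- cell counting: 120 nuclei patches (6-12 cells each, >= 4 sigma apart),
  70/30 split, 60 epochs; counting by smoothed NMS on the predicted
  density;
- sequence fusion: 24 training / 8 held-out sequences of 4 x 64x64
  patches, 80 epochs, Adam 3e-3 -> 1e-4, alpha = 2.4e-4;
- search agreement: 20 slides of 512 px / 5 levels with 0-2 small lesions;
- staging: 40 slides (10 per class) of 3072 px / 6 levels at 1.0 um/px,
  plus an 8-point diameter sweep 0.05-2.6 mm.

## Known limitations

- The NumPy engine is single-threaded beyond BLAS matmuls; it is sized for
  desk-scale experiments, not gigapixel slides or 3000-epoch schedules.
- The classifier and density models are trained jointly from scratch; the
  two-stage protocol (train density, freeze, fit only the confidence head)
  is available by training a density model first and attaching a head, but
  is not the default path.
- The pyramidal TIFF reader handles SubIFD pyramids only; vendor WSI
  formats and annotation XML need external conversion (a documented stub
  states the CSV mapping).
- `equalize_color` is histogram matching; it does not model stain physics.
- Search with a trained classifier inherits that classifier's coarse-level
  errors; the pruning-equivalence guarantee is proved only for monotone
  oracles.
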