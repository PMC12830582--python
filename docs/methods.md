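# Methods

This note documents the models, parameter choices and numerical
decisions behind `dcshape`, and what the synthetic benchmark does and
does not demonstrate about real deformability-cytometry (DC) data.

## Segmentation

DC frames are 8-bit brightfield images of a static microfluidic scene
with transient objects. The pipeline is a fixed eight-stage sequence:

1. absolute difference against a per-pixel **temporal median**
   background (window `bg_window`, default 100 frames);
2. Gaussian smoothing (`smooth_sigma`, default 1 px);
3. fixed-offset threshold on |frame − background|
   (`threshold_offset`, default 8 gray levels);
4. binary opening (radius 1) then closing (radius 2);
5. 8-connected component labelling;
6. area gate (50–15,000 px²);
7. border exclusion;
8. hole filling.

The temporal median recovers the background exactly as long as each
pixel is object-covered in fewer than half of the windowed frames,
which holds at cytometry event rates. The absolute difference makes
detection insensitive to whether an object is darker or brighter than
the background — brightfield cells are both at once (dark interior,
bright diffraction rim).

Two details matter more than they look:

- **Border exclusion band.** The morphological closing erodes the
  outermost frame rows, so an object clipped by the frame edge can
  retreat from the border by up to the closing radius before the
  border test runs. The exclusion band is therefore as wide as the
  closing radius, not a single pixel.
- **Aggregates are not split.** Touching cells form a single event on
  purpose: "aggregate" is one of the five image classes and is handled
  by the classifier, not by watershed heuristics.

The threshold-monotonicity property (raising `threshold_offset` never
increases the event count) holds for objects whose difference image is
unimodal. Objects with a bright rim *and* a dark interior can split
into two components at thresholds between the two contrasts; the
property test uses rim-free objects for exactly this reason.

## Contours and the deformation statistic

Deformation is the isoperimetric deficit

    D = 1 − 2·sqrt(π·A) / l,

computed from the contour's shoelace area A and polygon perimeter l,
then clamped to [0, 1) with the clamping flagged. D is 0 for a circle,
≈ 0.114 for a square (1 − √π/2), dimensionless and scale-invariant.

Perimeter estimation dominates the error budget. Marching squares on a
raw binary mask overestimates the perimeter of a digitised disk of
radius 30 px by ~6.4 %, which alone would report D ≈ 0.06 for a
perfect circle — larger than the deformation differences the method is
meant to resolve. `extract_contour` therefore smooths the mask
indicator with a Gaussian (σ = 1.5 px) and traces the 0.5 iso-level,
which brings the disk bias down to |D| ≈ 0.0015 while keeping the area
within 0.5 %. The smoothing width is a compromise: larger σ suppresses
staircase bias further but rounds genuine boundary concavities of
anomalous cells. Masks below 5 px are rejected outright — no contour
at that scale supports meaningful morphometry.

Vertices are (row, col) in pixel-centre coordinates, counter-clockwise,
first vertex repeated last. One convention, used everywhere.

## Mode summaries

Per-sample location statistics use the mode, not the mean: single-cell
area and deformation distributions are right-skewed with debris and
aggregate tails even after classification. The mode is the argmax of a
Gaussian KDE with Silverman's bandwidth, evaluated on a 512-point grid
over the sample range — deterministic and binning-free, unlike a
histogram mode. On 9,000 unimodal draws the mode lands within 0.005 of
the true location; with fewer than ~900 cells the estimate becomes
unstable, so summaries flag samples below that floor.

Class fractions are computed over **all** events; the deformation/area
modes and droplet averages are restricted to intact-labelled cells,
the physiologically meaningful subpopulation. This intact-only
restriction is a deliberate reading of what a population summary
should mean — the alternative (all events) is available by relabelling.

## Classifier

Five classes: intact, anomalous, dead, aggregate, debris. The network
is a residual CNN on 224×224 grayscale input with the classification
head flatten → dense(256) → ReLU → dropout(0.3) → dense(5); training
uses Adam (batch 64, up to 100 epochs), cross-entropy with
inverse-frequency class weights w_c = N/(K·n_c), a stratified 80/20
split, augmentation (crop, rotation, horizontal flip, affine,
perspective, brightness/contrast), early stopping on validation loss,
learning-rate halving on plateau, and restoration of the
best-validation weights. Normalisation statistics (a single μ, σ pair
for 1-channel data) come from the training set only; validation is
never augmented.

The stack is implemented in numpy (`dcshape.nn`): im2col convolutions,
batch normalisation, dropout, dense layers, residual blocks, Adam, and
weighted softmax cross-entropy, with exact analytic gradients verified
against finite differences in the test suite. Two backbones exist:

- `resnet18` — four residual stages (64→512 channels), the default
  for full-scale data;
- `tiny` — one stem convolution plus two residual stages (8→32
  channels), for CPU desk-scale runs.

The desk-scale profile used by the tests and the acceptance script is
the tiny backbone at 64×64 input, learning rate 3·10⁻⁴, ≤10 epochs on
200 images per class; it reaches ≥0.94 balanced validation accuracy on
the default synthetic classes in under a minute on one CPU core. The
learning rate, hidden width (256) and patience values are this
package's defaults — conservative, and fully configurable — since the
training protocol fixes only epochs, batch size, optimiser, dropout
and the split. Pretrained weights are deliberately not used; training
starts from seeded random initialisation, so runs are reproducible
bit-for-bit.

Ties in the argmax label resolve to the lowest class index.

## Droplet counting

Lipid droplets appear as compact dark inclusions in the cytoplasm. The
detector runs inside the segmented mask: erode by 2 px (exact
Euclidean-distance erosion, so a darkened diffraction rim can never
leak into the interior), compute the median m and range r of the
remaining intensities, mark pixels below m − 0.35·r, label 8-connected
components, and keep those with area between 4 px² and 25 % of the
cell area. The threshold is *relative* to the within-cell intensity
range, making counts robust to illumination drift between runs. Both
the integer count per cell and the total droplet-area fraction are
reported; sample averages over intact cells are non-integer by nature.

Known failure mode: in cells with strong smooth texture and no
droplets, the within-mask range is small and texture minima can
occasionally clear the relative threshold, producing a spurious count
of 1 (~3 % of default synthetic cells). Exact-count recovery on cells
with 0–5 planted droplets is ≥96 % at default contrast.

## Synthetic generator

The generator renders parameterised caricatures of the five event
classes on a gradient background with Gaussian noise, 8-bit quantised:
smooth bright-rimmed ellipses (intact), radial-sinusoid boundary
perturbations with blotchy texture (anomalous, amplitude ≥15 % of the
radius by default), small low-contrast granular objects (dead), unions
of 2–4 overlapping ellipses (aggregate — sometimes smaller than a
large intact cell, so size cannot separate them), and irregular blobs
below a quarter of the median intact area (debris). Droplets are
anti-aliased dark disks (radius 3 px, contrast 60 gray levels by
default) placed disjointly inside the eroded cell mask.

Ground truth is analytic: every object carries its boundary polygon
(dense parametric sampling; shapely union for aggregates), area,
perimeter, class and droplet geometry. Rasterised masks agree with the
polygon area to within 2 % for objects with min semi-axis ≥ 10 px.

Default conditions: 256×96 px frames (384×128 for the recovery
benchmark, where four large cells per frame need the extra room),
background 180 with a 10-gray-level lateral gradient, noise σ = 2,
intact semi-axes 18–28 px. A `hard` mode narrows the
intact-vs-anomalous perturbation amplitude to 0.06–0.12, the knob for
classifier difficulty. Object placement keeps ≥8 px between boundary
polygons — comfortably above the 4 px no-touch guarantee, so the
segmenter's closing operation cannot bridge neighbours.

What passing these benchmarks does **not** show: the generator has no
optical point-spread function, no motion blur, no flow physics and no
photorealistic texture, and its class contrasts are cleaner than real
brightfield data. Synthetic accuracy figures (e.g. the ≥0.90 balanced
accuracy bar) therefore validate the *mechanics* of the pipeline —
losses, weighting, splits, determinism — not instrument-level
performance, and are not comparable to per-class accuracies published
for manually curated instrument images.

## Determinism and provenance

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; training, augmentation and placement are
reproducible bit-for-bit on a given platform. Pipeline outputs embed a
configuration hash, package version and seed — deliberately no
timestamps — so identical runs produce byte-identical CSV/JSON.

`pixel_size_um` (default 0.147 µm/px) is a configuration value; it is
never inferred from hardware names. The HDF5 event store keeps crops,
masks and contours as ragged datasets (flattened values plus
per-event shapes): crops genuinely vary in size and padding would
corrupt morphometry. The layout parallels the community `.rtdc`
convention without claiming bit-compatibility.
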