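# Methods

## The analysis model

`punctacoloc` performs object-based colocalization: it treats each channel
of a fluorescence image as a set of discrete puncta (small, roughly
circular protein clusters) and counts a structural synapse wherever a
red-channel punctum and a green-channel punctum overlap spatially. This is
appropriate when the *position* of synaptic compartments carries the
biology; when marker *abundance* is what changes, intensity-based
correlation measures on unthresholded images are the better tool and are
deliberately out of scope here. Two further assumptions are inherited from
the object-based approach: signals must be punctate rather than diffuse,
and objects within one channel must be non-overlapping so they can be
counted independently. The pipeline is strictly 2D — z-stacks are collapsed
into grouped maximum projections and each projection is analysed as an
independent image; full 3D reconstruction is not attempted.

### Image normalisation

All analysis runs on an 8-bit, three-plane RGB working copy. Higher bit
depths are rescaled over the *nominal* range of the dtype
(`round_half_up(v · 255 / (2^bits − 1))`), not per-image min–max, so the
conversion is data independent: two images with different histograms map
through the same transfer function. Per-image contrast stretching exists
only as the explicit, opt-in brightness-normalisation step. The 8-bit
reduction coarsens the available threshold values (256 instead of 65 536)
but does not affect spatial resolution.

Grouped max projection partitions the stack's planes, in acquisition
order, into consecutive groups of `group_size` (default 3, which turns a
15-plane stack at ~0.34 µm z-step into five ~1 µm projections). A trailing
remainder group is dropped with a warning rather than projected: a partial
projection would have a different effective depth than its siblings and
would bias per-projection densities.

### Preprocessing (off by default)

Noise reduction = rolling-ball background subtraction followed by Gaussian
blur; brightness normalisation = linear rescale fixing the fraction of
saturated pixels. Defaults: ball radius 50 px and blur sigma 1 px (both
well above/below typical punctum scales, so puncta survive), saturated
fraction 0.0035. These steps modify the data the analysis sees, so they
are disabled unless requested, the applied configuration is echoed into
the run log, and they should be held constant within an experiment.

### Thresholding

The foreground test is `intensity >= threshold` (inclusive, ImageJ-style).
Four methods share one audit contract — every mask-producing call appends
an `image, channel, method, value` record, and the emitted `thresholds.csv`
can be fed back through the `from_file` method to replay a run
byte-exactly. Interactive manual thresholding is intentionally replaced by
this value table: it preserves the reproducibility contract without a GUI.

The statistical method is a simplified spot detector in the SynQuant
spirit. Candidate objects are connected components of `plane >= level` for
every intensity level present, swept from high to low; each candidate is
accepted iff its area lies in `[min_size, max_size]` (default 10–100 px²),
its bounding-box fill is ≥ `min_fill` (0.5), its bounding-box aspect ratio
is ≤ `max_wh_ratio` (4), and its contrast z-score against a 2-px
surrounding ring,

    z = (μ_in − μ_ring) / (σ_noise · √(1/n_in + 1/n_ring)),

reaches `z_threshold` (default 10, with `σ_noise` = 12 intensity units).
Overlapping candidates from different levels are resolved greedily by
descending z, so every pixel belongs to the strongest object claiming it.
Because intensity offsets cancel in z, the mask is invariant to adding a
constant to the plane (up to saturation). Numerical shortcuts: the sweep
stops once a level covers more than half the plane (no compact small
object can still emerge below that), and a candidate whose bounding box
and area are unchanged from a higher level is not re-scored. The
`z_axis_multiplier` parameter is accepted for configuration parity and
ignored with a warning (it only matters in 3D). This is a
re-implementation from the parameter semantics, not a port of the original
component-tree algorithm, and is validated only against this package's
contract.

External probability masks (e.g. from a user-trained pixel classifier such
as ilastik) enter through `external_mask`, binarised at probability 0.5;
classifier training itself is out of scope.

### Puncta detection

Puncta are 8-connected components (matching the common particle-analysis
default) filtered by per-channel area limits (default min 4 px², no max)
and by the ROI: membership is decided by the **centroid**, so each punctum
is counted exactly once and the rule is unambiguous at ROI edges. Reported
measurements: centroid, area `A`, equivalent radius `√(A/π)`, and
circularity `4πA/P²` clamped to ≤ 1, with a single pixel defined as 1.0.
The perimeter `P` is the boundary crack length with corner correction:
count every pixel edge exposed to background, then shorten each 90° corner
by `(2 − √2)/2`. On a rasterised disc of radius ~10 px this lands within
~4 % of `2πr` (circularity ≈ 0.93), while a 1-px line is properly
penalised (≈ 0.29); the naive crack length without correction would score
the disc at ≈ 0.69. Circularity is estimator-dependent, so this one
estimator is used everywhere.

### Colocalization

*Circular approximation*: every red×green pair is tested;
`d < r₁ + r₂` (strict — tangency has zero overlap area and does not
count). The overlap area is the circle–circle lens, computed by the
sector-minus-triangle construction: with `a₁ = (d² + r₁² − r₂²)/(2d)` the
signed distance from center 1 to the intersection chord, `a₂ = d − a₁`,
and `h = √(r₁² − a₁²)` the half-chord,

    A = (r₁² · acos(a₁/r₁) − a₁h) + (r₂² · acos(a₂/r₂) − a₂h),

with the containment (`π·min(r₁,r₂)²`) and separation (0) limits handled
exactly. Counting is per qualifying *pair* — a punctum may appear in
several records when puncta are dense — and the Summary reports both the
pair count and a deduplicated count (distinct red puncta involved). The
record center is the midpoint of the intersection chord,
`c₁ + (d² + r₁² − r₂²)/(2d²) · (c₂ − c₁)`.

*Pixel overlap*: the logical AND of the 2 or 3 channel masks; each
8-connected component of the AND image with area ≥ `coloc_min_size`
(default 1) and centroid inside the ROI is one record. The ROI filter is
applied to the overlap components, not the input masks (input puncta
counts in the Summary are still ROI-filtered). This method handles
non-circular objects and triple colocalization, which the circular method
does not.

## The simulated benchmark

The generator emulates a two-channel synapse-image validation set: each
1024×1024 image holds 1000 puncta positions — 334 red-only, 333
green-only, 333 with a red and a green punctum pasted at the same location
to form a synapse (667 red and 666 green puncta in total) — on an i.i.d.
Gaussian background whose mean and SD are a reference histogram
(mean 20, SD 12) scaled by a noise multiplier from
{0.00, 0.25, 0.50, 0.75, 1.00}; the benchmark holds 20 images per level,
100 in total. Multiplier 0 is a black background, 0.25–0.75 resemble
realistic acquisitions, and 1.00 — since the reference histogram includes
true signal — is deliberately worse background than any acceptable real
image.

Templates are synthesised Gaussian-profile discs (10 per channel): support
radius drawn uniformly from 1–3 px, profile sigma `r/2` (so the support
edge keeps ~13.5 % of the peak and survives any threshold ≥ 1), peak drawn
uniformly from 120–230. The radius range emulates 0.2–1 µm synaptic puncta
at a confocal pixel size of ~0.126 µm/px (footprint diameters 3–7 px ≈
0.38–0.88 µm), sized so every punctum also clears the default 4 px²
minimum-size filter. Real validation sets crop templates from
micrographs; synthetic stamps keep the package self-contained, at the cost
of not reproducing real point-spread-function asymmetries — a reason the
benchmark validates the *pipeline geometry*, not any specific antibody.

Positions are anchored by the top-left corner of the pasted bounding box,
sampled uniformly with rejection so that no two boxes of the same channel
overlap (the pipeline assumes non-overlapping objects per channel);
placement gives up with a clear error after 10⁴ rejected draws per
punctum. Cross-channel overlap is exactly the designed "both" positions
plus chance adjacency between red-only and green-only puncta — kept, as in
real images, which is why measured precision sits slightly below 1 even on
noise-free images. Pasting takes the pixelwise max of stamp and
background, so noise never darkens a punctum. At a "both" position the two
channels' stamps share the anchor but may differ in size, producing
varying degrees of partial overlap; the truth center used for scoring is
the midpoint of the two stamp centers. Templates derive from the
configuration seed (one pool per benchmark), while positions and noise
derive from the per-image seed, so every image is exactly reproducible
from the manifest.

Scoring matches detections to true synapse centers greedily by ascending
distance, one-to-one, within a tolerance (default 5 px — about one
template diameter; the matching rule is a package choice, documented
because published validations rarely state theirs). TP/FP/FN then give
recall and precision, with empty denominators defined as 1. The
distance-sorted greedy is order-independent and agrees with brute-force
maximum matching on small instances (tested).

## Batch driver and outputs

`run_experiment` discovers images non-recursively inside the subfolders of
the experiment directory (at least one subfolder is required; file
extensions tif/tiff/png/bmp; names must contain a single `.`). Failures
are isolated per image and listed at the end of the run log. Outputs:
`Summary.csv` (one row per analysed image/projection: puncta counts,
record and deduplicated colocalization counts, thresholds, minimum-size
settings, ROI area), `thresholds.csv`, per-channel and colocalization
puncta tables, a `_colocs` overlay (white 3-px discs at record centers)
and per-channel `_thresholded` masks, saved losslessly as PNG. All CSVs
declare the coordinate convention (0-based, x = column, y = row, origin
top-left) in a header comment. Two runs with the same configuration are
byte-identical; the Summary's threshold columns store the numeric value
when one exists (method tag otherwise) precisely so that a `from_file`
replay of a fixed-value run reproduces `Summary.csv` byte-for-byte.

## Problem sizes used in the test suite

The shipped tests validate the full benchmark bookkeeping at its native
size (100 × 1024² images) and run detection-fidelity and concordance
checks on 20 noise-free plus 20 maximum-noise images; unit tests use
64–256 px fixtures. Monte-Carlo verification of the lens area uses 2×10⁷
rejection-sampling points per case; the closed-form cross-check uses 10⁴
random radius/distance triples.

## Known limitations

- 2D only; colocalization across optical sections is not modelled.
- A punctum is approximated by its equivalent circle in circular mode;
  elongated or merged objects are better served by pixel mode.
- No watershed splitting of touching puncta — the non-overlap assumption
  is the user's responsibility via staining/imaging quality.
- The synthetic benchmark does not emulate autofluorescence gradients,
  uneven illumination, bleed-through, or real PSF shapes; passing it shows
  the geometry and bookkeeping are right, not that a threshold choice will
  work on any particular real dataset.
- Proprietary microscope formats (.lif, .oib) must be converted to TIFF
  upstream; CMYK is supported only through explicit channel picking.
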