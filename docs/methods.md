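# Methods

This note documents the models, numerical choices and known limitations of
`lodgekit`, in the order data flows through the toolkit.

## Sensor model and file conventions

The toolkit targets six-band agricultural multi-spectral cameras in the
MicaSense RedEdge-P layout: five narrow bands — blue (475 nm), green
(560 nm), red (668 nm), red edge (717 nm), near-infrared (842 nm) — at one
resolution (1456x1088 native) and a broadband panchromatic channel at a
higher resolution (2464x2056 native), one single-channel 16-bit TIFF per
band per shot, named `<capture>_<band>.tif`. Integer codes are normalised
by the dtype maximum (65535, not 65536), so the largest code maps exactly
to 1.0 and loading is monotone with `{0, max} -> {0, 1}`.

Bounding boxes use 0-based, half-open pixel rectangles (x right, y down),
making integer-corner areas exact. On disk the YOLO text dialect is used
(normalised centre/size, 0-based class indices, 6-decimal precision); the
in-memory severity classes are 1-based, matching the 1-9 field rating
scale, and the shift is applied only at the I/O boundary. Round-tripping a
box through write/read moves each corner by at most ~1.5 quantisation steps
of the larger image dimension (≈ 0.002 px at 1456x1088).

## Registration

**Metric.** Alignment quality of a band pair is the mutual information (in
bits; the argmax is base-invariant) of their joint intensity histogram: 64
equal-width bins per axis over [0, 1], intensity 1.0 assigned to the last
bin. Each pixel contributes its Gaussian weight
`w(x,y) = exp(−((x−x_c)² + (y−y_c)²)/2σ²)` to one joint cell; `σ` defaults
to `min(H, W)/4` and the centre to the image centre. The weighting focuses
the metric on the image centre, where scene overlap is guaranteed under
small rigid motions; `weighted=False` gives plain MI. Pixels whose warped
source falls outside the moving image are excluded from the histogram
entirely — a constant fill value would add a spurious histogram mode and
bias the metric.

**Transform.** Rigid only: `p' = R(θ)(p − c) + c + t` with the rotation
centre `c` fixed at the image centre. Applying a transform to an image
moves its content along the point map; resampling is inverse-mapped
bilinear interpolation with a validity mask.

**Optimiser.** A (1+1)-evolution strategy on `(θ, t_x, t_y)`: proposals are
`parent + radius · scales · N(0, I)` from a seeded generator; strictly
improving proposals are accepted and multiply the radius by the growth
factor 1.002, rejections divide by the same factor; the search stops below
radius 1.5·10⁻⁶ or at 500 iterations. The radius lives in a normalised
parameter space with step scales `(1 rad, diag px, diag px)` where `diag`
is the image diagonal — without such a scaling a single radius for radians
and pixels would be meaningless. In practice the radius cannot shrink from
2·10⁻⁴ to 1.5·10⁻⁶ within 500 iterations (1.002⁻⁵⁰⁰ ≈ 0.37), so runs end
at the iteration cap with `converged=False`; the best-seen transform is
still returned and the acceptance-only trace is monotone by construction.

**Pyramid.** Registration runs coarse-to-fine over a 3-level image pyramid
(factor 2 per level, anti-aliased downsampling); each finer level starts
from the previous estimate with translations doubled, and each level's
optimiser run derives its seed from the base seed plus the level index, so
the whole procedure is bit-reproducible.

**Noise artifact and pre-smoothing.** Binned-histogram MI with bilinear
resampling has a known lattice artifact on noisy imagery: interpolation at
off-grid offsets averages independent sensor noise, lowering the warped
image's conditional entropy and lifting MI at half-pixel misalignments.
For near-pure translations this biases the optimum by up to half a pixel.
`register_pair` therefore pre-smooths both images with a small Gaussian
(`presmooth_sigma = 0.75` px; 0 disables) before metric evaluation:
correlating the noise over neighbouring pixels removes the variance
difference between on- and off-grid sampling without displacing the peak.
On the synthetic benchmark this took translation errors from a ~0.5 px
plateau to ~0.1 px typical.

**Whole captures.** `register_capture` aligns every band onto the green
band (band 2), the reference that pairs best against both the visible and
NIR ends of the spectrum. The panchromatic band, when present, is first
bilinearly resampled to the reference shape and then registered like any
other band. A band that fails to register still produces an output (warped
by its best-seen transform) with its convergence flag recorded; the capture
is never discarded wholesale.

**Performance.** The metric evaluation (inverse-map, bilinear sample,
weighted histogram accumulation) is a single fused numba-compiled pass with
a vectorised numpy fallback; the reference image's bin indices and the
weight map are cached per pyramid level. Registering one 364x272 band pair
(1500 metric evaluations over 3 levels) takes well under a second after JIT
warm-up.

## Enhancement presets

**Haze & gamma.** Per channel `c` of a unit-range three-channel image:

    a_c      = 0.25 · percentile(I_c, 1)
    t_c(x,y) = 1[I > a_c] · (1 + 0.2 (I − a_c)) − 0.7,  clipped below at 1e-6
    b_c      = mean over pixels of (I − a_c) · t_c^0.6
    out      = b_c · t_c^0.6,  rescaled so the channel maximum maps to 1

Three resolutions make this chain computable and are each toggleable in
`HazeGammaParams`: the indicator is multiplicative; `t_c` is floored at a
small positive value before the fractional power (with the 0.7 offset,
negative `t_c` is common, and fractional powers of negatives are
undefined); and the final rescale bounds the otherwise unbounded product.
Percentiles use linear interpolation between order statistics. The map is
monotone within each channel (the indicator step, the floor and the
positive gamma all preserve order when `b_c > 0`, which holds for any
non-degenerate channel).

**Contrast stretch.** Per channel, a linear map of `[I_min,c, I_max,c]`
onto `[0, 255]`, limits computed separately for each band (channel min and
max by default; explicitly narrower limits clip). Endpoints are exact:
channel min -> 0, max -> 255, midpoint -> 127.5. The operation is
idempotent on already-stretched channels.

## Composites and indices

Composites are pure channel stacking — `(3, 2, 1)` gives true colour,
`(4, 2, 1)` replaces the red channel with red edge — so extracting a
channel returns the source band bit-exactly. Indices are per-pixel ratios
(B, G, R, NIR = bands 1, 2, 3, 5):

    NDVI = (NIR − R) / (NIR + R)
    VARI = (G − R) / (G + R − B)
    GARI = (NIR − (G − (B − R))) / (NIR + (G − (B − R)))
    SABI = (NIR − R) / (B + G)

Pixels where `|denominator| < 1e-9` (VARI's `G + R − B` can vanish on real
reflectances) are masked invalid and zero-filled rather than divided. GARI
also circulates with the denominator `NIR − (G + (B − R))`; the standard
form above is the default and `as_printed=True` selects the alternative —
both are exposed rather than guessing which a given source intended.

## Detection evaluation

Matching is greedy in descending confidence: each detection claims the
unmatched ground truth with the highest IoU at or above the threshold.
All ties break deterministically — confidence ties by input order, IoU ties
toward the lower ground-truth index — so every metric is bit-reproducible
and invariant to image order. AP uses all-point (continuous)
interpolation: one PR point per detection in the global confidence sweep,
sentinel points at recall 0 (precision 1) and recall 1 (precision 0), a
monotone non-increasing precision envelope, integrated over recall
change-points. This is the convention of the YOLO detector family whose
output files the toolkit consumes. mAP averages AP over classes with at
least one ground-truth box; classes absent from the ground truth are
excluded from the mean, not counted as zero. mAP@0.5:0.95 averages mAP
over the ten IoU thresholds 0.50, 0.55, …, 0.95.

The confusion matrix uses class-agnostic greedy matching (so cross-class
confusions are visible off the diagonal) after confidence filtering: a
matched pair increments (gt class, detected class); unmatched truths go to
the background column, unmatched detections to the background row. Raw
counts are emitted; normalisation is left to the consumer. True negatives
are not accounted — the concept is undefined for detection.

NMS is greedy and class-aware by default (IoU threshold 0.45,
configurable); the pipeline applies confidence filtering and NMS to
external predictions before scoring.

## Synthetic scenes

The generator emulates a UAV frame over a breeding trial: a `rows x cols`
grid of rectangular plots (defaults: 4x5 plots of 56x40 px with a 12 px
gap, centred) on a soil background, at a configurable fraction of native
sensor resolution (default 0.25, i.e. 364x272 spectral / 616x514
panchromatic, chosen so the full registration suite runs in about a
minute). Each plot carries a severity class; severity maps to a lodged-area
fraction `f(c) = 0.75 (c − 1)/8` for classes 1-8 and `f(9) = 0.875`,
anchored at the two quantitative points of the field scale (class 1: no
lodging; class 9: more than 75 % flat) with a declared — not inferred —
linear ramp between. The lodged patch is a slab from the plot's top edge,
so its rasterised area matches `f` to within ~2 %.

Reflectance is piecewise constant per material with fixed plausible band
profiles (upright canopy: NIR-bright, red-dark; lodged canopy: brighter in
the visible, darker in NIR; soil intermediate), modulated by a shared
smooth texture field (a sum of 24 random sinusoids with 20-80 px
wavelengths, unit variance, 0.25 amplitude) standing in for canopy-density
and illumination variation. Each band is rendered by point-sampling this
continuous scene in its own misaligned frame — the band's pixel grid is
pulled back through the inverse of its true rigid transform and the scene
function evaluated there, exactly as a physically offset sensor images the
same field — then independent Gaussian sensor noise (sd 0.01, about 1 % of
full scale) is added. Point-sampling rather than warping a rendered raster
keeps the reference and moving bands statistically symmetric; warping would
smooth the moving band and measurably displace the MI optimum. Misalignments
default to uniform draws within ±2° and ±10 px (the green reference band is
always at identity); all randomness derives from one seed and regeneration
is bit-identical.

What the generator does **not** model: perspective and lens distortion
(real band offsets are only approximately rigid), radiometric calibration
and illumination gradients, plant-scale canopy texture, plot-edge
raggedness, and any correlation between severity and canopy height.
Passing tests therefore demonstrate correctness of the algorithms under
the stated rigid-motion/noise model, not field-ready accuracy claims on
real imagery.

`generate_detections` degrades truth boxes into detector-like output:
independent misses at `miss_rate`, uniform corner jitter within
`±jitter_px`, confidences from a two-regime model (correct boxes uniform in
[0.6, 0.99], spurious in [0.05, 0.4]), and spurious random-class boxes
added with probability `spurious_rate` per truth box.

## Pipeline

`run_preprocess` discovers captures by filename convention, registers each
to the reference band, composes the configured band order, applies the
chosen preset, optionally resizes the composite to a detector-ready square
(640 px default; enhancement precedes the resize, configurable by
resizing the input instead), and writes aligned 16-bit TIFFs, an 8-bit
composite and a JSON transform sidecar. Failures are isolated per capture
and recorded in the manifest, which contains no timestamps so identical
configurations reproduce byte-identical manifests. `run_evaluate` reads
ground-truth and prediction YOLO files matched by stem, warns on
predictions without ground truth (scored as all-false-positive), filters
and deduplicates predictions, and writes the JSON report. The train/val/
test splitter (70/10/20 by default) is a seeded list partitioner for users
who train their own detector; the toolkit itself never runs one.

## Test and benchmark sizes

The test suite exercises registration at two scales: half-scale fixtures
(182x136, proportionally scaled misalignments) for fast unit tests, where
attainable rotation precision is coarser because angular sensitivity grows
with image extent, and the quarter-scale study geometry (364x272, ±10 px,
±2°) for the 20-scene truth-recovery benchmark, where ≥ 90 % of band
registrations must land within 0.5 px and 0.2°. Metric and evaluation
operations are validated against independent brute-force oracles (double
loops, threshold enumeration, set-based NMS) at 1e-12 / 1e-9 tolerances on
hundreds of seeded random instances.
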