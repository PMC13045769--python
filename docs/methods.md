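# Methods

## Image model and conventions

An image is a rectangular grid of finite Z values with strictly
increasing physical X (per column) and Y (per row) axes. Grid row 0
holds the smallest Y and column 0 the smallest X; PNG rasters are
emitted top-down, i.e. vertically flipped relative to the physical Y
axis. On write, XYZ ASCII rows are emitted with X varying fastest
(line-by-line acquisition order); on read, points are placed by their
(X, Y) coordinates, so any complete-grid permutation of lines parses
identically and incomplete grids are rejected with the first missing
point named. Values are printed with 10 significant digits, which
bounds the round-trip error of every downstream text exchange.

The `.s94` container implemented here is a fixed little-endian layout
(magic `S94F`, version, cols, rows, X/Y scan sizes, a Z scale factor,
then row-major int16 counts). It makes the raw-to-ASCII converter fully
testable offline; vendor files in other `.s94` layouts are out of scope.

## Filtering

**Flattening.** Every image row is independently fitted with a
least-squares degree-2 polynomial in the physical X coordinate, which is
subtracted. Residuals are orthogonal to {1, X, X²} per row, the
operation is idempotent, and rows with fewer than three points are
rejected rather than silently degraded. Per-row fitting removes sample
tilt and slow Z-piezo drift that varies from line to line.

**Equalisation.** The lower/upper percentile values L, U of the image's
Z distribution (linear interpolation between order statistics — frozen
because clip counts depend on the convention) become hard limits; values
outside are reassigned to the nearest limit and the image is shifted so
its minimum is exactly 0. Defaults are the (1, 99) percentile pair,
exposed independently per tail. Ordering of pixel values is never
inverted and unclipped differences are preserved. A constant image
equalises to all zeros.

Batch filtering processes a folder in lexicographic order and always
applies flattening before equalisation: tilt inflates the apparent Z
spread, which would corrupt the percentile limits if clipping ran first.

## GMM segmentation

Pixel values of a filtered monolayer image concentrate at a few discrete
levels (background/ethyl regions, dark molecules, bright molecules), so
the Z sample is fitted with a K-component univariate Gaussian mixture by
expectation–maximisation (scikit-learn backend). Frozen numerical
settings: k-means initialisation seeded explicitly, per-sample
log-likelihood tolerance 1e-6, at most 500 iterations, variance floor
1e-12 against component collapse. A fixed seed therefore yields
bit-identical fits. Components are reported sorted by mean, with
weights, variances and the label grid permuted consistently; ties are
broken by a stable sort.

The component weight πₖ is reported as the cluster's "responsibility" —
its share of the total distribution — and the per-pixel posterior is
used only to assign labels (argmax rule). Heights are referenced to the
lowest cluster: with three clusters over (background, dark, bright),
μ₂ − μ₁ and μ₃ − μ₁ are the dark- and bright-molecule heights. Cluster
count selection stays manual: a sweep fits K = 2..K_max independently,
reports log-likelihoods and emits a segmented control sheet (grey level
round(255·k/(K−1)) per ascending cluster) for visual inspection; no
information criterion is auto-applied. In a series every frame is fitted
independently — no warm starts — so a frame's result never depends on
its neighbours.

## Fixed-threshold segmentation

The mean Z range over the first N frames (the calibration sample,
assumed acquired at equilibrium) is divided into n equal intervals
anchored at Z = 0, matching upstream equalisation's zero rebasing.
Boundaries are frozen after calibration and never recomputed. Labelling
is a single vectorised binary search — linear in pixel count, with no
iterative optimisation — which is the method's advantage over the GMM
for videos of hundreds of frames. Intervals are half-open [low, high);
the top interval is closed above at +∞ so frames whose range exceeds
the calibration keep all pixels counted (fractions always sum to 1).
Zero-extension calibration frames are excluded from the average with a
logged warning instead of poisoning the scheme.

## Drift correction

Anchor deviations dᵢ = (xᵢ − x₀, yᵢ − y₀) relative to the first tracked
frame are fitted per axis as a smooth function of frame index — a
natural cubic spline through the anchors (natural boundary conditions;
with two anchors this degenerates to the linear segment) or a
least-squares polynomial — and evaluated at every frame. The fit is
applied to the anchor deviations directly rather than to a densified
interpolation of them; the target curve is the same and fewer smoothing
artefacts arise. Beyond the anchored span the boundary value is held
constant, because spline and polynomial extrapolation diverge; affected
frames are logged. The reference frame's deviation is forced to exactly
(0, 0).

Frames are rigidly translated by the negated deviation rounded half-up
to whole pixels: no resampling, so the multiset of non-zero Z values is
preserved bit-exactly. Frames must be pre-expanded with a zero border
wide enough for the largest translation (heuristic default:
1.5 × the largest anchor deviation); a translation that would push data
off the canvas raises an error naming the frame and the minimum extra
pad. Sub-pixel correction would require interpolation and is
deliberately not attempted; residual scatter of a stationary feature is
therefore at the ±1 px rounding scale.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies
on, not the physics of tunnelling. Molecules are isotropic flat-topped
blobs — a plateau at the class height offset with a Gaussian rolloff
edge of width `blob_sigma` (default 0.5 px), truncated 3σ past the
plateau — on a square or triangular lattice (default triangular,
spacing 16 px on a 128×128 grid). The plateau is essential: it is what
makes the pixel-height distribution multimodal at the programmed class
offsets, the property every segmentation test measures; a pure Gaussian
bump would place almost no pixels at the class height. The default
plateau radius fills half a lattice spacing minus the 3σ rolloff,
emulating a close-packed monolayer in which the "background" class is
itself a molecular region (ethyl groups) rather than bare substrate.
Supports never overlap (enforced by a spacing check), so with zero
noise and zero backgrounds the Z value at each molecule centre equals
its class offset exactly, and the ground-truth record (centres, classes,
per-row background coefficients, outlier positions) predicts the
expected cluster means, pixel fractions and interval occupancies without
running the toolkit.

Default conditions: three classes at 0/+25/+45 pm with probabilities
0.5/0.3/0.2 and 5 pm additive Gaussian noise — the height scale and
class structure of an Fe-porphyrin monolayer with its two molecular
contrast states over the ligand background. Outliers are isolated
single-pixel spikes of ±`outlier_magnitude` (default 200 pm), the
failure mode equalisation exists to suppress. Per-row backgrounds are
a + b·x + c·x² with coefficients drawn uniformly from configurable
ranges (zero by default). One global seed drives independent substreams
for placement/classes, backgrounds, noise and outliers, so changing one
knob never reshuffles the others.

Drifting series translate the frame-0 scene by a smooth trajectory
(default: per-axis sine ramps reaching 12 and 8 px; any callable pinned
to (0, 0) at t = 0 is accepted), embed it in a zero pad and add fresh
per-frame noise. The optional dim schedule emulates a potential step
that darkens the monolayer: from a given frame onward a seeded, nested
subset of the middle-class molecules (default 60 %, ramped over a few
frames) drops to the background level. Dimming per molecule — rather
than lowering the whole class's offset — moves mixture *weight* from the
middle to the lowest component while the component means stay put, which
is the signature an adaptive GMM and the frozen thresholds both report
as rising dark-pixel and falling grey-pixel fractions; shifting the
whole class's mean would instead merge components and produce no clean
fraction response.

## What the fixtures do and do not show

Passing tests demonstrate that the algebra, the statistics and the
bookkeeping of the chain are correct on data that honours the model's
assumptions: discrete height classes, line-wise smooth backgrounds,
rigid translational drift, stationary noise. They do not demonstrate
robustness to what real EC-STM data adds: intra-frame creep distortion,
tip changes mid-series, molecular internal structure, non-Gaussian
noise, or partial molecular order. One fixture-scale caveat is worth
noting: with molecules whose plateaus span a large fraction of a scan
line (as in the default 128 px fixtures), per-line flattening removes
part of the molecular signal itself and biases recovered heights; on
instrument-scale images, where many molecules average out along each
line, this bias is small. Height-recovery tests therefore filter with
equalisation alone.

## Problem sizes

Tests and the acceptance script run on 128×128 images (≈ 60 molecules),
series of 12–60 frames, and 50,000-point mixture samples — sizes at
which every stochastic check is comfortably stable while the whole
suite completes in well under a minute on a laptop-class core.
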