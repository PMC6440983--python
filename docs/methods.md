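# Methods

## The tracking problem and its abstraction

A mouse in an overhead open-field recording is reduced, frame by frame, to a
directed ellipse with six parameters: center `(x, y)` in pixels, full major
and minor axis lengths, and the heading angle θ encoded as `(sin θ, cos θ)`.
Coordinates follow image convention (origin top-left, `x` = column rightward,
`y` = row downward) but angles are measured on a *display-space* polar grid —
0° points right, angles grow counterclockwise as seen on screen — so all
trigonometry internally negates the row axis. This matches the semantics of
the up/left/down/right direction labels. The sin/cos encoding avoids the
0°/360° discontinuity in both regression targets and decoded outputs.

A silhouette determines orientation only modulo 180°. The head direction is
recovered with a four-class quadrant prediction over the half-open spans
[45°,135°) = up, [135°,225°) = left, [225°,315°) = down, [315°,45°) = right.
The span boundaries sit *between* the cardinal headings, so a mouse running
straight along a wall does not flicker between classes. Spans are
lower-inclusive so the four classes partition the circle exactly.
`resolve_direction` picks, of the two candidates θ and θ+180°, the one
circularly closer to the chosen span's center; this equals span membership
whenever a candidate lies strictly inside the span and degrades gracefully on
the boundary.

## Ellipse fit

The mask→ellipse fit is the equivalent-second-moment ellipse: the center is
the foreground centroid and the full axes are `4·√λ` for the eigenvalues λ of
the pixel covariance (population, pixel centers at integer coordinates), with
the orientation given by the principal eigenvector. For a filled disc of
radius r this yields axis 2r exactly in the continuum limit. The fit is
closed-form, deterministic, and — on convex blobs — behaves like a
contour-based least-squares fit. It is applied after 8-connected
largest-component selection (single-animal assumption: the largest blob is
the mouse). An empty mask yields the first-class `NO_DETECTION` value, which
propagates through tracks and metrics as a missing frame and is never
interpolated.

Accuracy is resolution-limited: below a minor axis of about 8 px the
rasterized silhouette is too coarse for any moment fit to recover axes within
a few percent. The synthetic-data generator therefore never emits mice with a
minor axis under 8 px (see below).

## Network families

All three families consume `(N, 1, S, S)` frames normalized to [0, 1].
At the reference input size S = 480 the shape schedule is:

* **Segmentation (default tracker).** Encoder: six 5×5 conv + batch-norm +
  ReLU blocks with 2×2 max-pooling after the first five, filter schedule
  8, 16, 32, 64, 128, 128, reaching 15×15×128; then a 5×5 conv to 256, a 3×3
  stride-3 max-pool and a final 5×5 conv to the 5×5×512 bottleneck. Decoder:
  six strided transposed convolutions (5×5; stride 3 for the 5→15 stage,
  stride 2 thereafter) with *no* ReLU, each followed by a summation skip
  junction adding the pre-pool encoder activation of matching shape
  (channel depths mirror the encoder, so no projections are needed), closed
  by a 1×1 conv to two channels (background/foreground) with a softmax
  across the two. Direction head: two 5×5 conv+BN+ReLU blocks (128, 64) on
  the bottleneck, flattened into one fully connected layer with 4 outputs.
  Loss: mean per-pixel 2-class cross entropy + 4-class direction cross
  entropy, summed. Inference thresholds the foreground softmax at 0.5,
  keeps the largest component, fits the moment ellipse and resolves the
  direction with the head's argmax.
* **Binned classification.** Five [3×3 conv, 3×3 conv, 2×2 pool] ReLU blocks,
  filters 16→256, terminal 15×15×256; the flattened features feed one
  independent fully connected layer per parameter, sized by that parameter's
  bin count (range/resolution; x at 1 px resolution over 0–480 gives 480
  bins). Loss: summed per-head categorical cross entropy. Decoding takes the
  argmax bin (ties to the lowest index) and returns the *bin center*
  (min + (i + 0.5)·resolution). The default configuration predicts the
  center location (x, y) only; axis and angle heads can be added.
* **Direct regression.** A pluggable feature encoder (default: the binned
  family's VGG-style encoder; any encoder meeting the flatten contract
  works) followed by fully connected layers to exactly 6 outputs. Loss: mean
  squared error on `(x, y, major, minor, sin θ, cos θ)`. Decoding normalizes
  the (sin, cos) pair before atan2, clamps negative axes to zero with a
  warning, and swaps reversed axes (rotating θ by 90°) so major ≥ minor.

The encoder filter schedule holds at 128 for the sixth block: doubling
throughout is arithmetically incompatible with a 15×15×128 terminal from a
480 px input (480/2⁵ = 15), and the printed shapes win. Any input size with
`S % 32 == 0` and `(S/32) % 3 == 0` (e.g. 96) follows the same schedule
proportionally, which is what keeps desk-scale tests honest: shapes are
asserted relative to the input, not hard-coded.

The layer stack (im2col convolution, zero-stuffed-adjoint transposed
convolution, batch norm with running statistics, max-pool, dense) is
implemented in-repo in numpy with explicit backprop and is
finite-difference-checked in the test suite. Weight init is fan-in-scaled
normal, fully seeded; batch norm uses momentum 0.1, eps 1e-5, and running
statistics at inference.

## Augmentation

Three label-consistent families:

* the 8 symmetries of the square (identity, rotations by 90°/180°/270°,
  horizontal, vertical and both diagonal mirrors — the dihedral group of
  order 8, an immediate 8× multiplier). Ellipse centers, angles and
  quadrant labels are transported exactly; a rasterize–flip–refit oracle
  verifies the transport in the tests. Diagonal reflections require square
  frames; non-square input is rejected.
* random rigid transforms: rotation about the frame center (display-CCW)
  plus per-axis translation, both uniform on ±range. Frames warp bilinearly
  with border replication, masks with nearest-neighbor (preserving
  binarity); the ellipse is mapped by the same transform and the direction
  label recomputed.
* random photometrics: per-pixel Gaussian noise, additive brightness, and
  multiplicative contrast pivoting at mid-gray 128
  (`clip(c·(f−128)+128+b+n, 0, 255)`), all normal. Labels untouched.

Defaults: rotation ±10°, translation ±20 px, noise σ 3, brightness σ 10,
contrast σ 0.05 (at 96 px training the translation is scaled to ±10 px so
the mouse cannot be pushed outside the frame, which would desynchronize mask
and ellipse label). All randomness flows through one explicit seeded
generator; a training draw samples one symmetry uniformly, then a rigid
transform, then photometrics.

## Synthetic arena

The renderer produces frames with *exact* ground truth: the mask is the
rasterized body ellipse itself, so there is no rendering/label drift by
construction. It emulates the features that defeat background subtraction
in real arenas: flat, radial-gradient, bedding-textured (smoothed noise) and
glare-banded (additive bright vertical bands — sufficient to break naive
thresholding without ray-tracing reflections) backgrounds; configurable
mouse/background contrast; a tail drawn in the image but *excluded* from the
mask (mirroring the annotation convention that tails are removed for a
better ellipse fit — and, usefully, the rump-side tail is the only
head/rump asymmetry, so it is the direction cue a network can learn);
optional cast shadow; movable bright spheres that are nudged away whenever
the walking mouse would touch them; slow sinusoidal lighting drift; and
sensor noise. Presets black / gray / albino / piebald / 24h / komp2 differ
only in their `SceneConfig` and span an axis of segmentation difficulty
(albino = low contrast, piebald = two-tone body, 24h = bedding + lighting
drift, komp2 = glare + shadow).

Poses are sampled uniformly: major axis uniform at 10–16% of the frame side
(a mouse at 8 px/cm zoom occupies roughly that fraction of a 480 px arena),
aspect ratio uniform on 0.30–0.50, position uniform over placements fully
inside the frame, heading uniform on the circle. At small frame sizes the
size range is scaled up so the minor axis stays ≥ 8 px (the fit's resolution
floor); this compresses the arena-to-mouse ratio at 96 px, which is the
price of a desk-scale benchmark with meaningful labels. Videos follow a
correlated random walk (Gaussian step length and turning rate) whose heading
reflects off the walls *before* each move, so every displacement has exactly
the drawn step length and total distance has a closed form when the step
spread is zero.

What the generator does **not** emulate: postural deformation (rearing,
grooming, mid-jump), fur texture, perspective distortion, motion blur, and
multi-animal scenes. Passing the desk-scale benchmark therefore demonstrates
that the implementation trains and tracks correctly, not that it matches
published accuracy on real videos — full-scale numbers (sub-pixel validation
center error, IoU above 0.8 on real annotations, beam-break concordance)
depend on a large annotated video corpus that this package deliberately does
not ship.

## Evaluation metrics

* **Center (hypotenuse) error**: Euclidean distance between centers, px.
* **IoU**: |a∩b|/|a∪b| on masks (segmentation family) or rasterized
  ellipses (families producing a full fit). Two empty masks score 1.0
  (perfect agreement on absence), one empty scores 0.0; real evaluations
  never hit the empty–empty case.
* **Cumulative relative distance error**: per whole minute m (bins of
  `floor(frame/(60·fps))`, displacement credited to the earlier frame's bin,
  trailing partial minute kept) Σ|d_a(m) − d_b(m)| / Σ d_b(m) with b the
  reference. The alternative aggregation — relative error of the cumulative
  totals — is implemented as `mode="cumulative"`; the per-minute sum is the
  default and reports state which is used.
* **Minor-axis RSD**: population (ddof = 0) standard deviation over mean of
  the minor-axis series. A width proxy: a well-tracked mouse has nearly
  constant width across postures, so high RSD flags unstable segmentation.

NoDetection frames are excluded from per-frame error aggregates with their
count reported; distance sums bridge detection gaps with the straight-line
displacement between flanking detections (dropping the frames would deflate
distance).

## Training

Mini-batch Adam on the family loss, inputs scaled to [0, 1], optional
augmentation drawn per sample, a fixed validation set evaluated every epoch,
and the best-validation weights restored at the end. The checkpoint
criterion is selectable: validation loss (default) or median validation
center error — for tracking use the summed loss is dominated by the
direction term, so selecting on the tracking metric keeps the model that
actually tracks best. All shuffling,
augmentation and init derive from one seed: (seed, config) → bit-identical
histories. Defaults: Adam, learning rate 1e-4, batch 4 at 480 px / 16 at
96 px. The desk-scale benchmark uses learning rate 1e-3 — at a few hundred
gradient steps the 1e-4 default has not yet escaped the
all-background-prediction plateau that the ~3% foreground pixel fraction
induces, while 1e-3 converges in ~15 epochs; at full scale (tens of
thousands of steps) the smaller rate is the safer default. The training-set
size benchmark shuffles once and takes nested prefixes, so each size's
training set contains the smaller ones, and trains from scratch per size
against one fixed validation set.

Desk-scale study conditions (used by the test suite and the acceptance
script): 96 px frames, high-contrast scene, 300 training / 50 validation
frames, 28 epochs, batch 16, checkpoint on validation center error — about
seven minutes on one CPU core. Distance traveled is especially sensitive to
per-frame center jitter (independent errors inflate path length), so the
video check rewards the low-jitter models the center-error checkpoint
selects. Measured outcomes at these conditions are printed by
`scripts/acceptance.py`; representative values are median validation center
error under 0.5 px and mean mask IoU around 0.85, with end-to-end distance
error of ~2% on a 240-frame video.

## Annotation engine

The headless core of the labeling workflow: foreground/background scribbles
seed a marker-based watershed on the Sobel gradient magnitude of the
median-denoised (3×3) frame; the flooded foreground region, reduced to its
largest component, is fitted and the user's coarse direction choice (±90°)
resolves the heading. The engine is a pure function of (frame, scribbles).
The stored quadrant label always follows the *resolved* angle, since the
user's hint may sit across a span boundary from the fit.

## Numerical and degenerate-input choices

* Rasterization: a pixel is foreground iff its integer-coordinate center
  satisfies the implicit inequality; degenerate axes give an empty mask.
* Mask threshold 0.5 on the foreground softmax channel; direction and bin
  argmax ties resolve to the lowest index.
* Undirected angles stored in [0°, 180°), directed in [0°, 360°).
* Binned heads require (max−min)/resolution to be a positive integer.
* Track CSVs store 6 decimal places (9 for sin/cos): lossless to 1e-6.
* Videos wider than square are center-cropped (mirroring the acquisition
  crop); frames smaller than the model are zero-padded, and predictions are
  mapped back to original-frame coordinates.
* Default calibration 30 fps and 8 px/cm, overridable everywhere.

## Known limitations

* The direction head needs a visible head/rump asymmetry; on the synthetic
  arena the tail is the only cue, and quadrant accuracy at desk scale
  (~0.75) is accordingly weaker than mask quality.
* The moment fit assumes a roughly convex silhouette; highly concave masks
  (e.g. a mouse curled around a food cup) can yield axes a contour-based
  fit would judge differently.
* Per-frame independence: no temporal smoothing, no identity logic, single
  animal only.
* mp4/avi decoding requires an imageio plugin with codec support; the
  renderer's native PNG-directory format is always available.
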