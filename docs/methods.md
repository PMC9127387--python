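# Methods

This note documents the models implemented in `fluorotrack`, the
parameters that matter, the synthetic study conditions, and the design
choices made where the methods' published descriptions leave the design
open.

## Coordinate conventions

Frames are 8-bit grayscale, 0-based pixel grid, x right, y down. Boxes
are `(x, y, w, h)` with half-open footprint `[x, x+w) × [y, y+h)`. All
distances are in pixels; no physical pixel spacing is assumed.

## Preprocessing

**Rotation.** A frame is rotated about an anatomical anchor `O` (the
upper spine) by composing translate(−O) · rotate(θ) · translate(+O) in
homogeneous coordinates, θ clockwise positive, bilinear interpolation,
zero fill. The rotation is fixed per sequence (a per-frame tracked
anchor would require the anchor tracker to already be trusted; the
fixed variant is what the multi-target manager uses, and the anchor can
always be tracked explicitly as a target).

**Contrast stretching.** `P_out = (P_in − N_min)(O_max − O_min)/(N_max −
N_min) + O_min`, truncated to integer and clipped to [0, 255]. Global
scope takes `N_min/N_max` from the whole image; local scope from a
sliding window (default 31×31). A constant image is returned unchanged
with a warning, since the map is undefined.

**Bilateral filter.** Gaussian spatial kernel (σ_s, window radius
⌈2.5 σ_s⌉) times Gaussian range kernel (σ_r), applied only inside the
tracking ROI. It is an exact shift-sum implementation, not a grid
approximation, so a direct double-loop evaluation reproduces it to
rounding.

**Watershed with a segmentation level.** The notion of a coarse-to-fine
"segmentation level" `c` is realized as h-minima marker suppression on
the Sobel gradient: markers are regional minima deeper than
`h = h_base · 2^(c−1)` (default `h_base` = 4 intensity levels). Larger
`c` merges shallow basins, so lowering `c` can only refine the
partition — the property the bolus tracker's refinement loop relies on.
Consumers that union regions use the complete partition
(`lines=False`); the exported `SegmentationMap` keeps 1-px watershed
lines (label 0) for visualization and stats.

## Discrete-point bolus tracking

State: the region mask `S_p`, its bounding box, a set of
`round(γ_p · |S_p|)` random points (default γ_p = 0.1), the region's
mean gray `g_avg`, and the last centroid displacement.

Per frame: predict the box by the last displacement, expand ×1.2,
watershed at the current level (initial level 4), and score each region
with the weighted sum `Eva` of point share, point density and gray
distance. Regions with `Eva ∈ [E0, E1]` are accepted; a rejected region
larger than `β_img` (0.5) of the box restarts the whole box one level
lower; smaller rejected regions are re-segmented individually; below
`c_min` the gray band `[0, g_avg + 25]` decides pixel-wise. Accepted
pixels are united, cleaned with one 3×3 open-close, and the points are
resampled. An empty result freezes the velocity and flags `lost`.

Defaults: θ = (0, 0.5, 0.3, **−0.01**), band [0.25, ∞). The gray
weight is negative so that gray *distance penalizes*: with a positive
weight, any bright background region at distance ≳ 25 gray levels
from the bolus would clear the acceptance band on the distance term
alone and the tracker provably locks onto background. All weights are
free parameters in `RunConfig`.

## Improved inter-frame difference

The classical difference `|n(t) − n(t−1)| > m` detects change, not
objects: it leaves a ghost on vacated pixels and voids inside slowly
moving targets. The improved method:

1. bilateral-denoise the tracking box in both frames; contrast-stretch
   both with one joint linear map (separate maps would make static
   pixels differ);
2. threshold the absolute difference at `T_diff` (default 15, `≥`);
3. build the residual mask `d_seg`: previous-region pixels whose
   current value exceeds `T_p` — they were vacated by the dark target.
   `T_p` defaults to `g_avg + 25` when the target's running gray is
   known, else to Otsu of a doubled box;
4. combine as **sets**: `seg_c = (d_frame ∪ seg_p) \ d_seg`. The union
   saturates before subtraction; a vacated pixel sits in all three
   masks, so elementwise `d_frame + seg_p − d_seg = 1` would keep every
   ghost pixel and the residual cancellation would never happen;
5. fuse gray information: pixels of the box inside the target's gray
   band join the region (the difference is silent on the unmoved
   interior), then one open-close, then connected components are kept
   if they contain a discrete point or match `g_avg` within ±20.

The persistent state is exactly {previous frame, previous region, box}
— there is no background model, which is the method's memory advantage
over ViBe (20 samples/pixel) and EGMM (50-frame buffer/pixel).

## Background baselines

**ViBe.** Per-pixel sample set (n = 20) drawn from the 8-neighborhood
of one frame; background iff ≥ n_min = 2 samples lie within R = 20 of
the current value; stochastic 1-in-φ (φ = 16) temporal and spatial
updates. The spatial "protection" update refreshes a random neighbor's
model *with that neighbor's current value*: inserting the updating
pixel's own value instead can never absorb a sharply bounded stopped
object (its value differs from every inserted sample by more than R),
whereas the chosen variant absorbs it layer-by-layer from the border —
the behavior the update strategy is meant to provide. Classification is
exact with respect to the counting rule (verified against a brute-force
oracle pixel-for-pixel).

**EGMM (balloon estimator).** Per-pixel FIFO history (50 frames); the
kernel half-width `D` grows to the distance of the k-th nearest history
sample (k = 5); the balloon density `k/(2·L·D)` is high — background —
exactly when `D ≤ D_max` (default 20 intensity levels). The
classification is implemented through that equivalent width threshold:
a fixed density threshold proportional to `1/D` cancels `D` and
degenerates to a data-independent constant. Background pixels push
their value into the buffer; foreground pixels keep their history.

## Combined correlation-filter tracker

**Position filter (kernelized).** Search window 2.5× the target,
edge-replicated, cosine-tapered. Features: centered gray and/or 9-bin
HOG cell histograms (4-px cells, replicated to the pixel grid so all
channels share one shape). Training solves ridge regression over all
cyclic shifts in closed form, `α̂ = ŷ / (F(k_xx) + λ)` with the Gaussian
kernel correlation `k(τ) = exp(−(‖x‖² + ‖z‖² − 2·corr(x,z)(τ)) /
(σ_k²·N))`; detection reads the response `Re(F⁻¹(α̂ ⊙ F(k_xz)))` with
parabolic sub-pixel peak refinement. (The response formula is written
here with the inverse transform; the forward-transform spelling that
sometimes appears in print is not an involution and cannot return the
spatial response.) Defaults: λ = 1e−4, σ_k = 0.5, target bandwidth
√(wh)/16, learning rate θ = 0.02.

**Scale filter.** 33 factors `a^s`, a = 1.02, symmetric about 1. Each
scale patch is resized to 16×16, mean-removed, L2-normalized with
0.2-clipping (re-normalized), projected by a fixed PCA basis computed
at initialization (top 32 components of the first scale sample), and
Hann-tapered over the scale axis. A 1-D MOSSE-type filter with a
center-peaked Gaussian target scores the ladder; the argmax index maps
directly onto the factor ladder. HOG features and per-frame projection
updates were left out deliberately: at these patch sizes the raw-gray
descriptor already resolves one scale step, and a fixed basis keeps
the filter deterministic and cheap.

**Template update.** `α̂ ← (1−θ)·α̂ + θ·α_new` for the position filter
(coefficients and template) and the equivalent running average of
numerator/denominator for the scale filter — a convex combination, so
every coefficient stays between its old and new values.

**Watershed edge correction.** The box reported per frame snaps to the
bounding box of the union of watershed regions lying ≥ 60% inside the
current box (the target's segmented fragments), when that union's box
overlaps the tracked box with IoU ≥ 0.5. Snapping to the single
best-overlap region was measurably worse (it returns one fragment or a
background region); the union reading tightens boxes on every synthetic
scenario. The correction alters only the *reported* box; the filters'
internal center/size are not overwritten by it.

**Occlusion guard.** The tracker keeps a running mean of the response
peak; a frame whose peak falls below 0.25× that mean is flagged
occluded: templates freeze, the box coasts on the last confident
displacement, and the running mean is not polluted. Targets lost for
more than 10 consecutive frames are terminated by the multi-target
manager (and never revived — detection-free tracking has no birth
model).

**MOSSE baseline.** Single-channel, log-preprocessed, trained and
updated with running numerator/denominator averages (rate 0.125).

## Multi-target manager

Manual registration only (id, kind, start frame, box); each target runs
its own tracker with its own deterministic random stream derived from
(seed, id), so any subset of targets reproduces its trajectories
exactly and truncating the sequence reproduces the prefix. Relations
(center distance, box IoU) are compiled after tracking from the stored
trajectories, in the rotated (spine) frame when a rotation is given.
No Kalman/Hungarian data association is used: targets are
physiologically distinct and independently tracked, so identity
assignment is fixed at registration.

## Metrics

APE: mean Euclidean center distance over matched frames. AOR: mean IoU
(chosen over overlap/truth-area for symmetry). Accuracy/success rate:
fraction of frames with IoU ≥ 0.5 (the standard tracking-benchmark
definition; threshold configurable). Detector masks are reduced to
their largest connected component before scoring — identically for
every method; an empty detection predicts its last known centroid
(frame center before any detection), so rarely-firing detectors cannot
win the error metric on their few hits. Frames-per-second figures are
reported but hardware-bound and never asserted.

## Synthetic study conditions

The generator emulates what the real recordings are described to
contain, at desk scale:

* `side_view` (50 frames, 128², the lateral geometry): a deformable
  dark bolus with an oral-hold stage (12 dwell frames) followed by
  curved pharyngeal transport, at moderate contrast (bolus 78–100 over
  background 140–205). Dwell and low contrast are the two properties
  that separate residual-subtracting differencing from sample-based
  background models; without them the comparison would exercise
  nothing.
* `elevation_small_target` (30 frames, 96²): a small target with a long
  dwell and then abrupt fast motion — the elevation-view failure mode
  (4–5 px/frame after 18 static frames).
* `clean_translation`, `occlusion_pass`, `forward_lean`,
  `bolus_interference`, `scale_change`: one scenario per tracker
  capability (see `examples/`).

Noise is additive Gaussian (σ = 2–3) plus signal-dependent
(Poisson-like, scale 0.02–0.03); truth is recorded pre-noise and
pre-occluder, so metric ceilings are exact; boxes are the tight
bounding boxes of the masks and centroids are mask centroids.

What the generator does **not** model: X-ray physics (beam hardening,
scatter), anatomy-shaped backgrounds, motion blur, interlacing, and
bolus fragmentation into disconnected parts. Passing on these scenes
shows the algorithms implement their contracts and reproduce the
qualitative method orderings; it does not certify clinical performance
on hospital recordings.

## Numerical choices and degenerate inputs

Rotation uses bilinear interpolation with zero fill; uint8 outputs are
rounded. Contrast stretch truncates toward zero (so a 127.5 maps to
127). Watershed of a constant ROI returns one region. `n_scales = 1`
disables resizing entirely. Boxes are always clipped to the frame;
boxes that would leave the frame are clamped at the border. Empty
detections and empty bolus masks are legal outcomes that set `lost`
flags rather than raising. All randomness flows through
`numpy.random.Generator` seeded from user-supplied seeds; reruns are
byte-identical.

## Problem sizes

The test suite and the acceptance script run the full stack on 30–50
frame sequences at 96–128 px — sizes chosen so every scenario, five
seeds deep where averaged, completes interactively while still leaving
each algorithm dozens of frames of dynamics to fail on.

## Known limitations

* The bolus tracker assumes the bolus is the darkest structure in its
  search box; overlapping dark anatomy (e.g. mandible shadow) can
  capture the gray band.
* The improved difference inherits its box motion model from the last
  displacement; target accelerations larger than the box expansion
  margin lose the leading edge for a frame.
* The scale filter estimates isotropic scale only (aspect ratio is
  fixed at initialization).
* The occlusion guard is threshold-based; a slow gradual appearance
  change that depresses the peak can delay updates unnecessarily.
* AVI input requires an imageio backend with an AVI decoder; image
  stacks (PNG/TIFF) are the primary interchange format.
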