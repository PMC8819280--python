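# Methods

This note documents the models, parameter choices and numerical decisions
behind `spvsim`, and what the synthetic components do and do not emulate.

## Scene model and rendering

The environment is a closed rectangular corridor (default 3 m wide, 22 m
long, 2.5 m walls) in a right-handed frame with x across the width, y
along the length and z up. Obstacles are axis-aligned boxes in two fixed
size classes: small 0.50 x 0.30 x 0.90 m (width x depth x height) and
large 0.75 x 0.30 x 1.80 m; a full course holds 7 small + 6 large boxes.

Rendering is single-ray-per-pixel pinhole ray casting. The camera's
square field of view defaults to 35 deg so that rendered and displayed
fields coincide; the focal length in pixels is `(res/2) / tan(fov/2)`
(240 / tan 17.5 deg ≈ 771 px at 480 px). Rasters are row-major, origin
top-left, pixel centers at half-integer coordinates. The depth channel is
planar depth (distance along the camera's forward axis), so a frontal
wall at distance d reads exactly d everywhere.

Shading is stylized and flat: each corridor surface, and each box face
orientation per size class, has a fixed gray level. The levels are chosen
so that surfaces that can abut in the image differ in brightness — the
synthetic analogue of a laboratory corridor built from visually distinct
materials (dark floor, lighter walls, cardboard faces). Flat shading
guarantees that, in the plain course, photometric gradients occur only at
surface boundaries; this is the property that makes plain-course edge
detection approximate ideal surface-boundary detection, and the test
suite quantifies it (F1 ≥ 0.8 at 2-px tolerance between the Canny mask
and the geometric boundary mask; mean ≈ 0.94 along walked routes).
Frames rendered closer than ~0.5 m to a box face degenerate to a single
uniform surface and are excluded from that comparison; a walking observer
views obstacles tangentially, not nose-on.

The complex course multiplies square-wave stripe textures (default
period 0.55 m, contrast ±0.35, per-surface random phases) into the
surface levels of floor, walls and box faces, emulating wallpaper and
tape. Textures never alter geometry, so the ground-truth boundary mask is
pixel-identical between the plain and complex variants of a view.

### Ground-truth surface boundaries

A pixel is a boundary pixel iff for some 4-neighbor the depth jump
exceeds 5% of the nearer depth, or the angle between unit normals exceeds
20 deg. The relative depth criterion makes the oracle scale-free; its
side effect is that heavily foreshortened surfaces (the floor near the
vanishing point, beyond ~10 m) fire on within-surface depth gradients.
Those "far-end" pixels are genuine depth discontinuities at the pixel
scale and are kept.

### Route difficulty and generation

Difficulty is the length of the shortest collision-free 2-D path from
the entrance midline (x = width/2, y = 0) to the far-end line y = length,
with box footprints inflated by an agent radius of 0.30 m (half a
shoulder width; the walkable margin along the walls is likewise the agent
radius). The production planner builds a visibility graph over inflated
footprint corners (Liang–Barsky segment tests against open rectangle
interiors, so grazing contact is allowed) with a virtual goal reached by
a vertical drop — the optimal final leg to a goal line. Dijkstra on that
graph is exact for this polygonal world. The independent cross-check
discretizes the workspace at 5 cm and runs Dijkstra with a
coprime-offset neighborhood of radius 5 (worst-case metric error ≈ 0.5%);
the two planners agree within 1% on random layouts, and a mirrored layout
has exactly the mirrored path.

Candidate layouts are drawn on a slot grid: 13 longitudinal stations
(y = 2.0 m + k·1.5 m) alternating small/large, each with three lateral
positions (19%, 50%, 81% of the width). The published course layout gives
no slot coordinates, so the grid is configuration with these defaults. A
set of `n_routes` layouts is accepted when all their path lengths lie
within a tolerance (default 2%) of their median; mirrored copies are
appended. The search is deterministic given the seed and fails loudly
after a bounded attempt budget.

`walkthrough` samples camera poses along the shortest path at uniform arc
length (speed / frame rate), yaw along the local tangent, eye height
1.70 m — providing realistic frame streams for end-to-end simulation.

## Contour extraction

The Canny implementation is explicit rather than delegated so that its
conventions are pinned: ITU-R 601 grayscale conversion; Gaussian
smoothing (default sigma 3.0 px) with reflective borders; 3x3 Sobel
gradients with the L2 magnitude (chosen for isotropy; some library
implementations default to L1); non-maximum suppression over four
quantized gradient sectors with ties kept on both sides (this keeps the
result equivariant under 90-deg rotations); dual-threshold hysteresis
(defaults 25/50 on the 0–255 scale) implemented by connected-component
labeling of candidate pixels and keeping components that contain a
strong pixel — verified against a brute-force flood fill in the tests.

The surface-boundary route combines a thresholded boundary-probability
map (default threshold 94 of 255) with Canny-style contours of the
surface-normal map: each normal component is mapped from [-1, 1] to the
0–255 scale and edge-detected separately (default sigma 1.0, thresholds
25/50), and the masks are OR-combined. The boundary/normal input either
comes from the renderer's ground-truth channels (an ideal predictor) or
from any external callable returning the `BoundaryPrediction` contract;
no network or pretrained weights ship with the package, and monocular
prediction from RGB is out of scope.

Preprocessing center-crops to square and resamples bilinearly to
480 x 480, the display raster used throughout.

## Phosphene model

Phosphenes are strictly binary and idealized: equally sized, circular,
non-overlapping in expectation, with no cortical magnification, fading or
electrode crosstalk. A map is built once per run: base locations at the
cell centers of the uniform n x n partition of the 480-px display; a
temporally constant jitter uniform in ±0.15 of the grid pitch per axis;
temporally constant gains normal(1, 0.10) clipped to [0.5, 1.5]. The
jitter and gain magnitudes, and the mask-to-activation rule, are not
published quantities; they are package defaults flagged as assumptions.
Activation defaults to max-pooling the contour mask over each phosphene's
receptive window (one pitch-sized square centered on the jittered
location, clipped at borders): contour masks are ~1 px thin, so mean
pooling would extinguish nearly all phosphenes at low n; mean pooling is
retained as a configurable alternative for sensitivity analyses. Active
phosphenes are drawn as Gaussian blobs (sigma 2.0 px, truncated at 4
sigma) scaled by their gain, summed additively and clipped at 1. On the
35-deg display a blob subtends 2·2.0·35/480 ≈ 0.29 deg of visual arc.
Even n places no phosphene at the exact display center (cell-center
convention).

## Experimental design

Per session: two camera-vision controls first (one per complexity, order
randomized), then the 16 SPV condition instances (6 CED resolutions + 2
boundary resolutions, each at both complexities) shuffled freely — no
blocking. Layout matching: each (method, resolution) slot draws one base
layout and orientation per session; the plain and complex trials of that
slot use the same layout in opposite orientations, and boundary trials
reuse the CED assignment at the same resolution/session/complexity. The
two sessions' draws are independent. Training-session trials are not
modeled (no endpoints are analyzed from them). `verify_schedule` re-checks
every count and matching constraint and names offending slots.

## Synthetic behavioral model

The generator is a structural stand-in for unpublished human data; its
defaults encode the study conditions, not fitted values. Endpoint model:

- duration = condition mean + participant effect N(0, 7.748 s) +
  session-2 shift (−3.468 s, SPV trials only) + residual N(0, 6 s),
  floored at 3 s;
- collisions ~ Poisson(condition rate × participant frailty), frailty
  log-normal with log-sd 0.30; camera-vision collisions forced to zero;
- rating = condition mean + participant effect N(0, 0.783) + residual
  N(0, 1), rounded and clipped to [1, 10].

Condition means use two published anchors — camera-vision duration
16.74 s and rating 9.363, with the SPV conditions averaging near 31 s —
and otherwise follow a documented qualitative shape: durations fall
monotonically with resolution; the complexity penalty is large at 10x10
(+9 s), shrinks with resolution and reverses slightly at 50x50 (−1.5 s);
boundary-SPV is slightly worse than CED. Numeric values read off figures
are deliberately not used. The practice effect is a session-level shift,
not a per-trial slope, so the emergent trial-number correlation is weak
negative rather than calibrated.

What passing tests show: the analysis pipeline is correctly calibrated
(familywise type-I ≈ 3–4% against the 5% bound; >80% power for the
injected low-resolution complexity effect at n = 20) *under this
generator*. They do not validate the effect sizes against human behavior,
model within-session fatigue, perceptual learning dynamics, or any
speed–accuracy coupling (collisions and durations are conditionally
independent given the participant).

## Statistics

Endpoints are z-scored within participant over all analyzed trials,
controls included (sample sd, ddof 1); zero spread raises a named error
rather than propagating zeros. The pairing unit for planned comparisons
is the per-participant mean of a condition's trials across both sessions.
The Wilcoxon signed-rank test drops zero differences (Wilcoxon's original
rule), assigns mid-ranks to ties, enumerates the exact two-sided null
over all sign patterns for up to 15 informative pairs, and otherwise uses
the normal approximation with tie correction (variance from squared
mid-ranks) and continuity correction; with 20 participants the pipeline
runs on the approximate path. Both exact and approximate paths are
selectable. Families: 6 complexity comparisons (per-test threshold
0.05/6, displayed as 0.0083) and 4 method comparisons (0.05/4 = 0.0125);
thresholds are displayed rounded to four decimals. The Shapiro–Wilk
screen is advisory — the pipeline always proceeds with rank tests. The
restoration percentage maps a condition mean onto a 0–100 scale anchored
at the worst SPV condition (10x10 complex) and camera vision, unclamped
in both directions. The speed–accuracy screen is a per-condition
least-squares slope of collisions on duration with its sign.

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` use: 480-px renders for
image-level checks and 64–160 px for geometry unit tests; 50 random
layouts for the planner cross-check; 30 random fields (≤ 32x32) for the
hysteresis oracle; 100 and 50 random datasets (n ≤ 12) for the Wilcoxon
oracle; 500 null and 200 effect replicates (20 participants each) for
the calibration estimates; 200 participants for the dispersion check.

## Known limitations

No photorealism, global illumination or motion blur; no fisheye model
(the pinhole camera is the simplest model consistent with the 35-deg
display mapping); no collision physics or human locomotion model; no
temporal smoothing of contour masks; no cortical magnification,
phosphene fading or crosstalk; the behavioral generator's condition means
are plausible defaults, not estimates.
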