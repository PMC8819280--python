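# spvsim — simulated cortical prosthetic vision for indoor mobility research

Cortical visual prostheses elicit *phosphenes* — localized flashes of
light — one per stimulating electrode. Because an implant can only drive a
limited number of binary phosphenes, the camera frame must be simplified
before it reaches the electrode array; contour extraction is the canonical
strategy. `spvsim` is a toolkit for studying that design space in
simulation: how much indoor mobility performance a given phosphene
resolution can restore, and whether stricter *surface-boundary* scene
simplification beats plain edge detection.

It is aimed at researchers in visual neuroprosthetics and low-vision
simulation who need a fully synthetic, reproducible version of an
obstacle-course mobility experiment: a rendered corridor environment with
ground-truth geometry, the image-processing and phosphene-rendering
pipeline, randomized trial schedules, a synthetic behavioral cohort, and
the within-participant nonparametric statistics.

## What is inside

- **`spvsim.scene`** — a pinhole ray-cast renderer for a 3 m x 22 m
  corridor containing 7 small (30x50x90 cm) and 6 large (30x75x180 cm)
  boxes, in a *plain* variant (uniform surfaces) or a *complex* variant
  (procedural stripe textures emulating wallpaper/tape). Every frame comes
  with ground-truth depth, surface normals and a surface-boundary mask
  (depth or normal discontinuities), which stands in for an ideal
  monocular boundary predictor. Route difficulty is the length of the
  shortest collision-free path (visibility graph; a 5-cm grid Dijkstra
  serves as an independent cross-check), and layouts are generated
  difficulty-matched within a tolerance of the median, plus mirrored
  counterparts.
- **`spvsim.contours`** — scene simplification to a binary contour mask:
  Canny edge detection (Gaussian sigma 3.0 px, hysteresis thresholds
  25/50 out of 255) or surface-boundary combination (boundary probability
  thresholded at 94 out of 255, OR-ed with Canny-style contours of the
  normal map). An adapter contract lets any external boundary/normal
  predictor plug in.
- **`spvsim.phosphenes`** — binary phosphenes on an n x n grid (study
  values 10–50) rendered as Gaussian blobs (sigma 2.0 px, ~0.29 deg of
  visual arc on the 480 px / 35 deg display), with temporally constant
  location jitter and per-phosphene brightness gains.
- **`spvsim.design`** — randomized two-session trial schedules: per
  participant 4 camera-vision controls, 24 CED-SPV and 8 boundary-SPV
  trials, with complexity pairs route-matched in mirrored orientations and
  boundary trials route-matched to their CED counterparts.
- **`spvsim.behavior`** — a synthetic cohort generator with condition
  means, participant random effects (sd 7.748 s / 0.251 collisions /
  0.783 rating), a second-session practice effect (−3.468 s on SPV
  trials), Poisson collisions and bounded discrete ratings.
- **`spvsim.stats`** — within-participant z-scoring, an exact-enumeration
  Wilcoxon signed-rank test (normal approximation with tie and continuity
  correction beyond 15 informative pairs), Bonferroni-controlled planned
  comparison families (m=6 → per-test threshold 0.0083; m=4 → 0.0125),
  Shapiro–Wilk screening, the practice-effect correlation and the
  restoration-percentage metric.

## Worked example

```python
from spvsim import scene, contours, phosphenes

corridor = scene.CorridorSpec()                       # plain 3 x 22 m course
layout = scene.generate_route_layouts(1, corridor, seed=1)[0]
pose = scene.CameraPose(position=(1.5, 0.5, 1.70))    # entrance, eye height
view = scene.render_view(corridor, layout, pose)

ced = contours.extract_contours(view, "ced")
oracle = contours.extract_contours(view, "boundary_oracle")
print(contours.mask_f1(ced, oracle, tolerance_px=2.0))

spec = phosphenes.PhospheneGridSpec(n=26, seed=7)
frame = phosphenes.simulate_view(view, spec, "ced")
print(int(frame.activations.sum()), "of", 26 * 26, "phosphenes on")
```

prints

```
0.811
92 of 676 phosphenes on
```

The F1 of 0.81 (2-px tolerance) says that in the plain course the Canny
edge mask and the ideal surface-boundary mask nearly coincide — image
gradients occur only at surface boundaries there. The 26x26 percept lights
92 of 676 phosphenes, sketching the floor–wall junctions and box outlines;
rerunning with `n=10` or `n=50` shows the same contours sampled coarser or
denser. The `examples/` directory walks through each capability (render,
contours→phosphenes, route difficulty, schedules and synthetic cohorts,
statistics) as short narrative scripts, and the `spvsim` command exposes
the same stages as subcommands (`spvsim schedule --participants 20 --seed 1
--out schedule.csv`, `spvsim simulate --n 26 --out percept.png`, ...).

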