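# Methods

This note documents the models and procedures implemented in
`fishchain`, the parameter defaults and their rationale, the numerical
choices, what the synthetic benchmark emulates, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Body model

A fish is a chain of `n_r` oriented rectangles. Rectangle `i` is
anchored at the midpoint of its front edge, spans backwards along its
axis, and is hinged to its successor at joint `J_i`; the head rectangle
is the longest so that the nose always lies inside it. Default sizes
(`lengths (50, 30×7)`, `widths (35, 35, 35, 26, 20, 15, 11, 8)` px)
describe an adult zebrafish at roughly 10 px/mm; they are fixed per run
because the tracked fish are assumed homogeneous in size. A
per-detection scale hook exists but is off by default.

Conventions: image coordinates with the origin top-left and y down;
angles counter-clockwise on `(x, −y)`, so heading `θ` has image-space
direction `(cos θ, −sin θ)`. Orientations point from tail to head.
Rasterization assigns a pixel to a rectangle iff its center is inside,
half-open on one side of each axis so abutting rectangles tile without
seams. Consequence: rendered coverage is deterministic but not exactly
symmetric under 90° rotation for even widths (a one-pixel seam can
change sides); the corresponding invariant holds to ~3%.

## Detection

* **Background.** Two estimators are provided. `estimate_background` is
  the pixel-wise mean, appropriate for very long recordings where each
  pixel is almost always plate. `robust_background` (the pipeline
  default when no background image is supplied) takes the pixel-wise
  maximum of ≤31 frames sampled across the clip: under backlit imaging
  the plate is the brightest thing a pixel ever shows, so the maximum is
  immune to fish dwelling on a spot for most of a short clip. Gaussian
  sensor noise biases it up by a couple of gray levels — negligible
  against the 160-level fish/plate contrast. Pixels covered by a fish
  for an *entire* clip are unknowable from the clip alone; for short
  clips a precomputed background image should be supplied (it is an
  explicit pipeline input, and the synthetic generator exports one).
* **Segmentation.** `|frame − background| > threshold` with
  `threshold = 80` (half the default plate/fish contrast), minimum blob
  area 25% of the model's rectangle area. Both are calibration defaults,
  config-exposed.
* **Boundary.** Marching-squares contours of each component, resampled
  to 1 px of arc (so "8 units of arc" is 8 points), wound
  counter-clockwise on screen. Curvature is computed on a copy smoothed
  by a 5-point circular moving average: the rasterization staircase
  otherwise contaminates the tangential angles, while corner turning
  over the much wider 16-px curvature window is preserved.
* **Keypoints.** Nose/tail candidates are positive curvature maxima
  above `kappa_min = 0.08 rad/px` with non-maximum suppression over
  5×`neighbor_arc` (nose and tail sit half a perimeter apart, so
  suppression can be generous). For a two-peak blob the lower peak is
  the nose. For blobs with any other peak count (occlusions, strong
  bends) every peak below `kappa_max = 0.165 rad/px` is a nose
  candidate: the blunt nose tip (peak ≈ 0.13) always turns less sharply
  than the pointed tail tip (≈ 0.17–0.25), so the upper bound
  generalizes the lower-is-nose rule and keeps tail-first backward fits
  out of the candidate set. Both thresholds are calibrated defaults.
  Intersection corners of occluding fish have negative curvature and are
  never candidates.
* **Nose refinement.** The traced contour of a binarized sharp corner is
  rounded by 1–2 px and its pointwise maximum can sit between twin
  shoulder peaks, so the peak index is refined to the curvature-weighted
  centroid of its high-curvature run, and the nose position and head
  axis are taken from total-least-squares lines fitted to the two
  boundary flanks (4–20 px of arc to each side): their intersection is
  the apex, their bisector the head axis — the least-squares version of
  the perpendicular bisector of the neighbor chord. On rendered fish
  this recovers the nose to ≲1 px and the heading to ≲1.5°.
* **Chain fitting.** Rectangles 2..n_r are fixed sequentially; each
  draws `n_pb = 256` candidate angles uniformly on [0, 2π), scores each
  by the count of still-unclaimed region pixels it would cover, and
  keeps the best (ties broken toward the previous segment's angle, for
  smoothness and determinism). Claimed-pixel scoring prevents the
  degenerate fold-back onto the previous rectangle. The cover ratio is
  the covered fraction of the fish region, with the denominator capped
  at a reference single-fish area when the region is a merged
  multi-fish blob (see below); poses under 0.8 are rejected.

### Cover-ratio denominator during occlusion

The cover check asks whether the fitted rectangles cover ≥80% of *one
fish's worth* of foreground. For an isolated fish the denominator is
simply its component size. When components of several fish merge, using
the whole component would auto-reject every occluded fish for the whole
overlap; instead the denominator is `min(|region|, ref_area)` with
`ref_area` the expected single-fish silhouette area, estimated at run
start as the median component area over a few probe frames (isolated
fish dominate). This keeps detection alive through partial occlusion,
which the downstream coasting/relinking machinery depends on; the cost
is that a chain fitted onto the *wrong* fish inside a merged blob can
pass the check — such errors are caught later by the association gates
and the body-fit veto, not by the cover check itself.

## Tracking

State `X = [x, y, θ, x_{t−1}, y_{t−1}, θ_{t−1}]` of the first joint and
head orientation, with `F = [[2I₃, −I₃], [I₃, 0]]` (the constant-velocity
recursion `x̂_t = 2x_{t−1} − x_{t−2}`) and `H = [I₃ | 0]`. All angle
arithmetic (prediction, innovation, coasting) uses differences wrapped
to (−π, π]. Defaults `Q = diag(4, 4, 0.01, 4, 4, 0.01)`,
`R = diag(2, 2, 0.02)`, `P₀ = 10 Q` are order-of-magnitude values for
per-frame motion at ~100 fps, config-exposed. `R = 0` is handled as the
exact-measurement limit (posterior observed block equals the
measurement); a singular but nonzero `R` raises.

**Association.** Cost `exp(−(NCC + V))` with three infeasibility gates:
`NCC < 0.6`, `V < 0.05` (both config defaults), and a predicted-to-
measured `J_1` distance above 40 px. The distance gate is an extension:
for texture-poor silhouettes the NCC between any two well-centered head
patches of identical fish is ≈0.97+, so appearance alone cannot rule
out physically impossible jumps between look-alike fish; at ~100 fps a
fish moves a few px per frame, and 40 px is ~7× the largest per-frame
displacement. The tracker side of the NCC is the patch sampled from the
*current* frame at the predicted head rectangle, so the score decays as
a prediction drifts off its fish; the last associated patch is kept as
a fallback when the predicted rectangle leaves the canvas. The square
dummy-padded problem is solved with the Hungarian algorithm; pairs
assigned at infeasible cost count as unassociated.

**Body refit and veto.** Candidate segment angles are drawn from a von
Mises centered on the previous frame's segment orientations with
concentration `k_body = 50` (σ ≈ 8°): between consecutive frames at
~100 fps a segment rotates by at most a few degrees, so the motion
prior should concentrate accordingly. This tightness is what arms the
veto — a tracker updated with the wrong fish's head cannot bend its
body prior onto a body oriented 45°+ away, the cover collapses below
0.8, and the track is terminated within a frame or two. (The
association-scoring concentration stays at k = 4; a loose sampler of
that width would let the greedy cover search follow the wrong body and
disarm the veto.) The exact previous angle is always included in the
candidate set so a motionless fish cannot drift.

**Lifecycle.** Unassociated trackers coast (linear extrapolation) up to
5 frames, then terminate; a tracker that loses its target with fewer
than 2 measured frames is discarded entirely; unclaimed measurements
spawn trackers unless they sit within 30 px of an already-updated
tracker's head (duplicate candidates from merged blobs are not new
fish). Coasted poses are retained in the terminated tracklet, flagged,
and excluded from evaluation matching: the tracklet's end frame and
endpoint are then the extrapolated state at termination, which is what
makes the relinking gap gate meaningful (see below).

## Relinking

Candidate link `i → j` requires `0 < st_j − ed_i < max_interf = 6` and
endpoint head distance `D < max_interd = 80` px; its cost is
`exp(D) · exp(−V)` with `V` the von Mises similarity (k = 4) of the
endpoint head orientations. Body geometry is deliberately excluded — a
few frames of undulation change it too much to be a reliable cue.
Because tracklet ends include the coasted frames, coasting (≤5) plus
the gap gate (<6) compose into a bridgeable window of ~11 dark frames.
Two boundary cases are handled explicitly: a successor that spawned
while its predecessor was still coasting overlaps it in time, so the
predecessor's endpoint is evaluated at the frame before the successor
starts, provided everything beyond is coasted; and links never go
backward, so the link graph is a DAG.

With every tracklet forced to carry flow, a solution at total flow `f`
uses exactly `n − f` link edges forming vertex-disjoint chains, i.e. a
matching in the bipartite link graph; it is solved by successive
shortest augmenting paths (Bellman–Ford on the residual), which yields
the optimum at every intermediate cardinality. When no trajectory count
is given, the smallest feasible flow whose links all cost below a
configurable ceiling is chosen — link as much as possible, then as
cheaply as possible. Costs up to `exp(80) ≈ 5.5e34` stay in double
range; the pair `(D, V)` is stored on each edge for auditability.

## Evaluation

A fish-frame is correct iff the reported nose is within 10 px of the
annotated nose (the pose necessarily passed the 80% cover check, or it
would have been vetoed). Per frame, results are matched to truth
greedily by nose distance under the tolerance; unmatched truth records
are misses, unmatched results errors. Miss/error ratios and CTR divide
by fish × frames. AIT counts identity handoffs — the identity covering
a fish changes between its matched frames, or coverage stops for good
while the fish remains visible — per fish per 100 frames; a single
missed detection inside one continuing trajectory is not an
interruption. CIR scores each occlusion event by whether every involved
fish resumes, after the event, with the identity it carried before;
events with no scoreable frame on one side (e.g. an occlusion running
into the end of the clip) are excluded as unobservable.

## Synthetic sequences

The generator emulates backlit top-view imaging: plate 200, fish 40,
Gaussian noise σ = 4 gray levels, speeds 2–6 px/frame (≈0.8–2.3 body
lengths/s at 100 fps), arena 1200² px for five fish (comparable density
to 10–20 fish in a 2048² tank).

* **Kinematics.** Follow-the-leader chains: the head advances along a
  rate-limited heading, and each joint keeps its segment length while
  chasing its predecessor's new position, so the body traces the head's
  path and nothing rotates discontinuously between frames. A sinusoidal
  wiggle on the head's advance direction (amplitude 0.25 rad, period 30
  frames ≈ 3 Hz tail beat) travels down the chain as the
  backward-moving propulsive wave. The per-frame heading change is
  capped at `speed / (2·len_1)`: a head path tighter than the head
  segment would make the first joint orbit instead of follow, freezing
  the body until the head folds across it. Ground-truth chains satisfy
  the model's segment lengths exactly.
* **Silhouettes.** A smoothly tapered body — one trapezoid per segment
  with widths taken from the rectangle spec at the joints, a pointed
  nose cap and a rounded tail tip — reproduces a real fish outline's
  curvature signature: a moderate nose peak, a sharper tail peak, and
  no spurious corner peaks. A bare rectangle-union silhouette would
  have a flat head front and width-step corners and could not exercise
  the curvature detector the way real imagery does.
* **Avoidance.** Free fish blend wall repulsion (toward the arena
  center inside a buffer) with repulsion from the closest point of
  every nearby body, all rate-limited. With follow-the-leader bodies a
  collision can only start with a head entering another body, so danger
  is gauged head-to-skeleton; buffers exceed the turn diameter so
  evasions complete in time. On clean seeds no two silhouettes ever
  touch.
* **Scripted crossings.** One fish transits a fixed meeting point while
  its partner stages to a position abeam of the target's path, then
  runs a lead-pursuit intercept onto the rear body and, after first
  contact, holds course until the silhouettes separate. The staging
  keeps the pass transverse (a stern chase would drag the pursuer's
  nose along the body in a long graze); the post-contact commit
  prevents avoidance from peeling the pursuer off mid-crossing. Mutual
  partner avoidance stays on until the run-in so the pair cannot drift
  into an unplanned graze beforehand. The occlusion log is computed
  from rendered silhouette intersections — per overlapping pair, per
  contiguous span — not from the script, so it is exact.

### What the benchmark does and does not show

Passing on synthetic sequences establishes the geometry, filtering,
association, veto and relinking machinery end to end against exact
ground truth. It does not establish performance on real footage: real
fish have fins, translucent tails, specularities and shadows (softer,
noisier boundaries); real backgrounds have texture and illumination
drift; real occlusions include head-on contacts and prolonged parallel
swimming whose dark windows exceed the ~11-frame horizon that coasting
plus the 6-frame link gate can bridge — identity is then recoverable
only by appearance, which this method deliberately does not use.
Grazing passes of that kind are the dominant residual failure mode on
adversarial synthetic seeds as well.

## Problem sizes

Default test and acceptance runs use: a 5-fish, 200-frame clean school
and a 10-fish, 320-frame school with six scripted crossings (1600² px
arena); 50 single-fish frames for detection recovery; 200 random
matrices (≤6×6) and 100 random gated graphs (≤8 tracklets) for the
assignment and flow oracles; 20 seeded trials for the veto property.
These sizes were chosen so the full pipeline runs in minutes on one
core while every subsystem is exercised at realistic density.

## Known limitations

* Fixed, shared rectangle sizes: heterogeneous fish sizes need the
  (unimplemented) per-detection scale estimation.
* The cover denominator cap admits wrong-fish fits inside merged blobs;
  they are pruned by association and the veto, not by the check itself.
* No appearance model: identity across occlusions longer than ~11
  frames is unrecoverable by design.
* The background estimators assume backlit polarity (bright plate);
  pixels occluded for an entire clip are unknowable without a
  precomputed background.
* The energy-normalized NCC (no mean subtraction) is near-saturated for
  low-texture patches; the zero-mean variant is available behind a
  config flag.
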