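# fishchain

Planar multi-fish tracking with a chained-rectangle body model.

`fishchain` tracks the full body geometry of every fish in top-view,
backlit footage of a small school swimming in shallow water — the
imaging setup used for quantitative studies of zebrafish (*Danio rerio*)
collective behavior, where fish appear as dark, texture-poor silhouettes
on a bright plate. Unlike point trackers, it reports an articulated pose
per fish per frame, so body kinematics (bending, tail beat) are
available downstream, and it maintains identities through the frequent
occlusions that a real school produces.

## Method

Each fish is modeled as a chain of `n_r = 8` oriented rectangles
`rec_1..rec_8` (a long rigid head rectangle, then body rectangles of
tapering width), hinged at joints `J_1..J_7`. The pipeline has three
stages:

1. **Detection.** Background subtraction and thresholding yield binary
   silhouettes. Each blob's outline is resampled to unit arc length and
   its discrete curvature `C(i) = (φ(B_il) − φ(B_ir)) / l` is computed
   from tangential angles `φ = atan2(Δy, Δx)` of neighbors 8 px of arc
   away. The nose is the *lower* of the two positive curvature maxima
   (the tail tip turns more sharply); the head orientation is the
   perpendicular bisector of the chord between the nose's arc
   neighbors. Body rectangles are then fitted one at a time by random
   search over hinge angles, keeping the angle that covers the most
   still-unclaimed foreground. A pose whose rectangles cover less than
   80% of the fish region is rejected.
2. **Tracking.** A constant-velocity Kalman filter on
   `X = [x, y, θ, x_prev, y_prev, θ_prev]` tracks `J_1` and the head
   orientation. Trackers and detections are associated one-to-one by
   the Hungarian algorithm under the cost
   `C(i,j) = exp(−(NCC(i,j) + V(i,j)))`, where NCC is the
   energy-normalized cross-correlation of head-rectangle image patches
   and `V` a von Mises orientation agreement (k = 4); implausible pairs
   are infeasible. The body chain is then refitted with angles drawn
   from a von Mises centered on the previous frame's segment
   orientations — and a refit covering under 80% *vetoes* the head
   track, catching wrong associations. Unassociated trackers coast by
   linear extrapolation for up to 5 frames; unclaimed detections spawn
   new trackers.
3. **Relinking.** Fragments are reconnected by a min-cost max-flow
   problem over tracklet endpoints: a candidate link `i → j` exists iff
   `0 < st_j − ed_i < 6` and the endpoint heads are within 80 px, with
   cost `exp(D(i,j)) · exp(−V(i,j))`. Solving at a chosen total flow
   selects the globally cheapest set of links.

Evaluation against ground truth uses the miss/error ratios, the correct
tracking ratio (CTR), the average interruption times per fish per 100
frames (AIT), and the correct identification ratio after occlusion
events (CIR).

A seeded synthetic-sequence generator renders articulated fish with
follow-the-leader body kinematics, collision avoidance, and scriptable
crossing events, exporting exact per-frame ground truth and a
pixel-verified occlusion log — so the whole pipeline is testable without
real footage.

## Worked example

Generate a 3-fish, 120-frame sequence with one scripted crossing, run
the full pipeline, and score it against the exported ground truth:

```sh
fishchain simulate --out sim --n-fish 3 --frames 120 --arena 1100 \
    --seed 7 --crossing "60:0,1"
fishchain run --frames sim/frames --background sim/background.png \
    --truth sim/truth.csv --occlusions sim/occlusions.csv --seed 7 --out run
```

which prints:

```
wrote 120 frames, truth and occlusion log under sim
4 tracklets -> 3 trajectories under run
miss ratio              0.0278
error ratio             0.0000
CTR                     0.9722
AIT (/fish/100 frames)  0.0000
CIR                     1.0000
```

Reading: the scripted crossing briefly hid one fish (the 2.8% missed
fish-frames) and split its track into two tracklets; relinking merged
them back (4 tracklets → 3 trajectories, AIT 0), no spurious fish were
reported (error ratio 0), 97.2% of all fish-frames were tracked with the
nose within 10 px of truth, and every fish carried the correct identity
after the occlusion (CIR 1). `run/` also holds the tracklet and
trajectory CSVs (one row per fish per frame: nose, joints `J1..J7`,
per-rectangle orientations, cover ratio), a link-audit JSON and a run
manifest.

The same stages are available individually (`fishchain detect`, `track`,
`relink`, `eval`), compose to the identical result, and are importable
as a library (`fishchain.detect_frame`, `fishchain.track_sequence`,
`fishchain.relink`, `fishchain.evaluate`, `fishchain.simulate`).

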