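"""Seeded synthetic sequences of articulated fish with ground truth.

Emulates backlit top-view imaging of a shallow tank: a bright uniform
plate, dark low-texture fish silhouettes, mild sensor noise, ~100 fps
displacement.  Each fish follows a smooth random-walk heading with a
bounded turning rate and undulates its body segments sinusoidally with a
phase lag along the chain (a backward-travelling propulsive wave).
Scripted crossing events steer chosen pairs through an overlap so that
occlusion handling and identity bookkeeping can be tested against an
exported pixel-verified occlusion log.

Silhouettes are drawn as a smoothly tapered articulated body — a
trapezoid per chain segment with widths taken from the rectangle spec at
the joints, a pointed nose cap and a rounded tail tip — which reproduces
the curvature signature of a real fish outline (moderate positive peak
at the nose, sharper peak at the tail, no spurious corner peaks) that
the detector relies on.  The generating joint chain itself satisfies the
rectangle model's chain-length consistency, so model-space ground truth
is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .model import (
    DEFAULT_SPEC,
    FishPose,
    RectangleSpec,
    build_pose,
    heading_vector,
    wrap_angle,
)

__all__ = ["SimConfig", "CrossingEvent", "simulate", "render_silhouette", "SimResult"]


@dataclass(frozen=True)
class CrossingEvent:
    """Steer two fish through an overlap centered near ``frame``."""

    frame: int
    pair: tuple[int, int]


@dataclass
class SimConfig:
    """Study conditions of a synthetic sequence.

    Intensities follow the backlit regime (bright plate, dark fish);
    speeds correspond to ~100 fps imaging of adult zebrafish at roughly
    10 px/mm (a few px per frame); undulation amplitude/period give a
    ~3 Hz tail beat.
    """

    n_fish: int = 5
    arena: tuple[int, int] = (1200, 1200)  # (height, width) pixels
    frames: int = 200
    seed: int = 0
    spec: RectangleSpec = field(default_factory=lambda: DEFAULT_SPEC)
    plate_intensity: float = 200.0
    fish_intensity: float = 40.0
    noise_sigma: float = 4.0
    speed_range: tuple[float, float] = (2.0, 6.0)
    undulation_amplitude: float = 0.25  # head-wiggle amplitude, radians
    undulation_period: float = 30.0  # tail-beat period, frames
    turning_rate: float = 0.06  # max heading change, rad/frame
    nose_margin: float = 20.0
    min_clearance: float = 45.0  # enforced inter-fish distance, px
    crossings: tuple[CrossingEvent, ...] = ()

    def __post_init__(self):
        if not (0 <= self.fish_intensity < self.plate_intensity <= 255):
            raise ValueError("backlit imaging requires plate > fish, both in [0, 255]")
        if self.speed_range[1] > 10.0:
            raise ValueError("speeds above ~10 px/frame are not 100 fps-like")


@dataclass
class SimResult:
    frames: np.ndarray  # (T, H, W) uint8
    truth: pd.DataFrame  # frame, id, nose/joint coordinates, thetas
    occlusions: pd.DataFrame  # start_frame, end_frame, ids ("a|b")
    poses: list[list[FishPose]]  # per frame, per fish
    background: np.ndarray


def _fish_outline(pose: FishPose, spec: RectangleSpec) -> np.ndarray:
    """Closed polygon of the tapered silhouette for one pose."""
    n_r = spec.n_r
    # centerline: nose tip N, then gill point at J_1 equivalent, joints, tail end O
    centers = [pose.N]
    axes = [heading_vector(pose.theta[0])]
    half_widths = [0.0]
    # head taper: from the nose tip back to J_1 at full head width
    centers.append(pose.J[0])
    axes.append(heading_vector(pose.theta[0]))
    half_widths.append(spec.widths[1] / 2.0)
    for i in range(1, n_r - 1):
        centers.append(pose.J[i])
        axes.append(heading_vector(pose.theta[i + 1]))
        half_widths.append(spec.widths[i + 1] / 2.0)
    centers.append(pose.O)
    axes.append(heading_vector(pose.theta[-1]))
    half_widths.append(spec.widths[-1] / 2.0)

    left, right = [], []
    for c, a, hw in zip(centers, axes, half_widths):
        nvec = np.array([-a[1], a[0]])
        left.append(c + hw * nvec)
        right.append(c - hw * nvec)
    # rounded tail cap, swept from the left edge to the right edge behind O
    tail_axis = axes[-1]
    tail_n = np.array([-tail_axis[1], tail_axis[0]])
    tail_r = half_widths[-1]
    cap = [
        pose.O - tail_r * np.cos(t) * tail_axis + tail_r * np.sin(t) * tail_n
        for t in np.linspace(np.pi / 2, -np.pi / 2, 7)
    ]
    poly = left + cap + right[::-1]
    return np.asarray(poly)


def render_silhouette(pose: FishPose, spec: RectangleSpec, shape) -> np.ndarray:
    """Boolean silhouette mask of one fish on a canvas of ``shape``."""
    poly = _fish_outline(pose, spec)
    rr, cc = skdraw.polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _straight_chain(G: np.ndarray, heading: float, spec: RectangleSpec) -> np.ndarray:
    """Initial chain points G, J_1..J_{n_r-1}, O laid straight behind the head."""
    u = heading_vector(heading)
    cum = np.concatenate([[0.0], np.cumsum(spec.lengths)])
    return G[None, :] - cum[:, None] * u[None, :]


def _follow_chain(chain: np.ndarray, G_new: np.ndarray, spec: RectangleSpec) -> np.ndarray:
    """Advance a body chain after the head moved (follow-the-leader).

    Each point keeps its segment length while chasing its predecessor's
    new position, so the body traces the head's path; a wiggle imposed on
    the head's advance direction therefore travels down the chain as a
    backward-moving wave, the way a swimming fish's body does.
    """
    out = np.empty_like(chain)
    out[0] = G_new
    for k, length in enumerate(spec.lengths, start=1):
        d = chain[k] - out[k - 1]
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            d = -heading_vector(0.0)
            norm = 1.0
        out[k] = out[k - 1] + d / norm * length
    return out


def _chain_pose(chain: np.ndarray, spec: RectangleSpec, nose_margin: float,
                frame: int) -> FishPose:
    """FishPose (exact chain-length consistency) from chain points."""
    diffs = chain[:-1] - chain[1:]
    thetas = np.arctan2(-diffs[:, 1], diffs[:, 0])
    G = chain[0]
    N = G - nose_margin * heading_vector(thetas[0])
    return FishPose(G=G.copy(), N=N, J=chain[1:-1].copy(), O=chain[-1].copy(),
                    theta=thetas, frame=frame)


def _pose_points(pose: FishPose) -> np.ndarray:
    return np.vstack([pose.N[None], pose.G[None], pose.J, pose.O[None]])


def _min_pair_distance(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    d = pts_a[:, None, :] - pts_b[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).min())


def simulate(config: SimConfig) -> SimResult:
    """Generate frames, ground truth and an occlusion log.

    Fish are initialized on a spaced grid, advance by a per-fish constant
    speed along a smoothly wandering heading, reflect off walls, and are
    rejection-steered apart so silhouettes never intersect unless a
    scripted crossing forces them together.  The occlusion log is
    computed from rendered silhouette intersections, not from the script,
    so it is exact.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.arena
    spec = config.spec
    body_len = float(sum(spec.lengths))
    # the body follows the head's path, so the head only needs half a head
    # width of wall clearance; the initial straight tails need a full body
    margin = 40.0
    inset = body_len + margin + 20.0
    if H < 2 * inset or W < 2 * inset:
        raise ValueError("arena too small for the fish model")

    n = config.n_fish
    # spaced initial head positions, inset past the wall-avoidance buffer,
    # with headings biased toward the arena center and rejection-resampled
    # so no two initial straight bodies start anywhere near each other
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xs = np.linspace(inset, W - inset, cols) if cols > 1 else np.array([W / 2.0])
    ys = np.linspace(inset, H - inset, rows) if rows > 1 else np.array([H / 2.0])
    center = np.array([W / 2.0, H / 2.0])
    speeds = rng.uniform(*config.speed_range, size=n)
    wiggle_phases = rng.uniform(0, 2 * np.pi, size=n)
    headings = np.zeros(n)
    chains = []
    for i in range(n):
        gx = xs[i % cols] + rng.uniform(-20, 20)
        gy = ys[i // cols] + rng.uniform(-20, 20)
        G = np.array([gx, gy])
        to_c = center - G
        base = float(np.arctan2(-to_c[1], to_c[0]))
        best, best_d = None, -1.0
        for _try in range(60):
            h = wrap_angle(base + rng.uniform(-1.2, 1.2))
            chain = _straight_chain(G, h, spec)
            d = min(
                (_min_pair_distance(chain, c) for c in chains), default=np.inf
            )
            if d > best_d:
                best, best_d, best_h = chain, d, h
            if d >= 80.0:
                break
        headings[i] = best_h
        chains.append(best)
    positions = [c[0] for c in chains]

    # scripted-crossing controller: the first member transits a fixed
    # meeting point while the second pursues the first's mid-body with a
    # small speed boost — pursuit of a body point guarantees contact —
    # and the event ends at the first silhouette overlap of the pair
    approach = 90  # activation horizon before the scripted meeting, frames
    meet_points: dict[tuple[int, int], np.ndarray] = {}
    contact_frame: dict[tuple[int, int], int] = {}
    last_touch: dict[tuple[int, int], int] = {}
    run_in: set[tuple[int, int]] = set()  # pairs past the staging phase
    pursuit_boost = 1.3

    frames = np.empty((config.frames, H, W), dtype=np.uint8)
    truth_rows = []
    poses_all: list[list[FishPose]] = []
    overlap_sets: list[set[tuple[int, int]]] = []

    def scripted_targets(t):
        """fish id -> (steer target, speed factor) for active crossings.

        Approach phase: the first member transits the fixed meeting
        point while the second steers an intercept course onto the
        first's rear body (leading its motion keeps the pass transverse;
        pure pursuit would curve into a tail-chase that drags the nose
        along the body).  After first contact the pursuer holds its
        heading and punches straight through — without the commit,
        avoidance would peel it off into a long grazing slide with its
        nose buried in the merged silhouette, exactly the slow kind of
        occlusion that coasting and relinking cannot bridge.
        """
        out = {}
        for ev in config.crossings:
            key = tuple(sorted(ev.pair))
            a, b = key
            if key in contact_frame:
                # commit lasts until the silhouettes have stayed apart for
                # a few frames (first body touch happens long before the
                # pursuer's head has crossed), with a hard cap
                committed = (
                    t <= last_touch.get(key, contact_frame[key]) + 5
                    and t <= contact_frame[key] + 70
                )
                if committed:
                    # both hold course: the pursuer punches through at
                    # approach speed so its nose is buried only briefly,
                    # and the target not turning keeps the pass transverse
                    ahead_b = positions[b] + 300.0 * heading_vector(headings[b])
                    factor = max(pursuit_boost, (speeds[a] + 2.0) / speeds[b],
                                 4.0 / speeds[b])
                    out[b] = (ahead_b, factor, a)
                    ahead_a = positions[a] + 300.0 * heading_vector(headings[a])
                    out[a] = (ahead_a, 1.0, b)
                continue
            if not ev.frame - approach <= t <= ev.frame + 120:
                continue
            if key not in meet_points:
                meet_points[key] = (positions[a] + positions[b]) / 2.0
            # speed floors keep the rate-limited turning maneuverable; the
            # pursuer's boost guarantees closure even on a faster target
            factor = max(pursuit_boost, (speeds[a] + 2.0) / speeds[b],
                         4.0 / speeds[b])
            rear = chains[a][-3]
            ua = heading_vector(headings[a])
            na = np.array([-ua[1], ua[0]])
            abeam = float(na @ (positions[b] - rear))
            if key not in run_in and abs(abeam) < 160.0:
                # staging: hold a position abeam of the target's path so
                # the final run-in crosses the body perpendicular — a
                # stern-chase approach would slide the nose along the
                # body instead of punching across it.  Mutual avoidance
                # stays on (partner None) until the run-in: an early
                # drift into contact would graze instead of crossing.
                side = 1.0 if abeam >= 0 else -1.0
                out[b] = (rear + side * 220.0 * na, factor, None)
                out[a] = (meet_points[key], max(1.0, 4.0 / speeds[a]), None)
                continue
            run_in.add(key)
            eta = float(np.linalg.norm(rear - positions[b])) / (factor * speeds[b])
            lead = rear + eta * speeds[a] * heading_vector(headings[a])
            los = lead - positions[b]
            los /= max(np.linalg.norm(los), 1e-9)
            out[b] = (lead + 80.0 * los, factor, a)
            # the target holds course during the run-in so the crossing
            # angle set up by the staging is not turned away
            ahead_a = positions[a] + 300.0 * heading_vector(headings[a])
            out[a] = (ahead_a, 1.0, b)
        return out

    wall_buffer = 160.0  # > min turn radius: turns complete before the clamp
    avoid_buffer = 280.0  # > 2x min turn radius: evasions complete in time
    center = np.array([W / 2.0, H / 2.0])

    # fish cannot pivot in place: capping the per-frame heading change at
    # speed / R_min enforces a minimum path radius.  The radius must
    # exceed the head-segment length: a head path tighter than that makes
    # the first joint orbit instead of follow, freezing the body until
    # the head folds across it (self-occlusion destroys the nose/tail
    # curvature signature even without a neighbor involved).
    min_turn_radius = 2.0 * spec.lengths[0]

    def turn_toward(i, desired, max_turn, eff_speed=None):
        v = speeds[i] if eff_speed is None else eff_speed
        max_turn = min(max_turn, v / min_turn_radius)
        dh = wrap_angle(desired - headings[i])
        headings[i] = wrap_angle(headings[i] + float(np.clip(dh, -max_turn, max_turn)))

    for t in range(config.frames):
        targets = scripted_targets(t)
        scripted_ids = set(targets)

        # steer, then advance.  All heading changes are rate-limited and
        # the body follows the head's path, so nothing about the
        # silhouette jumps between frames; priorities: scripted crossing,
        # then blended wall/inter-fish avoidance, then random wander.
        def repulsion(i, exclude=()):
            """Inter-fish repulsion on fish i's head, skipping ``exclude``.

            With follow-the-leader bodies a collision can only start with
            this fish's head entering another body, so danger is gauged
            by head-to-skeleton distance and the push comes from the
            closest point of the other body (head-from-head once bodies
            touch, when the nearest point loses meaning).
            """
            v = np.zeros(2)
            for j in range(n):
                if j == i or j in exclude:
                    continue
                dists = np.linalg.norm(chains[j] - positions[i], axis=1)
                k_near = int(np.argmin(dists))
                d = float(dists[k_near])
                if d < avoid_buffer:
                    ref = chains[j][k_near] if d >= 60.0 else positions[j]
                    away = positions[i] - ref
                    if np.linalg.norm(away) < 1e-6:
                        away = heading_vector(headings[i])
                    v += (away / np.linalg.norm(away)) * (
                        2.0 * (1.0 + 3.0 * (avoid_buffer - d) / avoid_buffer)
                    )
            return v

        for i in range(n):
            x, y = positions[i]
            speed_factor = 1.0
            if i in targets:
                # scripted approach still bends around third parties so a
                # choreographed pair does not plough through the school
                target, speed_factor, partner = targets[i]
                to_t = target - positions[i]
                norm = max(np.linalg.norm(to_t), 1e-9)
                steer = 3.0 * to_t / norm + repulsion(i, exclude=(partner,))
                turn_toward(i, float(np.arctan2(-steer[1], steer[0])),
                            3 * config.turning_rate,
                            eff_speed=speed_factor * speeds[i])
            else:
                # blended avoidance: wall and inter-fish repulsion combine
                # into one steering vector so neither is ever ignored
                steer = np.zeros(2)
                wall_pen = max(
                    (margin + wall_buffer) - x, x - (W - margin - wall_buffer),
                    (margin + wall_buffer) - y, y - (H - margin - wall_buffer),
                )
                if wall_pen > 0:
                    to_c = center - positions[i]
                    steer += (to_c / np.linalg.norm(to_c)) * (
                        1.0 + wall_pen / wall_buffer
                    )
                steer += repulsion(i)
                if np.any(steer):
                    turn_toward(i, float(np.arctan2(-steer[1], steer[0])), 0.3)
                else:
                    cap = min(config.turning_rate, speeds[i] / min_turn_radius)
                    headings[i] = wrap_angle(
                        headings[i] + rng.uniform(-cap, cap)
                    )
            wiggle = config.undulation_amplitude * np.sin(
                2.0 * np.pi * t / config.undulation_period + wiggle_phases[i]
            )
            step = speed_factor * speeds[i] * heading_vector(headings[i] + wiggle)
            G_new = positions[i] + step
            # failsafe clamp; the buffers are sized so this stays inactive
            G_new = np.clip(G_new, margin, [W - margin, H - margin])
            chains[i] = _follow_chain(chains[i], G_new, spec)
            positions[i] = chains[i][0]

        # build poses and render
        frame_poses = []
        canvas = np.full((H, W), config.plate_intensity, dtype=float)
        masks = []
        for i in range(n):
            pose = _chain_pose(chains[i], spec, config.nose_margin, t)
            frame_poses.append(pose)
            m = render_silhouette(pose, spec, (H, W))
            masks.append(m)
            canvas[m] = config.fish_intensity
        if config.noise_sigma > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sigma, size=(H, W))
        frames[t] = np.clip(canvas, 0, 255).astype(np.uint8)
        poses_all.append(frame_poses)

        overlaps = set()
        for i in range(n):
            for j in range(i + 1, n):
                # cheap reject before the pixel test
                if _min_pair_distance(_pose_points(frame_poses[i]),
                                      _pose_points(frame_poses[j])) > body_len:
                    continue
                if np.any(masks[i] & masks[j]):
                    overlaps.add((i, j))
        overlap_sets.append(overlaps)
        for pair in overlaps:
            contact_frame.setdefault(pair, t)  # ends scripted pursuit
            last_touch[pair] = t

        for i, pose in enumerate(frame_poses):
            row = {
                "frame": t, "id": i,
                "nose_x": pose.N[0], "nose_y": pose.N[1],
                "G_x": pose.G[0], "G_y": pose.G[1],
                "O_x": pose.O[0], "O_y": pose.O[1],
            }
            for k in range(spec.n_r - 1):
                row[f"J{k + 1}_x"] = pose.J[k, 0]
                row[f"J{k + 1}_y"] = pose.J[k, 1]
            for k in range(spec.n_r):
                row[f"theta_{k + 1}"] = pose.theta[k]
            truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)

    # contiguous per-pair overlap spans -> occlusion events
    events = []
    open_spans: dict[tuple[int, int], int] = {}
    for t, overlaps in enumerate(overlap_sets):
        for pair in overlaps:
            open_spans.setdefault(pair, t)
        for pair in list(open_spans):
            if pair not in overlaps:
                events.append((open_spans.pop(pair), t - 1, pair))
    for pair, st in open_spans.items():
        events.append((st, len(overlap_sets) - 1, pair))
    events.sort()
    occl = pd.DataFrame(
        [
            {"start_frame": st, "end_frame": ed, "ids": f"{p[0]}|{p[1]}"}
            for st, ed, p in events
        ],
        columns=["start_frame", "end_frame", "ids"],
    )

    background = np.full((H, W), config.plate_intensity)
    return SimResult(
        frames=frames, truth=truth, occlusions=occl,
        poses=poses_all, background=background,
    )
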