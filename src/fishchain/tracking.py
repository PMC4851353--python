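"""Two-stage per-frame tracking.

Stage one tracks each fish's head with a constant-velocity Kalman filter
on the state ``[x, y, theta, x_prev, y_prev, theta_prev]`` of the first
joint J_1 and the head orientation, associating trackers to detections
with the Hungarian algorithm under a cost that combines head-patch
normalized cross-correlation with a von Mises orientation-agreement
term.  Stage two refits the body rectangle chain around the tracked
head, drawing candidate segment angles from a von Mises centered on the
previous frame's segment orientations; a refit covering less than 80% of
the fish region vetoes (terminates) the head track.

Tracker lifecycle: an unassociated tracker coasts by linear
extrapolation for up to 5 frames before termination; a tracker that
loses its target with fewer than 2 tracked frames is discarded as a
detection error; each unassociated measurement spawns a new tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import i0 as bessel_i0

from .detection import Detection, HeadObservation, OrientedRectangle, _fit_segments, _region_points, sample_patch
from .model import FishPose, RectangleSpec, build_pose, heading_vector, wrap_angle

__all__ = [
    "KalmanModel",
    "TrackerState",
    "TrackingParams",
    "kalman_predict",
    "kalman_update",
    "coast",
    "ncc",
    "von_mises_similarity",
    "association_cost",
    "build_cost_matrix",
    "associate",
    "track_body",
    "step_frame",
]

_I3 = np.eye(3)


def _default_F() -> np.ndarray:
    F = np.zeros((6, 6))
    F[:3, :3] = 2 * _I3
    F[:3, 3:] = -_I3
    F[3:, :3] = _I3
    return F


def _default_H() -> np.ndarray:
    H = np.zeros((3, 6))
    H[:, :3] = _I3
    return H


@dataclass
class KalmanModel:
    """Constant-velocity transition/observation model with noise covariances.

    ``F`` realizes x_t = 2 x_{t-1} - x_{t-2} on the stacked
    current/previous state; ``H`` observes the current triple.  ``Q`` and
    ``R`` are state and observation noise covariances; the defaults are
    order-of-magnitude values for per-frame motion at ~100 fps and are
    exposed in the pipeline config.
    """

    F: np.ndarray = field(default_factory=_default_F)
    H: np.ndarray = field(default_factory=_default_H)
    Q: np.ndarray = field(default_factory=lambda: np.diag([4.0, 4.0, 0.01, 4.0, 4.0, 0.01]))
    R: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 0.02]))
    P0_factor: float = 10.0

    def initial_P(self) -> np.ndarray:
        return self.P0_factor * self.Q


@dataclass
class TrackerState:
    """One fish's tracker: Kalman state, patch, lifecycle counters, history."""

    id: int
    X: np.ndarray  # [x, y, theta, x_prev, y_prev, theta_prev]
    P: np.ndarray
    patch: np.ndarray  # last associated head patch
    lost_count: int = 0
    history: dict[int, FishPose] = field(default_factory=dict)
    n_measured: int = 1
    start_frame: int = -1

    @property
    def position(self) -> np.ndarray:
        return self.X[:2]

    @property
    def theta(self) -> float:
        return float(self.X[2])

    def last_pose(self) -> FishPose | None:
        if not self.history:
            return None
        return self.history[max(self.history)]


@dataclass
class TrackingParams:
    """Tunables of the tracking stage (association gates, lifecycle, body fit)."""

    thr_ncc: float = 0.6
    thr_v: float = 0.05
    max_assoc_dist: float = 40.0  # gate: px between predicted and measured J_1
    k_orient: float = 4.0  # von Mises concentration of the association term
    k_body: float = 50.0  # concentration of body-segment angle proposals
    n_pb: int = 256
    max_lost: int = 5
    min_history: int = 2
    cover_min: float = 0.8
    spawn_min_dist: float = 30.0  # px: no new tracker on top of a tracked head
    zero_mean_ncc: bool = False


def _wrapped_state(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    X[2] = wrap_angle(X[2])
    X[5] = wrap_angle(X[5])
    return X


def kalman_predict(tr: TrackerState, km: KalmanModel):
    """Prior state and covariance under the constant-velocity model.

    The position part extrapolates linearly; the orientation part
    extrapolates the wrapped angular velocity so a heading crossing the
    -pi/pi seam does not jump.
    """
    X = tr.X
    Xhat = km.F @ X
    # redo the angle with a wrapped difference
    Xhat[2] = X[2] + wrap_angle(X[2] - X[5])
    Xhat[5] = X[2]
    Phat = km.F @ tr.P @ km.F.T + km.Q
    return _wrapped_state(Xhat), Phat


def kalman_update(Xhat: np.ndarray, Phat: np.ndarray, km: KalmanModel, Z):
    """Posterior state/covariance given an observation ``Z = [x, y, theta]``.

    The angle innovation is wrapped.  ``R = 0`` is handled as the
    exact-measurement limit (posterior observed block equals Z); a
    singular but nonzero R is an error.
    """
    Z = np.asarray(Z, dtype=float)
    H = km.H
    if not np.any(km.R):
        K = H.T.copy()
    else:
        S = H @ Phat @ H.T + km.R
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular innovation covariance: R must be positive definite"
            ) from None
        K = Phat @ H.T @ Sinv
    innov = Z - H @ Xhat
    innov[2] = wrap_angle(innov[2])
    X = Xhat + K @ innov
    P = (np.eye(6) - K @ H) @ Phat
    return _wrapped_state(X), P


def coast(tr: TrackerState, km: KalmanModel) -> None:
    """Propagate an unassociated tracker by linear extrapolation in place."""
    Xhat, Phat = kalman_predict(tr, km)
    tr.X, tr.P = Xhat, Phat
    tr.lost_count += 1


def ncc(patch_i: np.ndarray, patch_j: np.ndarray, zero_mean: bool = False) -> float:
    """Energy-normalized cross-correlation of two equal-size patches.

    No mean subtraction by default, so two nonnegative images score in
    [0, 1]; an all-zero patch scores 0.  ``zero_mean=True`` switches to
    the zero-mean variant.
    """
    a = np.asarray(patch_i, dtype=float)
    b = np.asarray(patch_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patches must have equal dimensions")
    if zero_mean:
        a = a - a.mean()
        b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def von_mises_similarity(y: float, mu: float, k: float = 4.0) -> float:
    """Von Mises density exp(k cos(y - mu)) / (2 pi I0(k)) at the wrapped difference."""
    if k <= 0:
        raise ValueError("concentration k must be positive")
    return float(np.exp(k * np.cos(wrap_angle(y - mu))) / (2.0 * np.pi * bessel_i0(k)))


def association_cost(
    ncc_value: float,
    v_value: float,
    thr_ncc: float,
    thr_v: float,
) -> float:
    """Cost exp(-(NCC + V)); infinite when either similarity is gated out."""
    if ncc_value < thr_ncc or v_value < thr_v:
        return np.inf
    return float(np.exp(-(ncc_value + v_value)))


def build_cost_matrix(
    predictions: list[tuple[np.ndarray, np.ndarray]],
    measurements: list[HeadObservation],
    frame: np.ndarray,
    spec: RectangleSpec,
    params: TrackingParams,
    trackers: list[TrackerState] | None = None,
) -> np.ndarray:
    """Association costs between predicted trackers and measurements.

    The tracker side of the NCC term is the patch sampled from the
    *current* frame at the predicted head rectangle, so the score decays
    as the prediction drifts off the fish it claims.  The von Mises term
    compares the predicted orientation against the measurement's.  Pairs
    whose predicted-to-measured J_1 distance exceeds the association
    gate are infeasible outright: at ~100 fps a fish moves a few pixels
    per frame, and for texture-poor silhouettes the appearance term
    alone cannot rule out physically impossible jumps between
    identical-looking fish.
    """
    n, m = len(predictions), len(measurements)
    C = np.full((n, m), np.inf)
    for i, (Xhat, _P) in enumerate(predictions):
        J1 = Xhat[:2]
        th = float(Xhat[2])
        rect = OrientedRectangle(
            J1 + spec.lengths[0] * heading_vector(th),
            th, spec.lengths[0], spec.widths[0],
        )
        pred_patch = None
        for j, meas in enumerate(measurements):
            if np.linalg.norm(meas.J_1 - J1) > params.max_assoc_dist:
                continue
            if pred_patch is None:
                pred_patch = sample_patch(frame, rect)
                if not np.any(pred_patch) and trackers is not None:
                    # predicted rectangle left the canvas
                    pred_patch = trackers[i].patch
            p = meas.patch
            if p.shape != pred_patch.shape:
                continue
            s = ncc(pred_patch, p, zero_mean=params.zero_mean_ncc)
            v = von_mises_similarity(th, meas.theta_1, params.k_orient)
            C[i, j] = association_cost(s, v, params.thr_ncc, params.thr_v)
    return C


_BIG = 1e9


def associate(C: np.ndarray):
    """One-to-one minimum-cost assignment with infeasible (infinite) pairs.

    Solves the square dummy-padded problem with the Hungarian algorithm;
    pairs assigned at infinite cost count as unassociated.  Returns
    (pairs, unassociated tracker rows, unassociated measurement columns).
    """
    C = np.asarray(C, dtype=float)
    n, m = C.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    size = max(n, m)
    padded = np.full((size, size), _BIG)
    padded[:n, :m] = np.where(np.isinf(C), _BIG, C)
    rows, cols = linear_sum_assignment(padded)
    pairs = []
    un_i = set(range(n))
    un_j = set(range(m))
    for r, c in zip(rows, cols):
        if r < n and c < m and np.isfinite(C[r, c]):
            pairs.append((int(r), int(c)))
            un_i.discard(int(r))
            un_j.discard(int(c))
    return pairs, sorted(un_i), sorted(un_j)


def track_body(
    J_1,
    region_mask: np.ndarray,
    prev_pose: FishPose | None,
    theta_1: float,
    spec: RectangleSpec,
    n_pb: int = 256,
    k_body: float = 50.0,
    rng=None,
    ref_area: float | None = None,
    nose_margin: float = 20.0,
) -> FishPose:
    """Refit the body chain around a tracked head with a motion prior.

    Candidate angles for each segment are drawn from a von Mises centered
    on that segment's orientation in the previous frame (uniform draws if
    there is no previous pose).  A cover ratio below the veto threshold
    signals that the head track has wandered off the fish.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    region_pts = _region_points(region_mask)
    J_1 = np.asarray(J_1, dtype=float)

    if prev_pose is None:
        def sampler(i):
            return rng.uniform(0.0, 2.0 * np.pi, size=n_pb)
    else:
        prev_theta = prev_pose.theta

        def sampler(i):
            draws = rng.vonmises(float(prev_theta[i]), k_body, size=n_pb)
            # keep the exact previous orientation in the candidate set so a
            # motionless fish cannot drift
            draws[0] = float(prev_theta[i])
            return draws

    return _fit_segments(J_1, theta_1, spec, region_pts, sampler, ref_area, nose_margin)


@dataclass
class StepResult:
    updated: list[TrackerState]
    spawned: list[TrackerState]
    terminated: list[TrackerState]
    discarded: list[TrackerState]  # short tracks removed from results entirely


def _new_tracker(det: Detection, frame_idx: int, next_id: int, km: KalmanModel) -> TrackerState:
    z = np.array([det.head.J_1[0], det.head.J_1[1], det.head.theta_1])
    X = np.concatenate([z, z])  # duplicated first observation, zero velocity
    pose = det.pose
    pose.frame = frame_idx
    tr = TrackerState(
        id=next_id, X=X, P=km.initial_P(), patch=det.head.patch,
        history={frame_idx: pose}, n_measured=1, start_frame=frame_idx,
    )
    return tr


def _coasted_pose(tr: TrackerState, frame_idx: int, spec: RectangleSpec,
                  nose_margin: float) -> FishPose:
    prev = tr.last_pose()
    thetas = prev.theta.copy() if prev is not None else np.full(spec.n_r, tr.theta)
    thetas[0] = tr.theta
    G = tr.position + spec.lengths[0] * heading_vector(tr.theta)
    pose = build_pose(G, thetas, spec, nose_margin=nose_margin, frame=frame_idx)
    pose.coasted = True
    return pose


def step_frame(
    trackers: list[TrackerState],
    detections: list[Detection],
    frame: np.ndarray,
    region_labels: np.ndarray,
    frame_idx: int,
    spec: RectangleSpec,
    km: KalmanModel,
    params: TrackingParams,
    rng=None,
    next_id: int = 0,
    ref_area: float | None = None,
    nose_margin: float = 20.0,
) -> tuple[StepResult, int]:
    """Advance all trackers by one frame.

    Predict, associate, update-or-coast, refit bodies, apply lifecycle
    rules, spawn trackers for unclaimed measurements.  ``region_labels``
    is the connected-component labeling of the frame's foreground, used
    to attribute a fish region to each tracked head for the body refit.
    Returns the step outcome and the next unused tracker id.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    predictions = [kalman_predict(tr, km) for tr in trackers]
    C = build_cost_matrix(
        predictions, [d.head for d in detections], frame, spec, params, trackers
    )
    pairs, un_trackers, un_meas = associate(C)

    updated: list[TrackerState] = []
    terminated: list[TrackerState] = []
    discarded: list[TrackerState] = []

    for i, j in pairs:
        tr = trackers[i]
        det = detections[j]
        Xhat, Phat = predictions[i]
        Z = np.array([det.head.J_1[0], det.head.J_1[1], det.head.theta_1])
        tr.X, tr.P = kalman_update(Xhat, Phat, km, Z)
        tr.patch = det.head.patch
        tr.lost_count = 0
        label = region_labels[
            min(max(int(round(tr.X[1])), 0), region_labels.shape[0] - 1),
            min(max(int(round(tr.X[0])), 0), region_labels.shape[1] - 1),
        ]
        if label == 0:
            label = det.head.label
        region_mask = region_labels == label if label else np.zeros_like(region_labels, bool)
        pose = track_body(
            tr.X[:2], region_mask, tr.last_pose(), tr.theta, spec,
            n_pb=params.n_pb, k_body=params.k_body, rng=rng,
            ref_area=ref_area, nose_margin=nose_margin,
        )
        pose.frame = frame_idx
        if pose.cover_ratio < params.cover_min:
            # body-fit veto: the head track is not sitting on a fish
            (terminated if tr.n_measured >= params.min_history else discarded).append(tr)
            continue
        tr.history[frame_idx] = pose
        tr.n_measured += 1
        updated.append(tr)

    for i in un_trackers:
        tr = trackers[i]
        if tr.n_measured < params.min_history:
            discarded.append(tr)  # tracking error: trajectory shorter than 2
            continue
        coast(tr, km)
        if tr.lost_count > params.max_lost:
            # the coasted frames stay in the tracklet: its end frame and
            # endpoint J_1 are the extrapolated state at termination,
            # which is what the relinking gap and distance gates measure
            terminated.append(tr)
        else:
            tr.history[frame_idx] = _coasted_pose(tr, frame_idx, spec, nose_margin)
            updated.append(tr)

    spawned = []
    for j in un_meas:
        J1 = detections[j].head.J_1
        # an unassociated measurement sitting on an already-tracked head is
        # a duplicate candidate from a merged blob, not a new fish
        if any(
            np.linalg.norm(tr.X[:2] - J1) < params.spawn_min_dist
            for tr in updated
        ):
            continue
        spawned.append(_new_tracker(detections[j], frame_idx, next_id, km))
        next_id += 1

    return StepResult(updated, spawned, terminated, discarded), next_id
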