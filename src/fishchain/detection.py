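"""Per-frame fish detection.

The detector turns one grayscale frame into a list of fitted poses in
five steps: background subtraction, boundary extraction with equal
arc-length resampling, curvature-based nose/tail keypoint detection,
head-rectangle placement from the boundary geometry around the nose, and
greedy random-search fitting of the body rectangle chain.  Poses whose
rectangles cover less than 80% of the fish region are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .model import (
    FishPose,
    OrientedRectangle,
    RectangleSpec,
    build_pose,
    heading_vector,
    points_in_rectangle,
    vector_angle,
    wrap_angle,
)

__all__ = [
    "BoundaryCurve",
    "CurvatureProfile",
    "HeadObservation",
    "Detection",
    "DetectionParams",
    "estimate_background",
    "robust_background",
    "segment_foreground",
    "extract_boundary",
    "compute_curvature",
    "find_nose_tail",
    "head_from_nose",
    "sample_patch",
    "fit_chain_detection",
    "detect_frame",
]


@dataclass
class BoundaryCurve:
    """Closed fish outline resampled to equal arc-length spacing.

    Points are ordered with consistent winding: counter-clockwise as seen
    on screen (y axis down), which makes convex corners carry positive
    curvature under the sign convention below.
    """

    B: np.ndarray  # (n_bw, 2) float (x, y)
    spacing: float
    label: int = 0  # connected-component label the curve came from

    @property
    def n_bw(self) -> int:
        return len(self.B)

    def point(self, i: int) -> np.ndarray:
        return self.B[i % self.n_bw]


@dataclass
class CurvatureProfile:
    """Signed discrete curvature per boundary point.

    ``C[i]`` approximates d(phi)/ds at point i from the tangential angles
    of the neighbors ``neighbor_arc`` pixels of arc before and after it;
    positive where the outline bends left along the traversal (convex for
    the winding produced by :func:`extract_boundary`).
    """

    C: np.ndarray
    phi: np.ndarray
    neighbor_arc: float


@dataclass
class HeadObservation:
    """Nose point, head orientation, first joint and the head image patch."""

    N: np.ndarray
    theta_1: float
    J_1: np.ndarray
    patch: np.ndarray  # head rectangle rotated to horizontal, (wid_1, len_1)
    nose_index: int = -1
    label: int = 0


@dataclass
class Detection:
    """A validated per-frame detection: fitted pose plus its head observation."""

    pose: FishPose
    head: HeadObservation


@dataclass
class DetectionParams:
    """Tunables of the detection stage.

    ``threshold`` (gray levels) binarizes the background difference;
    ``min_area`` (px) drops specks; ``kappa_min`` (rad/px) separates
    nose/tail curvature peaks from boundary noise; ``n_pb`` is the number
    of candidate angles drawn per body rectangle; ``nose_margin`` (px) is
    how far the head rectangle's front edge is placed ahead of the nose.
    Paper-unstated values are calibration defaults.
    """

    threshold: float = 80.0
    min_area: float = 0.25 * 6250.0
    kappa_min: float = 0.08
    kappa_max: float = 0.165  # nose peaks sit below this; tail tips above
    neighbor_arc: int = 8
    spacing: float = 1.0
    smooth_window: int = 5  # boundary denoise window for curvature only
    n_pb: int = 256
    nose_margin: float = 20.0
    cover_min: float = 0.8
    fish_area: float | None = None  # expected single-fish silhouette area
    seed: int = 0


def estimate_background(frames) -> np.ndarray:
    """Pixel-wise arithmetic mean of a sequence of frames.

    With enough frames of moving fish this approximates the empty,
    uniformly lit plate.
    """
    it = iter(frames)
    try:
        first = np.asarray(next(it), dtype=float)
    except StopIteration:
        raise ValueError("need at least one frame") from None
    acc = first.copy()
    n = 1
    for f in it:
        f = np.asarray(f, dtype=float)
        if f.shape != acc.shape:
            raise ValueError("frames have mismatched dimensions")
        acc += f
        n += 1
    return acc / n


def robust_background(frames, q: float = 1.0, max_samples: int = 31) -> np.ndarray:
    """Pixel-wise maximum (or upper quantile) of a frame subsample.

    For backlit footage the plate is the brightest thing in view, so a
    pixel belongs to the background at its brightest observed value: the
    maximum is immune even to a fish dwelling on a spot for most of a
    short clip (the pixels under a fish's starting position stay dark
    for the first body-length/speed frames, which contaminates a mean or
    mid-quantile on anything but very long recordings).  Gaussian sensor
    noise biases the maximum up by a couple of gray levels, negligible
    against the fish/plate contrast.  ``q < 1`` selects a quantile
    instead; the plain mean (``estimate_background``) remains appropriate
    when thousands of frames are available.
    """
    frames = np.asarray(frames)
    idx = np.linspace(0, len(frames) - 1, min(max_samples, len(frames))).astype(int)
    sample = frames[idx]
    if q >= 1.0:
        return sample.max(axis=0).astype(np.float32)
    return np.quantile(sample.astype(np.float32), q, axis=0)


def segment_foreground(frame, background, threshold: float) -> np.ndarray:
    """Binary foreground mask: |frame - background| > threshold."""
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background dimensions differ")
    return np.abs(frame - background) > threshold


def _resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polyline to (approximately) equal arc spacing."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(round(total / spacing)), 4)
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.stack([x, y], axis=1)


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_boundary(mask: np.ndarray, spacing: float = 1.0,
                     min_area: float = 0.0) -> list[BoundaryCurve]:
    """Trace, orient and resample one closed outline per connected component.

    Components smaller than ``min_area`` are dropped.  Outlines are
    subpixel marching-squares contours of the padded component mask,
    resampled to equal arc-length ``spacing`` and wound counter-clockwise
    on screen (negative shoelace area in raw image coordinates, whose y
    axis points down).
    """
    labels, n_comp = ndimage.label(mask)
    slices = ndimage.find_objects(labels)
    curves: list[BoundaryCurve] = []
    for lab in range(1, n_comp + 1):
        sl = slices[lab - 1]
        comp = labels[sl] == lab
        if comp.sum() < min_area:
            continue
        padded = np.pad(comp, 1).astype(np.float32)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        rc = max(contours, key=len)
        # (row, col) -> (x, y), undo padding and bounding-box crop
        pts = np.stack(
            [rc[:, 1] - 1.0 + sl[1].start, rc[:, 0] - 1.0 + sl[0].start], axis=1
        )
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 4:
            continue
        if _signed_area(pts) > 0:
            pts = pts[::-1]
        B = _resample_closed(pts, spacing)
        curves.append(BoundaryCurve(B=B, spacing=spacing, label=lab))
    return curves


def smooth_curve(curve: BoundaryCurve, window: int) -> BoundaryCurve:
    """Circular moving average of the boundary points (rasterization denoise)."""
    if window <= 1:
        return curve
    B = np.stack(
        [ndimage.uniform_filter1d(curve.B[:, i], window, mode="wrap") for i in (0, 1)],
        axis=1,
    )
    return BoundaryCurve(B=B, spacing=curve.spacing, label=curve.label)


def compute_curvature(curve: BoundaryCurve, neighbor_arc: float = 8.0,
                      smooth_window: int = 0) -> CurvatureProfile:
    """Discrete curvature from tangential angles of arc-offset neighbors.

    The tangential angle at each point is the four-quadrant arctangent of
    the central difference of its immediate neighbors; the curvature at
    point i is the wrapped difference of the tangential angles at the
    points ``neighbor_arc`` of arc before and after i, divided by the arc
    between them.  Using offset neighbors suppresses pixel-level boundary
    noise that two adjacent points would amplify; ``smooth_window`` > 1
    additionally denoises a copy of the curve before differentiation
    (point indices are unchanged, so profile indices still address the
    original curve).
    """
    if smooth_window > 1:
        curve = smooth_curve(curve, smooth_window)
    B = curve.B
    n = curve.n_bw
    off = max(int(round(neighbor_arc / curve.spacing)), 1)
    if n <= 2 * off + 2:
        raise ValueError("boundary curve too short for this neighbor arc")
    phi = np.arctan2(
        np.roll(B[:, 1], -1) - np.roll(B[:, 1], 1),
        np.roll(B[:, 0], -1) - np.roll(B[:, 0], 1),
    )
    dphi = wrap_angle(np.roll(phi, off) - np.roll(phi, -off))
    C = dphi / (2.0 * off * curve.spacing)
    return CurvatureProfile(C=C, phi=phi, neighbor_arc=off * curve.spacing)


def _local_maxima_circular(C: np.ndarray, threshold: float, window: int) -> list[int]:
    """Indices that are the strict maximum of their cyclic +-window slice."""
    n = len(C)
    idx = []
    for i in np.flatnonzero(C > threshold):
        sl = C[(np.arange(i - window, i + window + 1)) % n]
        if C[i] >= sl.max() and i == ((i - window + int(np.argmax(sl))) % n):
            idx.append(int(i))
    return idx


def find_nose_tail(profile: CurvatureProfile, kappa_min: float,
                   window: int | None = None,
                   kappa_max: float | None = None) -> list[tuple[int, int | None]]:
    """Locate nose (and tail) candidates among positive curvature peaks.

    Supra-threshold local maxima of the curvature are keypoint
    candidates; negative-curvature corners (occlusion intersections) are
    never candidates.  An isolated fish shows exactly two peaks, the
    lower of which is the nose and the higher the tail.  Any other peak
    count means the blob holds several (occluding) fish or extra bend
    peaks, so every peak is returned as a nose candidate, pruned
    downstream by the cover-ratio check and association.  ``kappa_max``
    generalizes the lower-is-nose rule to those multi-peak blobs: the
    blunt nose tip always turns less sharply than the pointed tail tip,
    so peaks above the bound are tails, never nose candidates.
    """
    if window is None:
        # nose and tail sit half a body perimeter apart, so suppression
        # can be generous: weak satellites of a true corner (rasterization
        # shoulders, neck bends near the head) die, while distinct
        # keypoints — even two noses of occluding fish — survive
        window = max(int(round(5 * profile.neighbor_arc)), 1)
    peaks = _local_maxima_circular(profile.C, kappa_min, window)
    if not peaks:
        return []
    if len(peaks) == 2:
        lo, hi = sorted(peaks, key=lambda i: profile.C[i])
        return [(lo, hi)]
    if kappa_max is not None:
        peaks = [i for i in peaks if profile.C[i] <= kappa_max]
    return [(i, None) for i in peaks]


def sample_patch(frame: np.ndarray, rect: OrientedRectangle) -> np.ndarray:
    """Grayscale patch of an oriented rectangle, rotated to horizontal.

    Rows run across the rectangle (width), columns along its axis from
    front edge to back edge; output shape is (width, length) rounded to
    integers.  Bilinear sampling; out-of-canvas pixels take the nearest
    edge value.
    """
    h = max(int(round(rect.width)), 1)
    w = max(int(round(rect.length)), 1)
    u = heading_vector(rect.theta)
    nvec = np.array([-u[1], u[0]])
    t = (np.arange(w) + 0.5) / w * rect.length
    s = ((np.arange(h) + 0.5) / h - 0.5) * rect.width
    tt, ss = np.meshgrid(t, s)
    xs = rect.anchor[0] - tt * u[0] + ss * nvec[0]
    ys = rect.anchor[1] - tt * u[1] + ss * nvec[1]
    return ndimage.map_coordinates(
        np.asarray(frame, dtype=float), [ys, xs], order=1, mode="nearest"
    )


def _interp_point(B: np.ndarray, fidx: float) -> np.ndarray:
    """Linear interpolation on a closed point sequence at a fractional index."""
    n = len(B)
    i0 = int(np.floor(fidx)) % n
    frac = fidx - np.floor(fidx)
    return (1.0 - frac) * B[i0] + frac * B[(i0 + 1) % n]


def refine_peak(profile: CurvatureProfile, index: int,
                window: int | None = None) -> float:
    """Sub-index peak position as the curvature-weighted centroid.

    The traced outline of a rasterized sharp corner carries a small flat
    facet at the very tip, so the pointwise curvature maximum can sit a
    few points off the apex between twin shoulder peaks.  The centroid of
    the contiguous high-curvature run around the detected maximum is a
    stable apex estimate.
    """
    n = len(profile.C)
    if window is None:
        window = max(int(round(profile.neighbor_arc)), 1)
    offs = np.arange(-window, window + 1)
    c = profile.C[(index + offs) % n]
    keep = c >= 0.6 * float(profile.C[index % n])
    # restrict to the contiguous run containing the peak itself
    mid = window
    lo = mid
    while lo > 0 and keep[lo - 1]:
        lo -= 1
    hi = mid
    while hi < len(offs) - 1 and keep[hi + 1]:
        hi += 1
    w = c[lo:hi + 1]
    return index + float(np.sum(w * offs[lo:hi + 1]) / np.sum(w))


def _corner_refine(curve: BoundaryCurve, index: float,
                   off_near: int = 4, off_far: int = 20):
    """Sub-pixel apex and axis of a boundary corner from its flank lines.

    The traced contour of a binarized silhouette rounds sharp corners by
    one or two pixels, so the curvature-peak point sits slightly inside
    the physical tip and the two-point chord around it is noisy.  A
    total-least-squares line through each flank (points
    ``off_near``..``off_far`` of arc away on either side) recovers the
    corner robustly: the lines' intersection is the apex, and the
    bisector of their outward directions is the corner axis — the
    least-squares version of the perpendicular bisector of the chord
    between equidistant flank points.  Returns ``(apex, axis unit vector
    pointing outward)``; the axis is None when the flanks are
    near-parallel (rounded corner) or the intersection is implausible,
    and the apex then falls back to the peak point itself.
    """
    n = curve.n_bw
    peak = _interp_point(curve.B, index)
    i = int(round(index))
    fits = []
    for sign in (-1, 1):
        idx = (i + sign * np.arange(off_near, off_far + 1)) % n
        pts = curve.B[idx]
        mean = pts.mean(axis=0)
        _u, _s, vt = np.linalg.svd(pts - mean, full_matrices=False)
        d = vt[0]
        if float(d @ (mean - peak)) < 0:
            d = -d  # orient the flank direction away from the corner
        fits.append((mean, d))
    (a1, d1), (a2, d2) = fits
    inward = d1 + d2
    if np.linalg.norm(inward) < 1e-6:
        return peak, None
    axis = -inward / np.linalg.norm(inward)
    det = d1[0] * (-d2[1]) - (-d2[0]) * d1[1]
    if abs(det) < 1e-3:
        return peak, axis
    rhs = a2 - a1
    t1 = (rhs[0] * (-d2[1]) - (-d2[0]) * rhs[1]) / det
    apex = a1 + t1 * d1
    if np.linalg.norm(apex - peak) > 5.0:
        return peak, axis
    return apex, axis


def head_from_nose(
    curve: BoundaryCurve,
    nose_index: float,
    spec: RectangleSpec,
    frame: np.ndarray,
    neighbor_arc: float = 8.0,
    nose_margin: float = 20.0,
    profile: CurvatureProfile | None = None,
) -> HeadObservation:
    """Place the head rectangle from the boundary geometry around the nose.

    The head orientation is the direction of the perpendicular bisector
    of the segment joining the boundary neighbors ``neighbor_arc`` of arc
    on either side of the nose, signed to point outward through the nose
    (the head is laterally symmetric about the body axis, so the bisector
    runs along it).  The head rectangle's front edge is placed
    ``nose_margin`` pixels ahead of the nose so the nose is interior.
    When the curvature profile is supplied the nose is refined to the
    sub-index peak position before the geometry is built.
    """
    off = max(int(round(neighbor_arc / curve.spacing)), 1)
    fidx = refine_peak(profile, int(nose_index)) if profile is not None else float(nose_index)
    N, axis = _corner_refine(curve, fidx)
    if axis is not None:
        theta_1 = vector_angle(axis)
    else:
        # perpendicular bisector of the chord between the arc-offset
        # neighbors, signed to point outward through the nose
        Bl = _interp_point(curve.B, fidx - off)
        Br = _interp_point(curve.B, fidx + off)
        mid = (Bl + Br) / 2.0
        chord = Br - Bl
        v = np.array([chord[1], -chord[0]])
        outward = N - mid
        if np.linalg.norm(outward) < 1e-9 or np.linalg.norm(v) < 1e-9:
            v = outward if np.linalg.norm(outward) > 0 else np.array([1.0, 0.0])
        elif float(v @ outward) < 0:
            v = -v
        theta_1 = vector_angle(v)
    u = heading_vector(theta_1)
    G = N + nose_margin * u
    J_1 = G - spec.lengths[0] * u
    rect = OrientedRectangle(G, theta_1, spec.lengths[0], spec.widths[0])
    patch = sample_patch(frame, rect)
    return HeadObservation(
        N=N, theta_1=theta_1, J_1=J_1, patch=patch, nose_index=nose_index,
        label=curve.label,
    )


def _region_points(region_mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(region_mask)
    return np.stack([xs, ys], axis=1).astype(float)


def _fit_segments(
    J_1: np.ndarray,
    theta_1: float,
    spec: RectangleSpec,
    region_pts: np.ndarray,
    angle_sampler,
    ref_area: float | None,
    nose_margin: float,
) -> FishPose:
    """Greedy chain fit shared by detection and body tracking.

    Rectangles 2..n_r are fixed one at a time: ``angle_sampler(i)``
    proposes candidate orientations for rectangle i, each candidate is
    scored by the number of still-uncovered region pixels it would cover,
    and the best one is kept (ties broken toward the previous segment's
    orientation).  The cover ratio is then the fraction of the region (or
    of ``ref_area`` pixels, if the region is a merged multi-fish blob)
    under the union of all rectangles.
    """
    n_pts = len(region_pts)
    G = J_1 + spec.lengths[0] * heading_vector(theta_1)
    thetas = [theta_1]
    covered = np.zeros(n_pts, dtype=bool)
    if n_pts:
        head = OrientedRectangle(G, theta_1, spec.lengths[0], spec.widths[0])
        covered |= points_in_rectangle(region_pts, head)
    anchor = J_1.copy()
    for i in range(1, spec.n_r):
        length, width = spec.lengths[i], spec.widths[i]
        cands = np.atleast_1d(angle_sampler(i))
        if n_pts:
            near = np.linalg.norm(region_pts - anchor, axis=1) <= length + width
            pts = region_pts[near & ~covered]
        else:
            pts = region_pts
        if len(pts):
            d = pts - anchor
            cos, sin = np.cos(cands), np.sin(cands)
            # axial coordinate t = -(d . u), lateral s = d . n, per candidate
            t = d @ np.stack([-cos, sin])
            s = d @ np.stack([sin, cos])
            inside = (t >= 0) & (t < length) & (np.abs(s) < width / 2)
            counts = inside.sum(axis=0)
        else:
            counts = np.zeros(len(cands), dtype=int)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        prev = thetas[-1]
        pick = tied[np.argmin(np.abs(wrap_angle(cands[tied] - prev)))]
        th = float(cands[pick])
        thetas.append(th)
        if len(pts) and best > 0:
            sel = np.flatnonzero(near & ~covered)[inside[:, pick]]
            covered[sel] = True
        anchor = anchor - length * heading_vector(th)
    pose = build_pose(G, np.array(thetas), spec, nose_margin=nose_margin)
    if n_pts == 0:
        pose.cover_ratio = 0.0
    else:
        denom = n_pts if ref_area is None else min(n_pts, ref_area)
        pose.cover_ratio = float(covered.sum()) / denom
    return pose


def fit_chain_detection(
    J_1,
    theta_1: float,
    spec: RectangleSpec,
    region_mask: np.ndarray,
    n_pb: int = 256,
    rng=None,
    ref_area: float | None = None,
    nose_margin: float = 20.0,
) -> FishPose:
    """Fit body rectangles by sequential random search over orientations.

    With no pose prior, each body rectangle draws ``n_pb`` candidate
    angles uniformly on [0, 2pi) and keeps the one covering the most
    still-unclaimed foreground.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    region_pts = _region_points(region_mask)
    J_1 = np.asarray(J_1, dtype=float)

    def sampler(i):
        return rng.uniform(0.0, 2.0 * np.pi, size=n_pb)

    return _fit_segments(J_1, theta_1, spec, region_pts, sampler, ref_area, nose_margin)


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    params: DetectionParams,
    spec: RectangleSpec,
    rng=None,
) -> list[Detection]:
    """Detect and fit every fish in one frame.

    Composes segmentation, boundary extraction, curvature keypointing,
    head placement and chain fitting over all blobs and nose candidates;
    poses covering less than ``cover_min`` of their fish region are
    dropped.
    """
    rng = np.random.default_rng(params.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    mask = segment_foreground(frame, background, params.threshold)
    curves = extract_boundary(mask, spacing=params.spacing, min_area=params.min_area)
    labels, _ = ndimage.label(mask)
    out: list[Detection] = []
    for curve in curves:
        profile = compute_curvature(
            curve, neighbor_arc=params.neighbor_arc,
            smooth_window=params.smooth_window,
        )
        candidates = find_nose_tail(profile, params.kappa_min,
                                    kappa_max=params.kappa_max)
        region_mask = labels == curve.label
        for nose_idx, _tail in candidates:
            head = head_from_nose(
                curve, nose_idx, spec, frame,
                neighbor_arc=params.neighbor_arc, nose_margin=params.nose_margin,
                profile=profile,
            )
            pose = fit_chain_detection(
                head.J_1, head.theta_1, spec, region_mask,
                n_pb=params.n_pb, rng=rng, ref_area=params.fish_area,
                nose_margin=params.nose_margin,
            )
            if pose.cover_ratio >= params.cover_min:
                out.append(Detection(pose=pose, head=head))
    return _dedupe(out, min_sep=spec.widths[0] / 2.0)


def _dedupe(dets: list[Detection], min_sep: float) -> list[Detection]:
    """Keep the best-covering detection among near-coincident noses."""
    dets = sorted(dets, key=lambda d: -d.pose.cover_ratio)
    kept: list[Detection] = []
    for d in dets:
        if all(np.linalg.norm(d.pose.N - k.pose.N) >= min_sep for k in kept):
            kept.append(d)
    return kept
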