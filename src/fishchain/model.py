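"""Chained-rectangle fish body model.

A fish silhouette seen from above is represented by a chain of ``n_r``
oriented rectangles: a long rigid head rectangle followed by body
rectangles of decreasing width that articulate at joints.  The model is
shared by the detector (random-search chain fitting), the tracker (pose
refinement with a motion prior) and the synthetic-sequence generator.

Coordinate conventions
----------------------
Image pixel coordinates: origin at the top-left corner, ``x`` rightward,
``y`` downward, 0-based; a pixel's center coincides with its integer
index.  Angles are measured counter-clockwise in the standard
mathematical convention on ``(x, -y)``, so the unit vector of a heading
``theta`` is ``(cos(theta), -sin(theta))`` in image coordinates.

Each rectangle is anchored at the midpoint of its *front* edge and spans
backwards (against its orientation) by its length; its width is centered
on the axis.  The orientation of every rectangle points from the fish's
tail toward its head, so ``theta[0]`` is the swimming direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RectangleSpec",
    "OrientedRectangle",
    "FishPose",
    "DEFAULT_SPEC",
    "wrap_angle",
    "heading_vector",
    "vector_angle",
    "build_pose",
    "rectangle_corners",
    "rasterize_rectangle",
    "render_pose",
    "cover_ratio",
    "chain_lengths",
]


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return float(out) if out.ndim == 0 else out


def heading_vector(theta):
    """Unit vector(s) of heading ``theta`` in image coordinates (y down)."""
    theta = np.asarray(theta, dtype=float)
    return np.stack([np.cos(theta), -np.sin(theta)], axis=-1)


def vector_angle(v) -> float:
    """Heading angle of an image-coordinate vector (inverse of heading_vector)."""
    v = np.asarray(v, dtype=float)
    return float(np.arctan2(-v[..., 1], v[..., 0]))


@dataclass(frozen=True)
class RectangleSpec:
    """Sizes of the rectangle chain.

    The head rectangle (index 0) is the longest so that the nose always
    falls inside it; body rectangles share one length and taper in width
    toward the tail.  Defaults are the calibrated sizes for adult
    zebrafish imaged at roughly 10 px/mm.
    """

    lengths: tuple = (50, 30, 30, 30, 30, 30, 30, 30)
    widths: tuple = (35, 35, 35, 26, 20, 15, 11, 8)

    def __post_init__(self):
        if len(self.lengths) != len(self.widths):
            raise ValueError("lengths and widths must have equal arity")
        if len(self.lengths) < 2:
            raise ValueError("a chain needs at least 2 rectangles")
        if any(l <= 0 for l in self.lengths) or any(w <= 0 for w in self.widths):
            raise ValueError("rectangle sizes must be positive")
        if any(self.lengths[0] <= l for l in self.lengths[1:]):
            raise ValueError("head rectangle must be the longest")

    @property
    def n_r(self) -> int:
        return len(self.lengths)

    def scaled(self, factor: float) -> "RectangleSpec":
        """Optional per-detection scale hook (off by default in the pipeline)."""
        return RectangleSpec(
            tuple(l * factor for l in self.lengths),
            tuple(w * factor for w in self.widths),
        )

    @property
    def body_area(self) -> float:
        return float(sum(l * w for l, w in zip(self.lengths, self.widths)))


DEFAULT_SPEC = RectangleSpec()


@dataclass(frozen=True)
class OrientedRectangle:
    anchor: np.ndarray  # midpoint of the front edge, (x, y) pixels
    theta: float  # axis orientation, back -> front
    length: float
    width: float


@dataclass
class FishPose:
    """One fish's fitted rectangle chain in one frame.

    ``G`` is the midpoint of the head rectangle's front edge, ``N`` the
    nose point (interior to the head rectangle), ``J`` the ``n_r - 1``
    joints between consecutive rectangles and ``O`` the midpoint of the
    last rectangle's back edge.  ``theta[i]`` orients rectangle ``i``.
    """

    G: np.ndarray
    N: np.ndarray
    J: np.ndarray  # (n_r - 1, 2)
    O: np.ndarray
    theta: np.ndarray  # (n_r,)
    cover_ratio: float = np.nan
    frame: int = -1
    coasted: bool = False

    def anchors(self) -> np.ndarray:
        """Front-edge midpoints of all rectangles: G, J_1 .. J_{n_r-1}."""
        return np.vstack([self.G[None, :], self.J])

    def rectangles(self, spec: RectangleSpec):
        return [
            OrientedRectangle(a, float(t), float(l), float(w))
            for a, t, l, w in zip(
                self.anchors(), self.theta, spec.lengths, spec.widths
            )
        ]

    def translated(self, delta) -> "FishPose":
        d = np.asarray(delta, dtype=float)
        return replace(
            self,
            G=self.G + d,
            N=self.N + d,
            J=self.J + d,
            O=self.O + d,
            theta=self.theta.copy(),
        )


def chain_lengths(pose: FishPose) -> np.ndarray:
    """Measured distances along the chain G->J_1->...->O."""
    pts = np.vstack([pose.G[None, :], pose.J, pose.O[None, :]])
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def build_pose(
    G,
    thetas,
    spec: RectangleSpec,
    nose_margin: float = 20.0,
    frame: int = -1,
) -> FishPose:
    """Construct a chain-consistent pose from the head front point and angles.

    The nose is placed ``nose_margin`` pixels behind the front edge along
    the head axis, which keeps it strictly inside the head rectangle.
    """
    G = np.asarray(G, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if thetas.shape != (spec.n_r,):
        raise ValueError(f"expected {spec.n_r} angles, got {thetas.shape}")
    pts = [G]
    for length, th in zip(spec.lengths, thetas):
        pts.append(pts[-1] - length * heading_vector(th))
    pts = np.asarray(pts)
    N = G - nose_margin * heading_vector(thetas[0])
    return FishPose(
        G=G, N=N, J=pts[1:-1], O=pts[-1], theta=thetas, frame=frame
    )


def rectangle_corners(rect: OrientedRectangle) -> np.ndarray:
    """Corners in order: front-left, front-right, back-right, back-left."""
    u = heading_vector(rect.theta)
    n = np.array([-u[1], u[0]])
    hw = rect.width / 2.0
    a = np.asarray(rect.anchor, dtype=float)
    return np.array(
        [
            a + hw * n,
            a - hw * n,
            a - hw * n - rect.length * u,
            a + hw * n - rect.length * u,
        ]
    )


def points_in_rectangle(points: np.ndarray, rect: OrientedRectangle) -> np.ndarray:
    """Membership test used for rasterization.

    A point belongs to the rectangle iff its axial coordinate lies in
    ``[0, length)`` measured backwards from the front edge and its lateral
    coordinate in ``[-width/2, width/2)`` — half-open on the far side so
    that abutting rectangles tile without double-counting seams.
    """
    u = heading_vector(rect.theta)
    n = np.array([-u[1], u[0]])
    d = np.asarray(points, dtype=float) - np.asarray(rect.anchor, dtype=float)
    t = -(d @ u)
    s = d @ n
    return (t >= 0) & (t < rect.length) & (s >= -rect.width / 2) & (s < rect.width / 2)


def rasterize_rectangle(rect: OrientedRectangle, canvas: np.ndarray) -> None:
    """OR the rectangle into a boolean canvas, clipping silently at edges."""
    corners = rectangle_corners(rect)
    x0 = max(int(np.floor(corners[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(corners[:, 0].max())) + 2, canvas.shape[1])
    y0 = max(int(np.floor(corners[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(corners[:, 1].max())) + 2, canvas.shape[0])
    if x0 >= x1 or y0 >= y1:
        return
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)
    inside = points_in_rectangle(pts, rect).reshape(ys.shape)
    canvas[y0:y1, x0:x1] |= inside


def render_pose(pose: FishPose, spec: RectangleSpec, canvas_shape) -> np.ndarray:
    """Rasterize the union of the pose's rectangles onto a boolean canvas.

    Parts of the pose extending outside the canvas are clipped silently.
    """
    canvas = np.zeros(canvas_shape, dtype=bool)
    for rect in pose.rectangles(spec):
        rasterize_rectangle(rect, canvas)
    return canvas


def cover_ratio(
    pose: FishPose,
    spec: RectangleSpec,
    mask: np.ndarray,
    ref_area: float | None = None,
) -> float:
    """Fraction of a fish's foreground region covered by its rectangles.

    ``mask`` is the boolean foreground region attributed to the fish (its
    connected component).  The denominator is the region size, optionally
    capped at ``ref_area``, the expected silhouette area of a single
    fish.  The cap matters when regions of several occluding fish merge
    into one component: the component is then much larger than any one
    fish, and a pose should be scored against one fish's worth of pixels
    rather than the whole merged blob.
    """
    region_size = int(np.count_nonzero(mask))
    if region_size == 0:
        raise ValueError("empty region: degenerate detection")
    rendered = render_pose(pose, spec, mask.shape)
    covered = int(np.count_nonzero(rendered & mask))
    denom = region_size if ref_area is None else min(region_size, float(ref_area))
    return covered / denom
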