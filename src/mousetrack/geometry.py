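"""Ellipse abstraction of a single mouse and the mask -> ellipse fit.

A tracked mouse is reduced to six numbers: center ``(x, y)``, full major and
minor axis lengths, and the heading angle encoded as ``(sin theta, cos theta)``.
Angles live on a display-space polar grid: 0 deg points along +x (rightward on
screen), angles increase counterclockwise *as seen on screen*.  Because array
row indices grow downward, all trigonometry here negates the row axis.

A silhouette only defines orientation modulo 180 deg; the head direction is
recovered separately from a four-class quadrant prediction (up / left / down /
right, the four half-open 90 deg spans centred on 90 / 180 / 270 / 0 deg).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class NoDetection:
    """Sentinel for frames where no mouse was found.

    A first-class result value: it propagates through tracks and metrics as a
    missing frame, it is never silently interpolated.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_DETECTION"

    def __bool__(self) -> bool:
        return False


NO_DETECTION = NoDetection()


class CardinalDirection(enum.IntEnum):
    """Quadrant classes for head direction on the polar grid.

    Spans are half-open, lower-inclusive, and partition [0, 360):
    up [45, 135), left [135, 225), down [225, 315), right [315, 45).
    The boundaries sit between the cardinal headings so that a mouse walking
    straight along an arena wall does not oscillate between classes.
    """

    UP = 0
    LEFT = 1
    DOWN = 2
    RIGHT = 3

    @property
    def center_deg(self) -> float:
        return {self.UP: 90.0, self.LEFT: 180.0, self.DOWN: 270.0, self.RIGHT: 0.0}[self]

    @classmethod
    def from_name(cls, name: str) -> "CardinalDirection":
        return cls[name.upper()]


@dataclass(frozen=True)
class EllipseFit:
    """Directed ellipse: the six-parameter abstraction of a mouse.

    ``x`` is the column coordinate of the center, ``y`` the row coordinate,
    both in px.  ``major``/``minor`` are *full* axis lengths in px.  The
    heading is stored as its sine and cosine to avoid the 0/360 discontinuity.
    """

    x: float
    y: float
    major: float
    minor: float
    sin_theta: float
    cos_theta: float

    def __post_init__(self):
        norm = math.hypot(self.sin_theta, self.cos_theta)
        if norm > 0 and abs(norm - 1.0) > 1e-9:
            object.__setattr__(self, "sin_theta", self.sin_theta / norm)
            object.__setattr__(self, "cos_theta", self.cos_theta / norm)

    @classmethod
    def from_angle(cls, x: float, y: float, major: float, minor: float,
                   theta_deg: float) -> "EllipseFit":
        t = math.radians(theta_deg % 360.0)
        return cls(x, y, major, minor, math.sin(t), math.cos(t))

    @property
    def theta_deg(self) -> float:
        """Heading in degrees, in [0, 360)."""
        return math.degrees(math.atan2(self.sin_theta, self.cos_theta)) % 360.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.x, self.y, self.major, self.minor,
                         self.sin_theta, self.cos_theta], dtype=np.float64)


@dataclass(frozen=True)
class UndirectedEllipse:
    """Ellipse whose orientation is defined only modulo 180 deg.

    This is what a silhouette alone determines; ``theta_deg`` stores the
    representative angle in [0, 180).
    """

    x: float
    y: float
    major: float
    minor: float
    theta_deg: float

    def __post_init__(self):
        object.__setattr__(self, "theta_deg", self.theta_deg % 180.0)

    def directed(self, theta_deg: float) -> EllipseFit:
        return EllipseFit.from_angle(self.x, self.y, self.major, self.minor, theta_deg)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Single-animal assumption: the biggest blob is the mouse.  Empty input
    yields an empty mask of the same shape.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask, dtype=np.uint8)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == int(np.argmax(counts))).astype(np.uint8)


def fit_ellipse_to_mask(mask: np.ndarray):
    """Fit the equivalent-second-moment ellipse to the largest blob of a mask.

    Center = centroid of foreground pixels; axes = full axes of the ellipse
    whose second moments match the pixel region (full axis = 4 * sqrt of a
    covariance eigenvalue, so a filled disc of radius r maps to axis 2r);
    orientation = principal eigenvector angle, display-space, mod 180.

    Returns :data:`NO_DETECTION` on an empty mask.
    """
    mask = largest_component(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return NO_DETECTION
    x = cols.astype(np.float64)
    y_up = -rows.astype(np.float64)  # display space: +y is up on screen
    cx = x.mean()
    cy_up = y_up.mean()
    dx = x - cx
    dy = y_up - cy_up
    cxx = np.mean(dx * dx)
    cyy = np.mean(dy * dy)
    cxy = np.mean(dx * dy)
    # closed-form eigendecomposition of the 2x2 covariance
    tr = cxx + cyy
    det = cxx * cyy - cxy * cxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)  # major
    lam2 = max(tr / 2.0 - math.sqrt(disc), 0.0)
    theta = 0.5 * math.degrees(math.atan2(2.0 * cxy, cxx - cyy))
    return UndirectedEllipse(
        x=cx,
        y=-cy_up,
        major=4.0 * math.sqrt(lam1),
        minor=4.0 * math.sqrt(lam2),
        theta_deg=theta % 180.0,
    )


def quadrant_of_angle(theta_deg: float) -> CardinalDirection:
    """Map a heading (any real, degrees) to its cardinal-direction quadrant."""
    t = float(theta_deg) % 360.0
    if 45.0 <= t < 135.0:
        return CardinalDirection.UP
    if 135.0 <= t < 225.0:
        return CardinalDirection.LEFT
    if 225.0 <= t < 315.0:
        return CardinalDirection.DOWN
    return CardinalDirection.RIGHT


def _circular_distance_deg(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def resolve_direction(e: UndirectedEllipse, q: CardinalDirection) -> EllipseFit:
    """Disambiguate the +-180 deg heading of an undirected ellipse.

    Of the two candidates ``theta`` and ``theta + 180``, the one closer (on
    the circle) to the center of the quadrant's span is chosen.  Whenever one
    candidate lies strictly inside the span this picks it; on boundary
    degeneracies the closer candidate wins.
    """
    t0 = e.theta_deg % 360.0
    t1 = (t0 + 180.0) % 360.0
    c = q.center_deg
    chosen = t0 if _circular_distance_deg(t0, c) <= _circular_distance_deg(t1, c) else t1
    return e.directed(chosen)


def rasterize_ellipse(e, shape) -> np.ndarray:
    """Rasterize an ellipse to a binary mask of the given (rows, cols) shape.

    A pixel is foreground iff its integer-coordinate center satisfies the
    implicit inequality with semi-axes major/2, minor/2.  Degenerate axes
    produce an empty mask.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    if e.major <= 0 or e.minor <= 0:
        return np.zeros((rows, cols), dtype=np.uint8)
    theta = e.theta_deg if isinstance(e, UndirectedEllipse) else e.theta_deg
    t = math.radians(theta)
    rr, cc = np.mgrid[0:rows, 0:cols]
    dx = cc - e.x
    dy = -(rr - e.y)  # display space
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    a = e.major / 2.0
    b = e.minor / 2.0
    return (((u / a) ** 2 + (v / b) ** 2) <= 1.0).astype(np.uint8)
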