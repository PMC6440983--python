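"""Evaluation statistics for comparing trackers.

Four statistics: center (hypotenuse) error, intersection-over-union of masks
or rasterized ellipses, cumulative relative error of distance traveled, and
the relative standard deviation of the minor axis (a stability proxy — the
width of a mouse stays nearly constant across postures, so a noisy minor-axis
series indicates unstable segmentation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .geometry import NO_DETECTION, EllipseFit, rasterize_ellipse


@dataclass
class Track:
    """Time-ordered per-frame ellipse fits with acquisition calibration.

    ``records`` is a list of ``(frame_index, EllipseFit | NO_DETECTION)``
    with strictly increasing frame indices.  Default calibration matches the
    acquisition convention of 30 fps and a zoom of 8 px/cm.
    """

    records: List[Tuple[int, object]] = field(default_factory=list)
    fps: float = 30.0
    px_per_cm: float = 8.0

    def __post_init__(self):
        if self.fps <= 0 or self.px_per_cm <= 0:
            raise ValueError("fps and px_per_cm must be positive")
        idx = [f for f, _ in self.records]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def append(self, frame: int, fit) -> None:
        if self.records and frame <= self.records[-1][0]:
            raise ValueError("frame indices must be strictly increasing")
        self.records.append((frame, fit))

    @property
    def n_frames(self) -> int:
        return len(self.records)

    def detected(self) -> List[Tuple[int, EllipseFit]]:
        return [(f, e) for f, e in self.records if e is not NO_DETECTION and e is not None]

    @property
    def detection_rate(self) -> float:
        return len(self.detected()) / len(self.records) if self.records else 0.0


@dataclass
class TrackingMetrics:
    center_error_px: float
    iou: float
    cum_rel_distance_error: float
    minor_axis_rsd: float


def center_error(a, b):
    """Euclidean distance between the centers of two fits, px.

    Either argument being NO_DETECTION yields NO_DETECTION (an
    undefined-for-frame marker); callers exclude and count those frames.
    """
    if a is NO_DETECTION or b is NO_DETECTION or a is None or b is None:
        return NO_DETECTION
    return math.hypot(a.x - b.x, a.y - b.y)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks of equal shape.

    Two empty masks agree perfectly on absence: IoU = 1.0.  One empty, one
    not: 0.0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def ellipse_iou(a, b, shape) -> float:
    """IoU of two ellipse abstractions, computed on their rasterizations."""
    if a is NO_DETECTION or b is NO_DETECTION:
        return NO_DETECTION
    return mask_iou(rasterize_ellipse(a, shape), rasterize_ellipse(b, shape))


def total_distance(t: Track, up_to_frame: Optional[int] = None) -> float:
    """Total distance traveled, cm.

    Sums center displacement over consecutive *detected* frames; a gap of
    NoDetection frames contributes the straight-line displacement between
    the flanking detections (dropping those frames entirely would deflate
    the distance).
    """
    det = t.detected()
    if up_to_frame is not None:
        det = [(f, e) for f, e in det if f <= up_to_frame]
    if not det:
        warnings.warn("track has no detections; total distance is 0")
        return 0.0
    d = 0.0
    for (_, e0), (_, e1) in zip(det, det[1:]):
        d += math.hypot(e1.x - e0.x, e1.y - e0.y)
    return d / t.px_per_cm


def per_minute_distances(t: Track) -> np.ndarray:
    """Distance traveled (cm) in each whole minute of the track.

    Minute bins are floor(frame / (60 * fps)); each inter-detection
    displacement is credited to the bin of its earlier frame.  A trailing
    partial minute forms its own bin.
    """
    det = t.detected()
    if not det:
        return np.zeros(0)
    frames_per_min = 60.0 * t.fps
    last_frame = t.records[-1][0]
    n_bins = int(last_frame // frames_per_min) + 1
    out = np.zeros(n_bins)
    for (f0, e0), (_, e1) in zip(det, det[1:]):
        out[int(f0 // frames_per_min)] += math.hypot(e1.x - e0.x, e1.y - e0.y)
    return out / t.px_per_cm


def cumulative_relative_distance_error(a: Track, b: Track,
                                       mode: str = "per_minute") -> float:
    """Cumulative relative error of distance traveled, with b as reference.

    ``per_minute`` (default): sum over whole minutes m of |d_a(m) - d_b(m)|,
    divided by the reference total sum_m d_b(m).  ``cumulative``: relative
    error of the two cumulative totals.  Reports should state which mode was
    used.
    """
    if a.fps != b.fps:
        raise ValueError("tracks must share fps")
    da = per_minute_distances(a)
    db = per_minute_distances(b)
    n = max(len(da), len(db))
    da = np.pad(da, (0, n - len(da)))
    db = np.pad(db, (0, n - len(db)))
    ref = db.sum()
    if ref == 0:
        raise ValueError("reference track has zero total distance")
    if mode == "per_minute":
        return float(np.abs(da - db).sum() / ref)
    if mode == "cumulative":
        return float(abs(da.sum() - ref) / ref)
    raise ValueError(f"unknown mode {mode!r}")


def minor_axis_rsd(t: Track) -> float:
    """Relative standard deviation (population sd / mean) of the minor axis."""
    minors = np.array([e.minor for _, e in t.detected()], dtype=np.float64)
    if minors.size < 2:
        raise ValueError("need at least 2 detected frames")
    mean = minors.mean()
    if mean == 0:
        raise ValueError("minor-axis mean is zero")
    return float(minors.std(ddof=0) / mean)
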