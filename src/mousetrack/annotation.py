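"""Headless annotation engine: scribble-seeded watershed + ellipse fit.

The labeling workflow marks a few foreground points on the mouse and a few
background points elsewhere; marker-based watershed on the gradient
magnitude grows those seeds into a segmentation, an ellipse is fit to the
mask, and the user supplies only the coarse head direction (one of four
quadrants) — the exact angle comes from the fit.  Pure function of its
inputs: identical (frame, scribbles) give identical masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.segmentation import watershed

from .augmentation import TrainingSample
from .geometry import (
    NO_DETECTION,
    CardinalDirection,
    fit_ellipse_to_mask,
    largest_component,
    quadrant_of_angle,
    resolve_direction,
)

_FG, _BG = 2, 1


@dataclass
class Scribbles:
    """Foreground / background seed pixels, (row, col) each."""

    fg: List[Tuple[int, int]] = field(default_factory=list)
    bg: List[Tuple[int, int]] = field(default_factory=list)

    def validate(self, shape) -> None:
        if not self.fg:
            raise ValueError("no foreground seeds")
        if not self.bg:
            raise ValueError("no background seeds")
        for r, c in [*self.fg, *self.bg]:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"seed ({r}, {c}) out of bounds for {shape}")
        if set(map(tuple, self.fg)) & set(map(tuple, self.bg)):
            raise ValueError("a pixel cannot seed both classes")

    @classmethod
    def from_json(cls, text: str) -> "Scribbles":
        data = json.loads(text)
        return cls(fg=[tuple(p) for p in data["fg"]],
                   bg=[tuple(p) for p in data["bg"]])

    def to_json(self) -> str:
        return json.dumps({"fg": [list(p) for p in self.fg],
                           "bg": [list(p) for p in self.bg]})


def watershed_segment(frame: np.ndarray, s: Scribbles) -> np.ndarray:
    """Marker-based watershed on the gradient magnitude of the frame.

    The frame is median-denoised (3x3) before the Sobel gradient so that
    sensor noise does not create spurious basins.  Pixels flooded from
    foreground markers form the mask.
    """
    frame = np.asarray(frame)
    s.validate(frame.shape)
    smoothed = ndimage.median_filter(frame.astype(np.float64), size=3)
    gradient = sobel(smoothed)
    markers = np.zeros(frame.shape, dtype=np.int32)
    for r, c in s.bg:
        markers[r, c] = _BG
    for r, c in s.fg:
        markers[r, c] = _FG
    labels = watershed(gradient, markers)
    return (labels == _FG).astype(np.uint8)


def annotate(frame: np.ndarray, s: Scribbles, direction: CardinalDirection,
             sample_id: str = "") -> TrainingSample:
    """Full annotation of one frame: segment, fit, resolve direction."""
    mask = largest_component(watershed_segment(frame, s))
    und = fit_ellipse_to_mask(mask)
    if und is NO_DETECTION:
        raise ValueError("watershed produced an empty mask; add more "
                         "foreground seeds")
    ell = resolve_direction(und, direction)
    # the stored label follows the resolved angle: the user's choice is only
    # a +-90 deg hint and may sit across a quadrant boundary from the fit
    sample = TrainingSample(frame=np.asarray(frame, dtype=np.uint8),
                            mask=mask, ellipse=ell,
                            direction=quadrant_of_angle(ell.theta_deg),
                            sample_id=sample_id)
    sample.validate()
    return sample
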