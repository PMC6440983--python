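"""Label-consistent training-set augmentation.

Three families, mirroring how overhead arena footage can be perturbed without
changing its meaning:

* the 8 symmetries of the square (identity, three rotations, horizontal,
  vertical and the two diagonal mirrors) — an immediate 8x increase in
  effective training-set size, with ellipse and direction labels transported
  exactly;
* small random rigid transforms (rotation about the frame center plus
  translation, uniform) applied identically to frame, mask and labels;
* photometric perturbations (per-pixel noise, additive brightness,
  multiplicative contrast about mid-gray, all normal) which leave labels
  untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .geometry import CardinalDirection, EllipseFit, quadrant_of_angle


@dataclass
class TrainingSample:
    """One annotated frame: image, mask, directed ellipse, quadrant label."""

    frame: np.ndarray     # 2-D uint8 grayscale
    mask: np.ndarray      # 2-D {0,1}, same shape
    ellipse: EllipseFit
    direction: CardinalDirection
    sample_id: str = ""

    def validate(self) -> None:
        if self.frame.shape != self.mask.shape:
            raise ValueError("frame/mask shape mismatch")
        if not np.isin(np.unique(self.mask), [0, 1]).all():
            raise ValueError("mask must be binary")
        if quadrant_of_angle(self.ellipse.theta_deg) != self.direction:
            raise ValueError("direction label inconsistent with ellipse angle")


@dataclass
class AugmentationConfig:
    """Ranges for the random augmentations.

    Rotation/translation are uniform on +-range; noise, brightness and
    contrast are normal.  Defaults are mild: the goal is invariance to
    jitter in camera mounting and illumination, not new poses.
    """

    rotation_range_deg: float = 10.0
    translation_range_px: float = 20.0
    noise_sd: float = 3.0
    brightness_sd: float = 10.0
    contrast_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range_deg", "translation_range_px",
                     "noise_sd", "brightness_sd", "contrast_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# The 8-element symmetry group of the square (dihedral D4).
# Each element is (k, flip): flip columns first (if flip), then rotate the
# array 90 deg counterclockwise (as displayed) k times.

D4_ELEMENTS = [(k, f) for f in (False, True) for k in range(4)]


def _d4_array(arr: np.ndarray, k: int, flip: bool) -> np.ndarray:
    if flip:
        arr = np.fliplr(arr)
    return np.rot90(arr, k)


def _d4_point(x: float, y: float, n: int, k: int, flip: bool):
    # array coords: x = col, y = row; square side n
    if flip:
        x = (n - 1) - x
    for _ in range(k % 4):
        # np.rot90 maps pixel (r, c) -> (n-1-c, r): (x, y) -> (y, n-1-x)
        x, y = y, (n - 1) - x
    return x, y


def _d4_angle(theta: float, k: int, flip: bool) -> float:
    if flip:
        theta = 180.0 - theta
    return (theta + 90.0 * (k % 4)) % 360.0


def apply_symmetry(s: TrainingSample, k: int, flip: bool) -> TrainingSample:
    """Apply one square symmetry to a sample, transporting all labels."""
    n_rows, n_cols = s.frame.shape
    if n_rows != n_cols:
        raise ValueError("square frame required: diagonal reflections are "
                         "undefined for non-square frames")
    x, y = _d4_point(s.ellipse.x, s.ellipse.y, n_rows, k, flip)
    theta = _d4_angle(s.ellipse.theta_deg, k, flip)
    ell = EllipseFit.from_angle(x, y, s.ellipse.major, s.ellipse.minor, theta)
    return TrainingSample(
        frame=np.ascontiguousarray(_d4_array(s.frame, k, flip)),
        mask=np.ascontiguousarray(_d4_array(s.mask, k, flip)),
        ellipse=ell,
        direction=quadrant_of_angle(theta),
        sample_id=s.sample_id,
    )


def reflect_all(s: TrainingSample):
    """The orbit of a sample under the 8 symmetries of the square."""
    return [apply_symmetry(s, k, f) for (k, f) in D4_ELEMENTS]


def random_symmetry(s: TrainingSample, rng: np.random.Generator) -> TrainingSample:
    k, f = D4_ELEMENTS[rng.integers(len(D4_ELEMENTS))]
    return apply_symmetry(s, k, f)


# ---------------------------------------------------------------------------
# Rigid transforms


def rigid_transform(s: TrainingSample, angle_deg: float, tx: float, ty: float
                    ) -> TrainingSample:
    """Rotate about the frame center (display-CCW) then translate.

    ``tx`` moves the content rightward (columns), ``ty`` downward (rows).
    Frame is warped bilinearly with border replication; the mask with
    nearest-neighbor to stay binary.  The ellipse center is mapped by the
    same transform and theta incremented by the rotation.
    """
    h, w = s.frame.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a = math.radians(angle_deg)
    ca, sa = math.cos(a), math.sin(a)
    # inverse map, (row, col) order, for ndimage.affine_transform
    matrix = np.array([[ca, sa], [-sa, ca]])
    offset = np.array([
        cy - ca * (cy + ty) - sa * (cx + tx),
        cx + sa * (cy + ty) - ca * (cx + tx),
    ])
    frame = ndimage.affine_transform(s.frame.astype(np.float32), matrix,
                                     offset=offset, order=1, mode="nearest")
    mask = ndimage.affine_transform(s.mask.astype(np.uint8), matrix,
                                    offset=offset, order=0, mode="nearest")
    # forward map of the center: display-CCW rotation in array coords
    dx, dy = s.ellipse.x - cx, s.ellipse.y - cy
    x = ca * dx + sa * dy + cx + tx
    y = -sa * dx + ca * dy + cy + ty
    theta = (s.ellipse.theta_deg + angle_deg) % 360.0
    ell = EllipseFit.from_angle(x, y, s.ellipse.major, s.ellipse.minor, theta)
    return TrainingSample(
        frame=np.clip(np.rint(frame), 0, 255).astype(np.uint8),
        mask=mask.astype(np.uint8),
        ellipse=ell,
        direction=quadrant_of_angle(theta),
        sample_id=s.sample_id,
    )


def random_rigid(s: TrainingSample, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> TrainingSample:
    if cfg.rotation_range_deg == 0 and cfg.translation_range_px == 0:
        return replace(s, frame=s.frame.copy(), mask=s.mask.copy())
    angle = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg)
    tx = rng.uniform(-cfg.translation_range_px, cfg.translation_range_px)
    ty = rng.uniform(-cfg.translation_range_px, cfg.translation_range_px)
    return rigid_transform(s, angle, tx, ty)


# ---------------------------------------------------------------------------
# Photometric perturbations


def random_photometric(frame: np.ndarray, cfg: AugmentationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Contrast (about mid-gray 128), brightness and per-pixel noise.

    frame' = clip(contrast * (frame - 128) + 128 + brightness + noise, 0, 255)
    with contrast ~ N(1, contrast_sd), brightness ~ N(0, brightness_sd),
    noise ~ N(0, noise_sd) per pixel.  Labels are untouched by construction.
    """
    f = frame.astype(np.float64)
    contrast = rng.normal(1.0, cfg.contrast_sd) if cfg.contrast_sd > 0 else 1.0
    brightness = rng.normal(0.0, cfg.brightness_sd) if cfg.brightness_sd > 0 else 0.0
    out = contrast * (f - 128.0) + 128.0 + brightness
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, size=f.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_sample(s: TrainingSample, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> TrainingSample:
    """One full random draw: symmetry, rigid transform, photometric."""
    out = random_symmetry(s, rng)
    out = random_rigid(out, cfg, rng)
    out.frame = random_photometric(out.frame, cfg, rng)
    return out
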