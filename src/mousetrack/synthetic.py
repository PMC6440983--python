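"""Synthetic top-down arena renderer with exact ground truth.

Emulates the visual regimes an overhead open-field camera produces — a dark
or low-contrast mouse blob on bedding-textured, gradient-lit or glare-banded
backgrounds, with optional tail, cast shadow and movable sphere distractors —
so every other module can be trained and tested without real videos.  Each
rendered frame comes with its exact segmentation mask and ellipse: the mask
is the rasterized body ellipse itself, the tail is drawn in the image but
excluded from the mask (matching the annotation convention that tails are
removed for a better ellipse fit).

Named presets (black, gray, albino, piebald, 24h, komp2) differ only in
their :class:`SceneConfig` and mirror the axis of difficulty of real
arenas: albino = low contrast, piebald = two-tone body, 24h = bedding plus
lighting drift, komp2 = reflective glare bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .augmentation import TrainingSample
from .geometry import EllipseFit, quadrant_of_angle, rasterize_ellipse
from .metrics import Track


@dataclass
class SceneConfig:
    """Everything that determines how a frame looks (not where the mouse is)."""

    frame_size: int = 480
    background: str = "flat"          # flat | gradient | bedding | glare
    bg_level: float = 200.0
    mouse_level: float = 40.0
    piebald: bool = False             # two-tone body patches
    piebald_level: float = 220.0
    tail: bool = True
    tail_length_frac: float = 0.9     # of the major axis
    tail_width_px: float = 2.0
    tail_in_mask: bool = False        # robustness-test toggle
    shadow: bool = False
    shadow_offset_px: Tuple[float, float] = (5.0, 5.0)   # (dx cols, dy rows)
    shadow_darkness: float = 30.0
    n_spheres: int = 0
    sphere_radius_range: Tuple[float, float] = (8.0, 20.0)
    sphere_level: float = 120.0
    lighting_drift: float = 0.0       # additive amplitude over a video
    noise_sd: float = 2.0
    mouse_major_frac: Tuple[float, float] = (0.10, 0.16)  # of frame size
    mouse_aspect_range: Tuple[float, float] = (0.30, 0.50)
    mouse_min_minor_px: float = 8.0   # resolution floor of the moment fit

    def __post_init__(self):
        for lv in (self.bg_level, self.mouse_level, self.piebald_level,
                   self.sphere_level):
            if not 0 <= lv <= 255:
                raise ValueError("gray levels must be in [0, 255]")
        if self.background not in ("flat", "gradient", "bedding", "glare"):
            raise ValueError(f"unknown background {self.background!r}")


PRESETS = {
    "black":   dict(bg_level=200, mouse_level=40),
    "gray":    dict(bg_level=200, mouse_level=145),
    "albino":  dict(bg_level=200, mouse_level=185),
    "piebald": dict(bg_level=200, mouse_level=40, piebald=True),
    "24h":     dict(background="bedding", bg_level=170, mouse_level=40,
                    lighting_drift=20.0),
    "komp2":   dict(background="glare", bg_level=120, mouse_level=40,
                    shadow=True, noise_sd=3.0),
}


def preset(name: str, frame_size: int = 480, **overrides) -> SceneConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SceneConfig(frame_size=frame_size, **kw)


@dataclass
class WalkConfig:
    """Correlated random walk for ground-truth trajectory generation."""

    step_mean_px: float = 2.0
    step_sd_px: float = 0.5
    turn_sd_deg: float = 15.0
    frames: int = 240
    seed: int = 0

    def __post_init__(self):
        if self.frames <= 0:
            raise ValueError("frames must be positive")
        if self.step_mean_px < 0 or self.step_sd_px < 0:
            raise ValueError("steps must be >= 0")


# ---------------------------------------------------------------------------
# Pose sampling


def sample_pose(scene: SceneConfig, rng: np.random.Generator) -> EllipseFit:
    """Uniformly sample a valid mouse pose (fully inside the frame).

    At small frame sizes the frame-relative size ranges are scaled up so
    the minor axis never falls below ``mouse_min_minor_px``: below that the
    rasterized silhouette is too coarse for any moment fit to resolve, and
    the ground-truth label itself would be meaningless.
    """
    s = scene.frame_size
    major = rng.uniform(*scene.mouse_major_frac) * s
    minor = major * rng.uniform(*scene.mouse_aspect_range)
    if minor < scene.mouse_min_minor_px:
        scale = scene.mouse_min_minor_px / minor
        major, minor = major * scale, minor * scale
    margin = major / 2.0 + 1.0
    x = rng.uniform(margin, s - 1 - margin)
    y = rng.uniform(margin, s - 1 - margin)
    theta = rng.uniform(0.0, 360.0)
    return EllipseFit.from_angle(x, y, major, minor, theta)


# ---------------------------------------------------------------------------
# Rendering


def _background(scene: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    s = scene.frame_size
    if scene.background == "flat":
        return np.full((s, s), scene.bg_level, dtype=np.float64)
    if scene.background == "gradient":
        rr, cc = np.mgrid[0:s, 0:s]
        r = np.hypot(rr - s / 2, cc - s / 2) / (s / 2)
        return scene.bg_level - 30.0 * r
    if scene.background == "bedding":
        tex = rng.normal(0.0, 1.0, size=(s, s))
        tex = ndimage.gaussian_filter(tex, sigma=max(s / 96.0, 1.0))
        tex = tex / (np.abs(tex).max() + 1e-9)
        return scene.bg_level + 25.0 * tex
    # glare: bright vertical bands, as from overhead LEDs on acrylic
    cc = np.arange(s, dtype=np.float64)
    bands = np.zeros(s)
    for center_frac, width_frac, amp in ((0.25, 0.06, 70.0), (0.70, 0.10, 90.0)):
        bands += amp * np.exp(-0.5 * ((cc - center_frac * s) / (width_frac * s)) ** 2)
    return np.full((s, s), scene.bg_level, dtype=np.float64) + bands[None, :]


def _tail_pixels(e: EllipseFit, scene: SceneConfig, shape) -> np.ndarray:
    """Mask of tail pixels: a stripe extending from the rump outward."""
    t = math.radians(e.theta_deg)
    # rump = back end of the major axis (display space; rows grow downward)
    rx = e.x - (e.major / 2.0) * math.cos(t)
    ry = e.y + (e.major / 2.0) * math.sin(t)
    length = scene.tail_length_frac * e.major
    ex = rx - length * math.cos(t)
    ey = ry + length * math.sin(t)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    # distance from pixel centers to the segment (rx,ry)-(ex,ey)
    vx, vy = ex - rx, ey - ry
    denom = vx * vx + vy * vy
    if denom == 0:
        return np.zeros(shape, dtype=bool)
    u = np.clip(((cc - rx) * vx + (rr - ry) * vy) / denom, 0.0, 1.0)
    d = np.hypot(cc - (rx + u * vx), rr - (ry + u * vy))
    return d <= scene.tail_width_px / 2.0


def _sphere(frame: np.ndarray, cx: float, cy: float, radius: float,
            level: float) -> None:
    s = frame.shape[0]
    rr, cc = np.mgrid[0:s, 0:s]
    d = np.hypot(rr - cy, cc - cx)
    inside = d <= radius
    shade = level + 60.0 * np.clip(1.0 - (d / radius) ** 2, 0.0, 1.0)
    frame[inside] = shade[inside]


def _place_spheres(scene: SceneConfig, mouse_mask: np.ndarray,
                   rng: np.random.Generator) -> List[Tuple[float, float, float]]:
    s = scene.frame_size
    placed = []
    for _ in range(scene.n_spheres):
        radius = rng.uniform(*scene.sphere_radius_range)
        for _attempt in range(100):
            cx = rng.uniform(radius + 1, s - 2 - radius)
            cy = rng.uniform(radius + 1, s - 2 - radius)
            if _sphere_clear((cx, cy, radius), mouse_mask, placed):
                placed.append((cx, cy, radius))
                break
        else:
            raise RuntimeError("could not place sphere without overlap")
    return placed


def _sphere_clear(sph, mouse_mask, others) -> bool:
    cx, cy, r = sph
    rr, cc = np.nonzero(mouse_mask)
    if rr.size and np.min(np.hypot(rr - cy, cc - cx)) <= r + 2:
        return False
    return all(math.hypot(cx - ox, cy - oy) > r + orad + 2
               for ox, oy, orad in others)


def render_frame(ellipse: EllipseFit, scene: SceneConfig,
                 rng: np.random.Generator, frame_index: int = 0,
                 spheres: Optional[List[Tuple[float, float, float]]] = None):
    """Render one frame; returns ``(frame uint8, mask uint8, ellipse)``.

    The mask is exactly the rasterized body ellipse (tail excluded unless
    ``tail_in_mask``); labels are independent of contrast, lighting and
    noise by construction.
    """
    s = scene.frame_size
    half = ellipse.major / 2.0
    if not (half <= ellipse.x <= s - 1 - half and half <= ellipse.y <= s - 1 - half):
        raise ValueError("ellipse not fully inside the frame")
    frame = _background(scene, rng)
    body = rasterize_ellipse(ellipse, (s, s)).astype(bool)

    if scene.shadow:
        sh = EllipseFit(ellipse.x + scene.shadow_offset_px[0],
                        ellipse.y + scene.shadow_offset_px[1],
                        ellipse.major, ellipse.minor,
                        ellipse.sin_theta, ellipse.cos_theta)
        shadow_px = rasterize_ellipse(sh, (s, s)).astype(bool) & ~body
        frame[shadow_px] -= scene.shadow_darkness

    if spheres is None:
        spheres = _place_spheres(scene, body, rng)
    for cx, cy, radius in spheres:
        _sphere(frame, cx, cy, radius, scene.sphere_level)

    tail_px = np.zeros((s, s), dtype=bool)
    if scene.tail:
        tail_px = _tail_pixels(ellipse, scene, (s, s)) & ~body
        frame[tail_px] = scene.mouse_level

    frame[body] = scene.mouse_level
    if scene.piebald:
        # patch of light fur on the rear half of the body
        t = math.radians(ellipse.theta_deg)
        rr, cc = np.nonzero(body)
        u = (cc - ellipse.x) * math.cos(t) - (rr - ellipse.y) * math.sin(t)
        patch = u < -0.15 * ellipse.major / 2.0
        frame[rr[patch], cc[patch]] = scene.piebald_level

    if scene.lighting_drift:
        frame += scene.lighting_drift * math.sin(2.0 * math.pi * frame_index / 300.0)
    if scene.noise_sd > 0:
        frame += rng.normal(0.0, scene.noise_sd, size=frame.shape)

    mask = (body | tail_px) if scene.tail_in_mask else body
    return (np.clip(np.rint(frame), 0, 255).astype(np.uint8),
            mask.astype(np.uint8), ellipse)


# ---------------------------------------------------------------------------
# Dataset and video generation


def generate_dataset(n: int, scene: SceneConfig, seed: int = 0,
                     id_prefix: str = "syn",
                     out_dir: Optional[str] = None) -> List[TrainingSample]:
    """n training samples with poses sampled uniformly over valid positions.

    With ``out_dir`` the samples are also written to the standard dataset
    store (PNG frames + PNG masks + labels CSV).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        pose = sample_pose(scene, rng)
        frame, mask, ell = render_frame(pose, scene, rng)
        samples.append(TrainingSample(
            frame=frame, mask=mask, ellipse=ell,
            direction=quadrant_of_angle(ell.theta_deg),
            sample_id=f"{id_prefix}{i:05d}"))
    if out_dir is not None:
        from .datasets import save_dataset
        save_dataset(samples, out_dir)
    return samples


def generate_video(walk: WalkConfig, scene: SceneConfig, fps: float = 30.0,
                   px_per_cm: float = 8.0):
    """Correlated random walk rendered frame by frame.

    Returns ``(frames, truth_track, masks)``.  Headings reflect off the
    walls *before* the move, so every displacement has exactly the drawn
    step length and total distance has a closed form when step_sd is 0.
    Sphere distractors are nudged away whenever the walking mouse would
    touch them (they are movable objects), so they never overlap the mask.
    """
    rng = np.random.default_rng(walk.seed)
    s = scene.frame_size
    pose = sample_pose(scene, rng)
    major, minor = pose.major, pose.minor
    margin = major / 2.0 + 1.0
    x, y, heading = pose.x, pose.y, pose.theta_deg

    body0 = rasterize_ellipse(pose, (s, s))
    spheres = _place_spheres(scene, body0, rng)

    frames, masks = [], []
    track = Track(fps=fps, px_per_cm=px_per_cm)
    for i in range(walk.frames):
        ell = EllipseFit.from_angle(x, y, major, minor, heading)
        body = rasterize_ellipse(ell, (s, s))
        spheres = [_nudge_sphere(sp, body, ell, s) for sp in spheres]
        frame, mask, _ = render_frame(ell, scene, rng, frame_index=i,
                                      spheres=spheres)
        frames.append(frame)
        masks.append(mask)
        track.append(i, ell)
        # advance
        heading = (heading + rng.normal(0.0, walk.turn_sd_deg)) % 360.0
        step = max(rng.normal(walk.step_mean_px, walk.step_sd_px), 0.0) \
            if walk.step_sd_px > 0 else walk.step_mean_px
        for _ in range(4):  # at most two wall reflections are ever needed
            t = math.radians(heading)
            nx = x + step * math.cos(t)
            ny = y - step * math.sin(t)  # display space: heading up = -rows
            if nx < margin or nx > s - 1 - margin:
                heading = (180.0 - heading) % 360.0
                continue
            if ny < margin or ny > s - 1 - margin:
                heading = (-heading) % 360.0
                continue
            x, y = nx, ny
            break
    return frames, track, masks


def _nudge_sphere(sph, body_mask, ell: EllipseFit, frame_size: int):
    cx, cy, r = sph
    rr, cc = np.nonzero(body_mask)
    if rr.size == 0:
        return sph
    d = np.hypot(rr - cy, cc - cx)
    gap = d.min() - r
    if gap > 2:
        return sph
    # push directly away from the mouse center
    vx, vy = cx - ell.x, cy - ell.y
    norm = math.hypot(vx, vy) or 1.0
    shift = (2 - gap) + 1.0
    ncx = float(np.clip(cx + shift * vx / norm, r + 1, frame_size - 2 - r))
    ncy = float(np.clip(cy + shift * vy / norm, r + 1, frame_size - 2 - r))
    if not _sphere_clear((ncx, ncy, r), body_mask, []):
        # clipped at a wall: slide along the wall instead
        ncx = float(np.clip(cx - shift * vy / norm, r + 1, frame_size - 2 - r))
        ncy = float(np.clip(cy + shift * vx / norm, r + 1, frame_size - 2 - r))
    return (ncx, ncy, r)
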