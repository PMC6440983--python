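"""Video -> per-frame ellipse track.

Per-frame inference is independent (no temporal smoothing or identity
logic): each frame is center-cropped or padded to the model's input size,
pushed through the family-appropriate decoder, and the resulting fit mapped
back to original-frame coordinates.  Tracks are written as plain CSV with
one row per frame; NoDetection rows keep the frame index with empty numeric
fields.

Video input is a directory of PNG frames (the renderer's native output) or
any container imageio can decode; acquisition defaults are 30 fps and a
zoom of 8 px/cm.
"""

from __future__ import annotations

import csv
import os
import warnings
from typing import Iterable, Optional

import imageio.v3 as iio
import numpy as np

from .geometry import NO_DETECTION, EllipseFit, quadrant_of_angle
from .metrics import Track, minor_axis_rsd, total_distance
from .networks import decode_binned, decode_regression, segmentation_to_ellipse

TRACK_HEADER = ["frame", "x", "y", "major", "minor", "theta_deg",
                "sin_theta", "cos_theta", "direction", "detected"]


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3].mean(axis=-1)
    return frame.astype(np.uint8)


def _crop_or_pad(frame: np.ndarray, size: int):
    """Center-crop/pad to size x size; returns (frame, (row0, col0)) where
    (row0, col0) is the offset of the crop window in the original frame
    (negative when padding was added)."""
    h, w = frame.shape
    r0 = (h - size) // 2
    c0 = (w - size) // 2
    out = np.zeros((size, size), dtype=frame.dtype)
    src_r = slice(max(r0, 0), max(r0, 0) + min(h, size))
    src_c = slice(max(c0, 0), max(c0, 0) + min(w, size))
    dst_r = slice(max(-r0, 0), max(-r0, 0) + min(h, size))
    dst_c = slice(max(-c0, 0), max(-c0, 0) + min(w, size))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out, (r0, c0)


def infer_frame(frame: np.ndarray, model):
    """One frame -> EllipseFit (or NO_DETECTION), in original coordinates."""
    frame = _to_grayscale(frame)
    size = model.input_size
    if frame.shape != (size, size):
        frame, (r0, c0) = _crop_or_pad(frame, size)
    else:
        r0 = c0 = 0
    x = (frame.astype(np.float32) / 255.0)[None, None]
    if model.family == "segmentation":
        ml, dl = model.forward(x)
        fit = segmentation_to_ellipse(ml[0], dl[0])
    elif model.family == "binned":
        scores = model.forward(x)
        vals = decode_binned({k: v[0] for k, v in scores.items()}, model.heads)
        # the default binned configuration tracks center location only;
        # missing parameters are reported as zero axes / zero heading
        fit = EllipseFit.from_angle(vals.get("x", 0.0), vals.get("y", 0.0),
                                    vals.get("major", 0.0),
                                    vals.get("minor", 0.0),
                                    vals.get("theta", 0.0))
    else:
        fit = decode_regression(model.forward(x)[0])
    if fit is NO_DETECTION:
        return NO_DETECTION
    if isinstance(fit, EllipseFit):
        if (r0, c0) != (0, 0):
            fit = EllipseFit(fit.x + c0, fit.y + r0, fit.major, fit.minor,
                             fit.sin_theta, fit.cos_theta)
        return fit
    # directionless regression output: report with heading 0 and a warning
    warnings.warn("direction unavailable for frame; reporting heading 0")
    return EllipseFit.from_angle(fit.x + c0, fit.y + r0, fit.major,
                                 fit.minor, fit.theta_deg)


def iter_video_frames(source) -> Iterable[np.ndarray]:
    """Yield grayscale frames from a PNG directory or a video container."""
    if isinstance(source, (list, tuple)):
        for f in source:
            yield _to_grayscale(f)
        return
    if os.path.isdir(source):
        names = sorted(n for n in os.listdir(source)
                       if n.lower().endswith(".png"))
        if not names:
            raise ValueError(f"no PNG frames found in {source}")
        for n in names:
            yield _to_grayscale(iio.imread(os.path.join(source, n)))
        return
    try:
        for frame in iio.imiter(source):
            yield _to_grayscale(frame)
    except Exception as exc:  # pragma: no cover - depends on codecs present
        raise RuntimeError(
            f"cannot decode {source!r}: no codec/plugin available "
            f"({exc}); supply a directory of PNG frames instead") from exc


def track_video(source, model, fps: float = 30.0, px_per_cm: float = 8.0,
                out_csv: Optional[str] = None):
    """Track every frame of a video; returns (Track, summary dict)."""
    track = Track(fps=fps, px_per_cm=px_per_cm)
    for i, frame in enumerate(iter_video_frames(source)):
        track.append(i, infer_frame(frame, model))
    if track.n_frames == 0:
        raise ValueError("video contained no frames")
    summary = {
        "n_frames": track.n_frames,
        "detection_rate": track.detection_rate,
        "total_distance_cm": total_distance(track) if track.detected() else 0.0,
    }
    if len(track.detected()) >= 2:
        try:
            summary["minor_axis_rsd"] = minor_axis_rsd(track)
        except ValueError:
            summary["minor_axis_rsd"] = float("nan")
    if out_csv:
        write_track(track, out_csv)
    return track, summary


# ---------------------------------------------------------------------------
# Track CSV I/O


def write_track(track: Track, path: str) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(TRACK_HEADER)
        for frame, fit in track.records:
            if fit is NO_DETECTION or fit is None:
                w.writerow([frame, "", "", "", "", "", "", "", "", 0])
            else:
                w.writerow([frame,
                            f"{fit.x:.6f}", f"{fit.y:.6f}",
                            f"{fit.major:.6f}", f"{fit.minor:.6f}",
                            f"{fit.theta_deg:.6f}",
                            f"{fit.sin_theta:.9f}", f"{fit.cos_theta:.9f}",
                            quadrant_of_angle(fit.theta_deg).name.lower(), 1])


def read_track(path: str, fps: float = 30.0, px_per_cm: float = 8.0) -> Track:
    track = Track(fps=fps, px_per_cm=px_per_cm)
    with open(path, newline="") as f:
        reader = csv.reader(f)
        header = next(reader, None)
        if header != TRACK_HEADER:
            raise ValueError(f"line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(TRACK_HEADER):
                raise ValueError(f"line {lineno}: expected "
                                 f"{len(TRACK_HEADER)} fields, got {len(row)}")
            try:
                frame = int(row[0])
                detected = int(row[9])
                if detected:
                    fit = EllipseFit(float(row[1]), float(row[2]),
                                     float(row[3]), float(row[4]),
                                     float(row[6]), float(row[7]))
                else:
                    fit = NO_DETECTION
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            track.append(frame, fit)
    return track
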