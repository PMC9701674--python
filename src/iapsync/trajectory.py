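"""Fingertip trajectory extraction from gesture videos and kinematics.

Participants wear a red cap on the left and a blue cap on the right index
finger; a 30 fps camera records the gestures. Per frame, the RGB image is
median-filtered, thresholded per channel for the requested cap color, and
the largest connected component of the resulting mask is shrunk to a point
(its centroid). The per-frame points form a 2-D trajectory that is
Gaussian-kernel smoothed and segmented into movements (runs of
frame-to-frame speed at or above a rest threshold, extended outward to the
enclosing local speed minima so the slow tails of a reach are kept).

Each movement segment aggregates into:

* amplitude — start-to-end displacement in mm (path length is exposed as an
  auxiliary output);
* mean velocity — path length / duration in mm/ms, duration from the frame
  count at the video frame rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, median_filter
from skimage.measure import label as sk_label, regionprops


@dataclass(frozen=True)
class ColorThresholds:
    """Per-channel intensity thresholds isolating one cap color: the target
    channel must be at least ``target_min``; the other two at most
    ``other_max``."""
    target_min: int = 120
    other_max: int = 90


@dataclass(frozen=True)
class TrajectoryConfig:
    red: ColorThresholds = field(default_factory=ColorThresholds)
    blue: ColorThresholds = field(default_factory=ColorThresholds)
    median_size: int = 3
    min_area_px: int = 10
    image_roi: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1)
    smoothing_bandwidth_frames: float = 1.0
    rest_speed_threshold_px: float = 2.0
    min_move_frames: int = 3
    fps: int = 30


_CHANNEL = {"red": 0, "blue": 2}


def segment_fingertip(frame: np.ndarray, color: str,
                      config: TrajectoryConfig | None = None,
                      _prefiltered: bool = False):
    """Centroid (x, y) of the cap blob in one RGB frame, or None if absent.

    Median-filter denoise, per-channel threshold conjunction, largest
    connected component, shrink-to-point via centroid. Components below
    ``min_area_px`` count as absent.
    """
    config = config or TrajectoryConfig()
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected an RGB frame of shape (H, W, 3)")
    thr = {"red": config.red, "blue": config.blue}[color]
    tgt = _CHANNEL[color]
    x0 = y0 = 0
    if config.image_roi is not None:
        x0, y0, x1, y1 = config.image_roi
        frame = frame[y0:y1, x0:x1]
    img = np.asarray(frame, dtype=np.uint8)
    if config.median_size > 1 and not _prefiltered:
        img = median_filter(img, size=(config.median_size, config.median_size, 1))
    mask = img[:, :, tgt] >= thr.target_min
    for ch in range(3):
        if ch != tgt:
            mask &= img[:, :, ch] <= thr.other_max
    if not mask.any():
        return None
    lab = sk_label(mask)
    props = regionprops(lab)
    best = max(props, key=lambda p: p.area)
    if best.area < config.min_area_px:
        return None
    cy, cx = best.centroid
    return float(cx + x0), float(cy + y0)


def extract_trajectory(frames: np.ndarray, color: str,
                       config: TrajectoryConfig | None = None) -> pd.DataFrame:
    """Per-frame fingertip points; gaps are kept as not-present rows.

    Returns columns ``frame, time_ms, x, y, present``.
    """
    config = config or TrajectoryConfig()
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    frames = np.asarray(frames)
    cfg = config
    x_off = y_off = 0
    prefiltered = False
    if frames.ndim == 4:
        if config.image_roi is not None:
            x0, y0, x1, y1 = config.image_roi
            frames = frames[:, y0:y1, x0:x1]
            x_off, y_off = x0, y0
            cfg = dataclasses.replace(config, image_roi=None)
        if cfg.median_size > 1:
            # denoise the whole clip in one call; cheaper than per-frame
            m = cfg.median_size
            frames = median_filter(frames, size=(1, m, m, 1))
            prefiltered = True
    rows = []
    for i, frame in enumerate(frames):
        c = segment_fingertip(frame, color, cfg, _prefiltered=prefiltered)
        present = c is not None
        x, y = (c[0] + x_off, c[1] + y_off) if present else (np.nan, np.nan)
        rows.append((i, i * 1000.0 / cfg.fps, x, y, present))
    df = pd.DataFrame(rows, columns=["frame", "time_ms", "x", "y", "present"])
    if not df["present"].any():
        raise ValueError("fingertip absent in every frame")
    return df


def _interp_gaps(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    f = series["frame"].to_numpy(dtype=float)
    pres = series["present"].to_numpy(dtype=bool)
    x = np.interp(f, f[pres], series["x"].to_numpy(dtype=float)[pres])
    y = np.interp(f, f[pres], series["y"].to_numpy(dtype=float)[pres])
    return x, y


def smooth_and_segment(series: pd.DataFrame,
                       config: TrajectoryConfig | None = None) -> list[pd.DataFrame]:
    """Smooth the trajectory and cut it into movement segments.

    Gaussian smoothing of x(t), y(t) with ``smoothing_bandwidth_frames``
    (0 leaves the series untouched); gaps are linearly interpolated before
    smoothing. Movements are maximal runs of frame-to-frame speed at or
    above ``rest_speed_threshold_px`` lasting at least ``min_move_frames``,
    each extended outward to the local speed minima bracketing it.
    Returns one DataFrame (frame, x, y, speed) per segment.
    """
    config = config or TrajectoryConfig()
    if int(series["present"].sum()) < config.min_move_frames:
        raise ValueError("not enough present points to segment")
    x, y = _interp_gaps(series)
    bw = config.smoothing_bandwidth_frames
    if bw > 0:
        x = gaussian_filter1d(x, bw, mode="nearest")
        y = gaussian_filter1d(y, bw, mode="nearest")
    speed = np.hypot(np.diff(x, prepend=x[0]), np.diff(y, prepend=y[0]))
    moving = speed >= config.rest_speed_threshold_px
    segments = []
    n = len(speed)
    for a, b in _runs(moving):
        if b - a < config.min_move_frames:
            continue
        # movement edges extend down the flanks of the speed run, stopping
        # where speed falls to a floor relative to the run's peak, so the
        # slow tails of a reach are kept without swallowing genuine rest
        floor = 0.014 * float(np.max(speed[a:b]))
        while a > 1 and speed[a - 1] > floor:
            a -= 1
        while b < n and speed[b] > floor:
            b += 1
        seg = pd.DataFrame({"frame": series["frame"].to_numpy()[a - 1:b],
                            "x": x[a - 1:b], "y": y[a - 1:b],
                            "speed": speed[a - 1:b]})
        segments.append(seg.reset_index(drop=True))
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


@dataclass(frozen=True)
class GestureKinematics:
    onset_frame: int
    offset_frame: int
    amplitude_mm: float
    mean_velocity_mm_ms: float
    path_length_mm: float
    duration_ms: float


def kinematics(segment: pd.DataFrame, px_per_mm: float,
               fps: int = 30) -> GestureKinematics:
    """Aggregate one movement segment into amplitude and mean velocity.

    Amplitude is the start-to-end displacement; mean velocity is path length
    over duration, both scaled by ``px_per_mm``.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    xy = segment[["x", "y"]].to_numpy(dtype=float)
    amp_px = float(np.linalg.norm(xy[-1] - xy[0]))
    path_px = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
    frames = segment["frame"].to_numpy()
    duration_ms = (frames[-1] - frames[0]) * 1000.0 / fps
    if duration_ms <= 0:
        raise ValueError("segment must span at least one frame interval")
    return GestureKinematics(
        onset_frame=int(frames[0]), offset_frame=int(frames[-1]),
        amplitude_mm=amp_px / px_per_mm,
        mean_velocity_mm_ms=(path_px / px_per_mm) / duration_ms,
        path_length_mm=path_px / px_per_mm, duration_ms=duration_ms)


def analyze_video(frames: np.ndarray, color: str, px_per_mm: float,
                  config: TrajectoryConfig | None = None) -> list[GestureKinematics]:
    """Full per-video pipeline: extract, smooth, segment, aggregate."""
    config = config or TrajectoryConfig()
    series = extract_trajectory(frames, color, config)
    segs = smooth_and_segment(series, config)
    return [kinematics(s, px_per_mm, config.fps) for s in segs]
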