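"""Gaze event parsing: velocity-threshold saccade detection, blinks, RoI labels.

Raw input is a 1000 Hz stream of screen-pixel gaze positions with a pupil
validity flag. The parser converts positions to degrees of visual angle,
estimates angular velocity with a five-point central difference followed by
a short boxcar smoother, and segments the stream into saccades (velocity at
or above a 30 deg/s threshold, with a minimum-duration gate), blinks
(contiguous invalid samples, with edge padding that absorbs blink-adjacent
velocity artifacts) and fixations (everything else). Events tile the trial.

Coordinates: origin at the top-left screen corner, x rightwards, y downwards,
0-based pixels. Gaze may lie outside the monitor (the partner's face sits
above the screen's top edge), so negative pixel coordinates are legal.
All event intervals are half-open ``[onset, offset)`` in integer ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, uniform_filter1d

GAZE_COLUMNS = ["time_ms", "x_px", "y_px", "valid"]

ROI_LABELS = ("social", "left_stim", "right_stim", "random")


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor geometry used to convert pixels to degrees of visual angle.

    Defaults describe a 24-inch 16:10 panel (1920 x 1200 px, 518.4 x 324 mm
    active area) viewed from 940 mm.
    """

    width_px: int = 1920
    height_px: int = 1200
    width_mm: float = 518.4
    height_mm: float = 324.0
    distance_mm: float = 940.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return self.width_mm / self.width_px, self.height_mm / self.height_px

    @property
    def center_px(self) -> tuple[float, float]:
        return self.width_px / 2.0, self.height_px / 2.0


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Convert screen-pixel coordinates to degrees of visual angle.

    Angles are measured from the screen center, per axis, as
    ``atan2(physical offset, viewing distance)``. Odd in its argument:
    a point mirrored through the center maps to the negated angle.
    """
    mmx, mmy = geometry.mm_per_px
    cx, cy = geometry.center_px
    dx_mm = (np.asarray(x_px, dtype=float) - cx) * mmx
    dy_mm = (np.asarray(y_px, dtype=float) - cy) * mmy
    deg_x = np.degrees(np.arctan2(dx_mm, geometry.distance_mm))
    deg_y = np.degrees(np.arctan2(dy_mm, geometry.distance_mm))
    return deg_x, deg_y


@dataclass(frozen=True)
class RoIMap:
    """Axis-aligned regions of interest, in screen pixels.

    ``social`` covers the interaction partner's face (a square, typically
    above the top edge of the monitor); ``left_stim``/``right_stim`` cover
    the two stimulus bars. Every other location is the "random" region.
    Rectangles are ``(x0, y0, x1, y1)`` with inclusive min edges and
    exclusive max edges.
    """

    social: tuple[float, float, float, float]
    left_stim: tuple[float, float, float, float]
    right_stim: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        rects = {"social": self.social, "left_stim": self.left_stim,
                 "right_stim": self.right_stim}
        for name, (x0, y0, x1, y1) in rects.items():
            if not (x1 > x0 and y1 > y0):
                raise ValueError(f"RoI {name} has non-positive extent")
        items = list(rects.items())
        for i, (na, a) in enumerate(items):
            for nb, b in items[i + 1:]:
                if _rects_overlap(a, b):
                    raise ValueError(f"RoIs {na} and {nb} overlap")

    def rect(self, label: str) -> tuple[float, float, float, float]:
        return {"social": self.social, "left_stim": self.left_stim,
                "right_stim": self.right_stim}[label]


def _rects_overlap(a, b) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def assign_roi(x_px, y_px, roi_map: RoIMap):
    """Label points with the RoI containing them (``random`` if none).

    Containment is inclusive on min edges and exclusive on max edges, so a
    point on a shared boundary belongs to the rectangle it is a min edge of.
    Accepts scalars or arrays; returns a scalar str or an object array.
    """
    x = np.atleast_1d(np.asarray(x_px, dtype=float))
    y = np.atleast_1d(np.asarray(y_px, dtype=float))
    out = np.full(x.shape, "random", dtype=object)
    for label in ("social", "left_stim", "right_stim"):
        x0, y0, x1, y1 = roi_map.rect(label)
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        out[inside] = label
    if np.isscalar(x_px) or np.ndim(x_px) == 0:
        return str(out[0])
    return out


@dataclass(frozen=True)
class ParserConfig:
    """Event-parser settings.

    velocity_threshold_deg_s : saccade criterion on angular speed (30 deg/s).
    smooth_width_ms          : boxcar width applied to the velocity trace.
    min_saccade_ms           : shortest run accepted as a saccade; suppresses
                               single-sample noise triggers.
    blink_pad_ms             : saccade-like artifacts starting or ending
                               within this distance of a blink edge are
                               absorbed into the blink.
    """

    velocity_threshold_deg_s: float = 30.0
    smooth_width_ms: int = 3
    min_saccade_ms: int = 4
    blink_pad_ms: int = 20
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)


def angular_speed(x_px, y_px, geometry: ScreenGeometry,
                  smooth_width_ms: int = 3) -> np.ndarray:
    """Angular speed (deg/s) on the 1 ms grid.

    Five-point central difference of the degree-converted positions,
    then a boxcar of ``smooth_width_ms``. NaN positions (pupil lost)
    propagate into the neighbourhood of the blink.
    """
    gx, gy = px_to_deg(x_px, y_px, geometry)
    finite = np.isfinite(gx) & np.isfinite(gy)
    if not finite.all():
        # interpolate across pupil-loss gaps so the running filters stay
        # well-defined, then invalidate the gap neighbourhood afterwards
        idx = np.arange(len(gx), dtype=float)
        gx = np.interp(idx, idx[finite], gx[finite])
        gy = np.interp(idx, idx[finite], gy[finite])
    vx = _central_diff5(gx)
    vy = _central_diff5(gy)
    speed = np.hypot(vx, vy) * 1000.0  # deg/ms -> deg/s
    if smooth_width_ms > 1:
        speed = uniform_filter1d(speed, size=smooth_width_ms, mode="nearest")
    if not finite.all():
        reach = 2 + (smooth_width_ms + 1) // 2  # stencil + smoother footprint
        bad = binary_dilation(~finite, iterations=reach)
        speed[bad] = np.nan
    return speed


def _central_diff5(f: np.ndarray) -> np.ndarray:
    # f'[i] = (f[i-2] - 8 f[i-1] + 8 f[i+1] - f[i+2]) / 12, edge-padded
    fp = np.pad(f, 2, mode="edge")
    return (fp[:-4] - 8 * fp[1:-3] + 8 * fp[3:-1] - fp[4:]) / 12.0


def detect_events(samples: pd.DataFrame, config: ParserConfig | None = None) -> pd.DataFrame:
    """Parse a gaze stream into fixation / saccade / blink events.

    ``samples`` must hold the columns ``time_ms, x_px, y_px, valid`` on a
    strict 1 ms grid. Returns a DataFrame with columns
    ``kind, onset, offset, x_start, y_start, x_end, y_end, peak_vel``
    whose intervals tile ``[t0, t0 + n)`` without overlap.
    """
    if config is None:
        config = ParserConfig()
    t = np.asarray(samples["time_ms"], dtype=np.int64)
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.diff(t) == 1):
        raise ValueError("samples must be on a strict 1 ms grid")
    valid = np.asarray(samples["valid"], dtype=bool)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid samples")
    x = np.asarray(samples["x_px"], dtype=float).copy()
    y = np.asarray(samples["y_px"], dtype=float).copy()
    x[~valid] = np.nan
    y[~valid] = np.nan
    n = len(t)

    speed = angular_speed(x, y, config.geometry, config.smooth_width_ms)

    blink_runs = _bool_runs(~valid)
    with np.errstate(invalid="ignore"):
        sacc_mask = np.nan_to_num(speed, nan=0.0) >= config.velocity_threshold_deg_s
    sacc_mask &= valid
    sacc_runs = [(a, b) for a, b in _bool_runs(sacc_mask)
                 if b - a >= config.min_saccade_ms]

    # absorb blink-adjacent saccade artifacts into the blink
    pad = config.blink_pad_ms
    merged_blinks = [list(r) for r in blink_runs]
    kept_sacc = []
    for a, b in sacc_runs:
        absorbed = False
        for br in merged_blinks:
            if a < br[1] + pad and b > br[0] - pad:
                br[0] = min(br[0], a)
                br[1] = max(br[1], b)
                absorbed = True
                break
        if not absorbed:
            kept_sacc.append((a, b))
    merged_blinks = _merge_overlaps(sorted(tuple(r) for r in merged_blinks))

    events: list[tuple] = []
    occupied = np.zeros(n, dtype=bool)
    for a, b in merged_blinks:
        events.append(("blink", a, b))
        occupied[a:b] = True
    for a, b in kept_sacc:
        if occupied[a:b].any():
            continue  # swallowed by an extended blink
        events.append(("saccade", a, b))
        occupied[a:b] = True
    for a, b in _bool_runs(~occupied):
        events.append(("fixation", a, b))
    events.sort(key=lambda e: e[1])

    rows = []
    for kind, a, b in events:
        seg_x, seg_y = x[a:b], y[a:b]
        if kind == "fixation":
            xs = xe = float(np.nanmean(seg_x)) if np.any(np.isfinite(seg_x)) else np.nan
            ys = ye = float(np.nanmean(seg_y)) if np.any(np.isfinite(seg_y)) else np.nan
        elif kind == "saccade":
            xs, ys = float(seg_x[0]), float(seg_y[0])
            xe, ye = float(seg_x[-1]), float(seg_y[-1])
        else:
            xs = ys = xe = ye = np.nan
        pv = float(np.nanmax(speed[a:b])) if kind == "saccade" else np.nan
        rows.append((kind, int(t[0] + a), int(t[0] + b), xs, ys, xe, ye, pv))
    return pd.DataFrame(rows, columns=["kind", "onset", "offset", "x_start",
                                       "y_start", "x_end", "y_end", "peak_vel"])


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_overlaps(runs):
    out: list[list[int]] = []
    for a, b in runs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def read_gaze_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df[GAZE_COLUMNS]


def read_asc_events(path) -> pd.DataFrame:
    """Read a simplified EyeLink-ASC-like text export of parsed events.

    Supported line formats (tab- or space-separated, monocular)::

        EFIX <eye> <start> <end> <dur> <x> <y> [...]
        ESACC <eye> <start> <end> <dur> <sx> <sy> <ex> <ey> [...]
        EBLINK <eye> <start> <end> <dur>

    End timestamps in ASC exports are inclusive; they are converted to the
    half-open convention used throughout this package.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag == "EFIX":
                s, e = int(parts[2]), int(parts[3]) + 1
                fx, fy = float(parts[5]), float(parts[6])
                rows.append(("fixation", s, e, fx, fy, fx, fy, np.nan))
            elif tag == "ESACC":
                s, e = int(parts[2]), int(parts[3]) + 1
                rows.append(("saccade", s, e, float(parts[5]), float(parts[6]),
                             float(parts[7]), float(parts[8]), np.nan))
            elif tag == "EBLINK":
                s, e = int(parts[2]), int(parts[3]) + 1
                rows.append(("blink", s, e, np.nan, np.nan, np.nan, np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["kind", "onset", "offset", "x_start",
                                     "y_start", "x_end", "y_end", "peak_vel"])
    return df.sort_values("onset", ignore_index=True)
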