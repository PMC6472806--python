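"""Head-restrained tail skeletonization.

Two segment-finding strategies are provided: ``"com"`` walks the tail by
taking the intensity-weighted center of mass of a square window placed one
segment ahead of the current endpoint, ``"arc"`` picks the brightest pixel
on an arc of one segment-length radius.  Both operate on preprocessed
frames where the tail is brighter than the background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .imaging import Frame

__all__ = [
    "TailParams",
    "TailTrace",
    "trace_tail",
    "resample_segments",
    "total_curvature",
]

MAX_BEND_DEFAULT = math.pi / 2


@dataclass(frozen=True)
class TailParams:
    """Geometry and method configuration for tail tracing.

    ``start_xy`` is the tail base (in pixels) and ``tail_dir0`` the resting
    direction toward the tip, typically derived from a user-supplied end
    point.  ``window_size`` defaults to one segment length.
    """

    start_xy: tuple[float, float]
    tail_dir0: float
    tail_length: float
    n_segments: int = 9
    window_size: float | None = None
    method: str = "com"
    arc_halfwidth: float = math.pi / 4
    max_bend: float = MAX_BEND_DEFAULT

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.tail_length <= 0:
            raise ValueError("tail_length must be > 0")
        if self.method not in ("com", "arc"):
            raise ValueError("method must be 'com' or 'arc'")

    @property
    def segment_length(self) -> float:
        return self.tail_length / self.n_segments

    @property
    def window(self) -> float:
        return self.segment_length if self.window_size is None else self.window_size


@dataclass(frozen=True)
class TailTrace:
    """Per-frame result: absolute segment angles and segment endpoints."""

    t: float
    theta: np.ndarray          # (n_segments,) absolute angles, radians
    points: np.ndarray         # (n_segments + 1, 2) endpoints in (x, y) px
    valid: bool = True

    @property
    def n_segments(self) -> int:
        return len(self.theta)


def _bilinear(px: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear intensity lookup at (x, y) pixel coordinates; samples
    outside the frame read as 0."""
    h, w = px.shape
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    fx = x - x0
    fy = y - y0

    def at(yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        inside = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        out = np.zeros(yy.shape, dtype=np.float64)
        out[inside] = px[yy[inside], xx[inside]]
        return out

    return (
        at(y0, x0) * (1 - fx) * (1 - fy)
        + at(y0, x0 + 1) * fx * (1 - fy)
        + at(y0 + 1, x0) * (1 - fx) * fy
        + at(y0 + 1, x0 + 1) * fx * fy
    )


def _window_inside(cx: float, cy: float, half: float, shape: tuple[int, int]) -> bool:
    h, w = shape
    return -half <= cx <= w - 1 + half and -half <= cy <= h - 1 + half


def _com_step(
    px: np.ndarray, end: np.ndarray, direction: float, seg_len: float, window: float
) -> float | None:
    """One COM step: returns the next absolute angle, or None when the
    sampling window carries no intensity / lies outside the frame."""
    cx = end[0] + seg_len * math.cos(direction)
    cy = end[1] + seg_len * math.sin(direction)
    half = window / 2.0
    if not _window_inside(cx, cy, half, px.shape):
        return None
    n = max(int(math.ceil(window)) + 1, 3)
    xs = np.linspace(cx - half, cx + half, n)
    ys = np.linspace(cy - half, cy + half, n)
    gx, gy = np.meshgrid(xs, ys)
    vals = _bilinear(px, gx, gy)
    total = vals.sum()
    if total <= 0:
        return None
    comx = (vals * gx).sum() / total
    comy = (vals * gy).sum() / total
    return math.atan2(comy - end[1], comx - end[0])


def _arc_step(
    px: np.ndarray, end: np.ndarray, direction: float, seg_len: float, halfwidth: float
) -> float | None:
    """One arc step: angle of the brightest sample along the look-ahead arc;
    ties broken toward the smallest deviation from the current direction."""
    # odd sample count at ~1 px arc spacing so the zero offset is included
    n = 2 * max(int(math.ceil(halfwidth * seg_len)), 2) + 1
    offsets = np.linspace(-halfwidth, halfwidth, n)
    # order by |deviation| so argmax tie-breaks toward straight-ahead
    order = np.argsort(np.abs(offsets), kind="stable")
    offsets = offsets[order]
    angles = direction + offsets
    xs = end[0] + seg_len * np.cos(angles)
    ys = end[1] + seg_len * np.sin(angles)
    h, w = px.shape
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not inside.any():
        return None
    vals = _bilinear(px, xs, ys)
    vals[~inside] = -np.inf
    best = int(np.argmax(vals))
    if vals[best] <= 0:
        return None
    return float(angles[best])


def trace_tail(frame: Frame, params: TailParams) -> TailTrace:
    """Trace ``params.n_segments`` tail segments starting at the tail base.

    Never raises on degenerate image content: when a step fails (window
    outside the frame or devoid of intensity) the previous direction is
    carried forward and the trace is flagged invalid.
    """
    px = np.asarray(frame.pixels, dtype=np.float64)
    h, w = px.shape
    x0, y0 = params.start_xy
    if not (0 <= x0 <= w - 1 and 0 <= y0 <= h - 1):
        raise ValueError("tail start point lies outside the frame")

    seg_len = params.segment_length
    points = np.empty((params.n_segments + 1, 2), dtype=np.float64)
    theta = np.empty(params.n_segments, dtype=np.float64)
    points[0] = (x0, y0)
    direction = params.tail_dir0
    valid = True

    for i in range(params.n_segments):
        if params.method == "com":
            ang = _com_step(px, points[i], direction, seg_len, params.window)
        else:
            ang = _arc_step(px, points[i], direction, seg_len, params.arc_halfwidth)
        if ang is None:
            ang = direction
            valid = False
        else:
            # clamp per-segment bend so the trace cannot fold onto the body
            dev = (ang - direction + math.pi) % (2 * math.pi) - math.pi
            dev = max(-params.max_bend, min(params.max_bend, dev))
            ang = direction + dev
        theta[i] = ang
        points[i + 1] = points[i] + seg_len * np.array([math.cos(ang), math.sin(ang)])
        direction = ang

    return TailTrace(t=frame.t, theta=theta, points=points, valid=valid)


def resample_segments(trace: TailTrace, n_out: int) -> TailTrace:
    """Interpolate the angle profile onto a fixed number of segments.

    The cumulative angle profile is linearly interpolated over normalized
    arc length; the first and last angles are preserved exactly, so
    :func:`total_curvature` is invariant under resampling.
    """
    if n_out < 2:
        raise ValueError("n_out must be >= 2")
    n_in = trace.n_segments
    if n_out == n_in:
        return replace(trace, theta=trace.theta.copy(), points=trace.points.copy())
    src = np.linspace(0.0, 1.0, n_in)
    dst = np.linspace(0.0, 1.0, n_out)
    theta = np.interp(dst, src, trace.theta)
    total_len = np.linalg.norm(np.diff(trace.points, axis=0), axis=1).sum()
    seg_len = total_len / n_out
    points = np.empty((n_out + 1, 2), dtype=np.float64)
    points[0] = trace.points[0]
    for i in range(n_out):
        points[i + 1] = points[i] + seg_len * np.array(
            [math.cos(theta[i]), math.sin(theta[i])]
        )
    return replace(trace, theta=theta, points=points)


def total_curvature(trace: TailTrace) -> float:
    """Angle difference between the last and first tail segment.

    Identical to the telescoping sum of successive angle differences.
    """
    return float(trace.theta[-1] - trace.theta[0])
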