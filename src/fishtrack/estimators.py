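"""Behavior-state estimators and closed-loop stimulus laws.

Sign convention: the vigor-derived fish velocity is *negative* when the fish
swims forward, so a closed-loop grating at gain 1 slows down (or reverses)
while the fish is swimming.  Thresholds like ``fish_vel < -15`` therefore
read "swimming forward faster than 15 mm/s".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import Frame

__all__ = [
    "VigorConfig",
    "GainProtocolSpec",
    "CalibrationTransform",
    "vigor",
    "fish_velocity",
    "grating_velocity",
    "interbout_intervals",
    "compute_calibration",
    "detect_calibration_points",
    "PhototaxisField",
    "phototaxis_field",
]


@dataclass(frozen=True)
class VigorConfig:
    """Vigor estimator configuration.

    ``vigor_scale`` and ``swim_threshold`` have no universal defaults — they
    depend on the preparation — and must be set explicitly for velocity
    estimation.
    """

    window: float = 0.050                # trailing std window, seconds
    vigor_scale: float | None = None     # (mm/s) per unit of curvature-std
    swim_threshold: float | None = None  # vigor units
    min_gap: float = 0.0                 # bout-merge gap, seconds

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")


@dataclass(frozen=True)
class GainProtocolSpec:
    base_velocity: float = 10.0          # mm/s
    spatial_frequency: float = 0.1       # cycles/mm
    gain_sequence: tuple[tuple[float, float], ...] = ((1.0, 60.0),)

    def __post_init__(self) -> None:
        for gain, duration in self.gain_sequence:
            if duration <= 0:
                raise ValueError("gain durations must be > 0")
            if gain < 0:
                raise ValueError("gains must be >= 0")


def vigor(curvature: np.ndarray, fs: float, cfg: VigorConfig) -> np.ndarray:
    """Trailing-window population standard deviation of total tail curvature.

    One output per input sample; samples before the first full window emit 0.
    """
    x = np.asarray(curvature, dtype=np.float64)
    n_win = int(round(cfg.window * fs))
    if n_win < 2:
        raise ValueError(
            f"window of {cfg.window} s holds fewer than 2 samples at {fs} Hz"
        )
    n = len(x)
    out = np.zeros(n)
    if n < n_win:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(x, n_win)
    out[n_win - 1 :] = windows.std(axis=1)   # population std, ddof = 0
    return out


def fish_velocity(vigor_value: float | np.ndarray, cfg: VigorConfig):
    """Vigor-proportional forward-velocity estimate, negative = forward.

    Zero below ``swim_threshold`` (threshold itself counts as swimming).
    """
    if cfg.vigor_scale is None or cfg.swim_threshold is None:
        raise ValueError("vigor_scale and swim_threshold must be configured")
    v = np.asarray(vigor_value, dtype=np.float64)
    out = np.where(v >= cfg.swim_threshold, -cfg.vigor_scale * v, 0.0)
    if np.isscalar(vigor_value) or np.ndim(vigor_value) == 0:
        return float(out)
    return out


def grating_velocity(v_base: float, v_fish, gain: float):
    """Closed-loop grating velocity law: ``v_base + gain * v_fish``.

    With the negative-forward convention, swimming subtracts from the
    baseline grating speed; gain 0 is open loop.
    """
    v = np.asarray(v_fish, dtype=np.float64)
    out = v_base + gain * v
    if np.ndim(v_fish) == 0:
        return float(out)
    return out


def interbout_intervals(
    vigor_trace: np.ndarray, fs: float, cfg: VigorConfig
) -> tuple[list[float], list[float], list[tuple[float, float]]]:
    """Bout segmentation of a vigor trace by threshold crossing.

    Bouts are maximal runs with ``vigor >= swim_threshold``; gaps shorter
    than ``cfg.min_gap`` are merged.  Returns
    ``(interbout_intervals_s, bout_durations_s, bout_spans)`` where spans are
    (start_t, end_t) pairs; the inter-bout interval is the time from one
    bout's end to the next bout's start.
    """
    if cfg.swim_threshold is None:
        raise ValueError("swim_threshold must be configured")
    v = np.asarray(vigor_trace, dtype=np.float64)
    active = v >= cfg.swim_threshold
    spans: list[list[int]] = []
    in_run = False
    for i, a in enumerate(active):
        if a and not in_run:
            spans.append([i, i])
            in_run = True
        elif a:
            spans[-1][1] = i
        else:
            in_run = False
    if cfg.min_gap > 0 and len(spans) > 1:
        merged = [spans[0]]
        gap_n = cfg.min_gap * fs
        for s in spans[1:]:
            if s[0] - merged[-1][1] - 1 < gap_n:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        spans = merged
    bout_spans = [(s0 / fs, (s1 + 1) / fs) for s0, s1 in spans]
    durations = [e - s for s, e in bout_spans]
    intervals = [
        bout_spans[i + 1][0] - bout_spans[i][1] for i in range(len(bout_spans) - 1)
    ]
    return intervals, durations, bout_spans


# ---------------------------------------------------------------------------
# camera <-> display calibration

@dataclass(frozen=True)
class CalibrationTransform:
    """Planar affine map: display = A @ camera + b."""

    A: np.ndarray      # (2, 2)
    b: np.ndarray      # (2,)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64).reshape(2, 2)
        b = np.asarray(self.b, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("calibration transform is singular")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    def map(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, dtype=np.float64) @ self.A.T + self.b

    def inverse_map(self, pts: np.ndarray) -> np.ndarray:
        Ainv = np.linalg.inv(self.A)
        return (np.asarray(pts, dtype=np.float64) - self.b) @ Ainv.T

    def as_matrix(self) -> np.ndarray:
        """2x3 [A | b] matrix for serialization."""
        return np.hstack([self.A, self.b[:, None]])


def compute_calibration(cam_pts: np.ndarray, disp_pts: np.ndarray) -> CalibrationTransform:
    """Unique affine transform mapping three camera points onto three display
    points.  Collinear camera points raise a degenerate-calibration error."""
    cam = np.asarray(cam_pts, dtype=np.float64).reshape(3, 2)
    disp = np.asarray(disp_pts, dtype=np.float64).reshape(3, 2)
    area2 = abs(
        (cam[1, 0] - cam[0, 0]) * (cam[2, 1] - cam[0, 1])
        - (cam[2, 0] - cam[0, 0]) * (cam[1, 1] - cam[0, 1])
    )
    scale = max(np.abs(cam).max(), 1.0)
    if area2 < 1e-9 * scale ** 2:
        raise ValueError("calibration points are collinear")
    M = np.hstack([cam, np.ones((3, 1))])           # [x y 1]
    coef = np.linalg.solve(M, disp)                  # rows: A row-wise + b
    A = coef[:2, :].T
    b = coef[2, :]
    return CalibrationTransform(A=A, b=b)


def detect_calibration_points(
    frame: Frame, n_points: int = 3, blur_sigma: float = 1.5, nms_radius: float = 6.0,
) -> np.ndarray:
    """The ``n_points`` brightest local maxima of a blurred frame, refined to
    sub-pixel precision by center of mass, sorted lexicographically."""
    px = gaussian_filter(np.asarray(frame.pixels, dtype=np.float64), blur_sigma)
    h, w = px.shape
    order = np.argsort(px, axis=None)[::-1]
    floor = px.min() + 1e-6 * (px.max() - px.min() + 1e-30)
    peaks: list[tuple[float, float]] = []
    for flat in order:
        y, x = divmod(int(flat), w)
        if px[y, x] <= floor:
            break
        if any((x - qx) ** 2 + (y - qy) ** 2 < nms_radius ** 2 for qx, qy in peaks):
            continue
        y0, y1 = max(y - 3, 0), min(y + 4, h)
        x0, x1 = max(x - 3, 0), min(x + 4, w)
        win = px[y0:y1, x0:x1] - px[y0:y1, x0:x1].min()
        tot = win.sum()
        if tot > 0:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            peaks.append(((win * xs).sum() / tot, (win * ys).sum() / tot))
        else:
            peaks.append((float(x), float(y)))
        if len(peaks) >= n_points:
            break
    if len(peaks) < n_points:
        raise ValueError(f"found only {len(peaks)} distinct maxima, need {n_points}")
    return np.asarray(sorted(peaks))


# ---------------------------------------------------------------------------
# phototaxis half-field geometry

@dataclass(frozen=True)
class PhototaxisField:
    """Half-plane stimulus locked to the fish midline.

    The boundary is the line through ``pos`` along ``heading``; which side is
    bright is set by ``bright_left``.  "Left" is the side with positive cross
    product ``heading x offset``.
    """

    pos: tuple[float, float]
    heading: float
    bright_left: bool = True

    def is_bright(self, point) -> bool:
        px, py = point
        dx, dy = px - self.pos[0], py - self.pos[1]
        cross = math.cos(self.heading) * dy - math.sin(self.heading) * dx
        return cross > 0 if self.bright_left else cross < 0

    def brightness_mask(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        dx = xs - self.pos[0]
        dy = ys - self.pos[1]
        cross = math.cos(self.heading) * dy - math.sin(self.heading) * dx
        return cross > 0 if self.bright_left else cross < 0


def phototaxis_field(
    fish_pos: tuple[float, float], fish_heading: float, bright_left: bool = True
) -> PhototaxisField:
    """Half-field stimulus descriptor with the light/dark boundary along the
    fish midline."""
    return PhototaxisField(pos=tuple(fish_pos), heading=float(fish_heading),
                           bright_left=bright_left)
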