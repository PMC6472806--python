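"""Ground-truth fixture generator.

Renders tail, eye and freely-swimming scenes with exactly known kinematics,
and generates curvature / trajectory time series with the statistical
structure the trackers assume.  The renderer — not the tracker — defines
truth; all randomness is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import Frame

__all__ = [
    "TailGroundTruth",
    "FishTemplate",
    "SceneGroundTruth",
    "render_tail_frame",
    "render_eye_frame",
    "render_calibration_frame",
    "generate_bout_trace",
    "generate_bout_train",
    "simulate_swim_trajectory",
    "render_scene",
]


# ---------------------------------------------------------------------------
# low-level anti-aliased drawing (distance-field based, sub-pixel accurate)

def _dist_to_segments(xs: np.ndarray, ys: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Min distance from grid points (xs, ys) to the polyline ``pts``."""
    p = np.stack([xs, ys], axis=-1)[..., None, :]       # (..., 1, 2)
    a = pts[:-1][None, None, :, :]
    b = pts[1:][None, None, :, :]
    ab = b - a
    denom = (ab ** 2).sum(-1)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.sqrt(((p - proj) ** 2).sum(-1))
    return d.min(axis=-1)


def _soft_edge(dist: np.ndarray, radius: float, softness: float = 1.0) -> np.ndarray:
    """Coverage in [0, 1]: 1 inside ``radius``, rolling off over ``softness``."""
    return np.clip((radius + softness / 2 - dist) / softness, 0.0, 1.0)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.astype(np.float64), ys.astype(np.float64)


def _stamp_disc(img: np.ndarray, center: tuple[float, float], radius: float,
                value: float) -> None:
    """Blend an anti-aliased disc of ``value`` into ``img`` (min-composited:
    darker marks win, matching dark fish on bright background)."""
    h, w = img.shape
    cx, cy = center
    r = int(math.ceil(radius + 2))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 2, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xs - cx, ys - cy)
    cov = _soft_edge(d, radius)
    patch = img[y0:y1, x0:x1]
    patch[:] = patch * (1 - cov) + value * cov


# ---------------------------------------------------------------------------
# tail fixtures

@dataclass(frozen=True)
class TailGroundTruth:
    """Exact tail geometry for one rendered frame."""

    angles: np.ndarray                       # absolute segment angles, radians
    start_xy: tuple[float, float]
    segment_length: float                    # pixels
    shape: tuple[int, int] = (120, 160)      # (rows, cols)
    width: float = 3.0                       # full tail width, pixels
    intensity: float = 200.0
    background: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def polyline(self) -> np.ndarray:
        """(n+1, 2) segment endpoints in (x, y) pixels."""
        angles = np.asarray(self.angles, dtype=np.float64)
        pts = np.empty((len(angles) + 1, 2))
        pts[0] = self.start_xy
        for i, a in enumerate(angles):
            pts[i + 1] = pts[i] + self.segment_length * np.array([math.cos(a), math.sin(a)])
        return pts

    @property
    def tail_length(self) -> float:
        return self.segment_length * len(self.angles)


def render_tail_frame(truth: TailGroundTruth, t: float = 0.0, frame_id: int = 0) -> Frame:
    """Draw the tail polyline as an anti-aliased bright curve on a dark
    background, plus seeded Gaussian pixel noise.  Raises if the curve
    leaves the frame (fixtures must be fully visible)."""
    pts = truth.polyline()
    h, w = truth.shape
    margin = truth.width / 2 + 1
    if (pts[:, 0].min() < margin or pts[:, 0].max() > w - 1 - margin
            or pts[:, 1].min() < margin or pts[:, 1].max() > h - 1 - margin):
        raise ValueError("tail curve leaves the frame")
    xs, ys = _grid(truth.shape)
    d = _dist_to_segments(xs, ys, pts)
    cov = _soft_edge(d, truth.width / 2)
    img = truth.background * (1 - cov) + truth.intensity * cov
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed + frame_id)
        img = img + rng.normal(0.0, truth.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 255.0)
    return Frame(pixels=img, t=t, frame_id=frame_id)


# ---------------------------------------------------------------------------
# eye fixtures

def render_eye_frame(
    centers: list[tuple[float, float]],
    semiaxes: list[tuple[float, float]],
    angles: list[float],
    shape: tuple[int, int] = (100, 140),
    background: float = 220.0,
    eye_value: float = 30.0,
    t: float = 0.0,
    frame_id: int = 0,
    supersample: int = 4,
) -> Frame:
    """Dark filled ellipses on a bright field, rendered with supersampled
    coverage so edges are sub-pixel accurate."""
    h, w = shape
    s = supersample
    ys, xs = np.mgrid[0 : h * s, 0 : w * s]
    xs = (xs + 0.5) / s - 0.5
    ys = (ys + 0.5) / s - 0.5
    mask = np.zeros((h * s, w * s), dtype=bool)
    for (cx, cy), (a, b), ang in zip(centers, semiaxes, angles):
        ca, sa = math.cos(ang), math.sin(ang)
        u = (xs - cx) * ca + (ys - cy) * sa
        v = -(xs - cx) * sa + (ys - cy) * ca
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cov = mask.reshape(h, s, w, s).mean(axis=(1, 3))
    img = background * (1 - cov) + eye_value * cov
    return Frame(pixels=img, t=t, frame_id=frame_id)


def render_calibration_frame(
    points: list[tuple[float, float]],
    shape: tuple[int, int] = (120, 160),
    sigma: float = 2.0,
    amplitudes: list[float] | None = None,
    background: float = 10.0,
) -> Frame:
    """Bright Gaussian spots at the given sub-pixel centers."""
    xs, ys = _grid(shape)
    img = np.full(shape, background, dtype=np.float64)
    if amplitudes is None:
        amplitudes = [200.0] * len(points)
    for (cx, cy), amp in zip(points, amplitudes):
        img += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))
    return Frame(pixels=np.clip(img, 0, 255))


# ---------------------------------------------------------------------------
# kinematic time series

def _envelope(n: int, kind: str) -> np.ndarray:
    if kind == "rect":
        return np.ones(n)
    if kind == "raised-cosine":
        return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))
    raise ValueError(f"unknown envelope {kind!r}")


def generate_bout_trace(
    f_beat: float,
    amplitude: float,
    duration: float,
    fs: float,
    envelope: str = "rect",
    t_start: float = 0.0,
    total_duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total-curvature time series of a single bout.

    ``curvature(t) = amplitude * env(t - t_start) * sin(2 pi f_beat (t - t_start))``
    inside the bout, zero outside.  Returns ``(t, curvature)``.
    """
    if fs <= 2 * f_beat:
        raise ValueError("sampling rate must exceed twice the beat frequency")
    if total_duration is None:
        total_duration = t_start + duration
    n = int(round(total_duration * fs))
    t = np.arange(n) / fs
    curv = np.zeros(n)
    in_bout = (t >= t_start) & (t < t_start + duration)
    tb = t[in_bout] - t_start
    env = _envelope(in_bout.sum(), envelope)
    curv[in_bout] = amplitude * env * np.sin(2 * np.pi * f_beat * tb)
    return t, curv


def generate_bout_train(
    bout_starts: list[float],
    f_beat: float,
    amplitude: float,
    bout_duration: float,
    fs: float,
    total_duration: float,
    envelope: str = "rect",
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose several identical bouts at the given start times."""
    n = int(round(total_duration * fs))
    t = np.arange(n) / fs
    curv = np.zeros(n)
    for start in bout_starts:
        _, one = generate_bout_trace(
            f_beat, amplitude, bout_duration, fs, envelope, start, total_duration
        )
        curv += one
    return t, curv


# ---------------------------------------------------------------------------
# freely-swimming scenes

@dataclass(frozen=True)
class FishTemplate:
    """Body proportions of the rendered fish (pixels, intensities 0-255).

    Offsets are chosen so that the mean of the two eye centers and the swim
    bladder center coincides with the nominal head position: the eyes sit
    ``bladder_back / 2`` ahead of it and the bladder ``bladder_back`` behind.
    """

    head_radius: float = 6.0
    eye_radius: float = 2.2
    bladder_radius: float = 2.5
    eye_spacing: float = 5.0           # between eye centers, perpendicular
    bladder_back: float = 6.0          # bladder behind head center
    tail_length: float = 28.0
    tail_width: float = 2.0
    body_value: float = 140.0          # head disc intensity
    eye_value: float = 30.0            # eyes darker than body
    bladder_value: float = 40.0
    tail_value: float = 150.0

    @property
    def eye_forward(self) -> float:
        return self.bladder_back / 2.0


@dataclass(frozen=True)
class SceneGroundTruth:
    """Per-frame, per-fish poses plus everything needed to re-render them."""

    pos: np.ndarray            # (n_frames, n_fish, 2) head centers, px
    heading: np.ndarray        # (n_frames, n_fish) radians, unwrapped
    tail_angles: np.ndarray    # (n_frames, n_fish, n_segments) absolute
    fs: float
    arena_shape: tuple[int, int] = (240, 320)
    background: float = 220.0
    noise_sigma: float = 0.0
    seed: int = 0
    template: FishTemplate = field(default_factory=FishTemplate)
    overlapping: np.ndarray | None = None   # (n_frames,) bool, fish overlap

    @property
    def n_frames(self) -> int:
        return self.pos.shape[0]

    @property
    def n_fish(self) -> int:
        return self.pos.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


def simulate_swim_trajectory(
    n_bouts: int,
    arena_shape: tuple[int, int] = (240, 320),
    fs: float = 100.0,
    bout_duration: float = 0.2,
    interbout: float = 0.5,
    peak_speed: float = 120.0,          # px/s at bout peak
    turn_mean: float = 0.0,
    turn_std: float = math.radians(25),
    start_pos: tuple[float, float] | None = None,
    start_heading: float = 0.0,
    seed: int = 0,
    n_fish: int = 1,
    forced_turns: list[float] | None = None,
    **scene_kwargs,
) -> SceneGroundTruth:
    """Bout-and-glide trajectory: stationary between bouts; during a bout the
    speed follows a raised-cosine envelope and the heading ramps by a draw
    from N(turn_mean, turn_std).  Fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    h, w = arena_shape
    total = n_bouts * (bout_duration + interbout) + interbout
    n = int(round(total * fs))
    pos = np.zeros((n, n_fish, 2))
    heading = np.zeros((n, n_fish))
    margin = 45.0
    for f in range(n_fish):
        if start_pos is None or n_fish > 1:
            p = np.array([
                rng.uniform(margin, w - margin),
                rng.uniform(margin, h - margin),
            ])
        else:
            p = np.array(start_pos, dtype=np.float64)
        hd = start_heading if n_fish == 1 else rng.uniform(0, 2 * math.pi)
        nb = int(round(bout_duration * fs))
        env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(nb) / max(nb - 1, 1)))
        # turn rate follows the speed envelope, so heading settles when the
        # fish stops moving
        turn_frac = np.cumsum(env) / env.sum()
        i = int(round(interbout * fs / 2))
        pos[:i, f] = p
        heading[:i, f] = hd
        for b in range(n_bouts):
            if forced_turns is not None:
                turn = forced_turns[b % len(forced_turns)]
            else:
                turn = rng.normal(turn_mean, turn_std)
            for k in range(nb):
                if i + k >= n:
                    break
                hd_k = hd + turn * turn_frac[k]
                step = peak_speed * env[k] / fs
                p = p + step * np.array([math.cos(hd_k), math.sin(hd_k)])
                p[0] = np.clip(p[0], margin, w - margin)
                p[1] = np.clip(p[1], margin, h - margin)
                pos[i + k, f] = p
                heading[i + k, f] = hd_k
            hd = hd + turn
            i += nb
            j = min(i + int(round(interbout * fs)), n)
            pos[i:j, f] = p
            heading[i:j, f] = hd
            i = j
        pos[i:, f] = p
        heading[i:, f] = hd

    template: FishTemplate = scene_kwargs.pop("template", FishTemplate())
    n_seg = scene_kwargs.pop("n_tail_segments", 5)
    tail_angles = np.repeat(
        (heading[..., None] + math.pi), n_seg, axis=-1
    )  # straight tail opposite the heading
    # mark frames where any two fish come closer than one body length
    overlap = np.zeros(n, dtype=bool)
    if n_fish > 1:
        for a in range(n_fish):
            for b in range(a + 1, n_fish):
                d = np.linalg.norm(pos[:, a] - pos[:, b], axis=1)
                overlap |= d < 2 * (template.head_radius + template.tail_length)
    return SceneGroundTruth(
        pos=pos, heading=heading, tail_angles=tail_angles, fs=fs,
        arena_shape=arena_shape, seed=seed, template=template,
        overlapping=overlap, **scene_kwargs,
    )


def _render_fish(img: np.ndarray, pos: np.ndarray, heading: float,
                 tail_angles: np.ndarray, tpl: FishTemplate) -> None:
    fwd = np.array([math.cos(heading), math.sin(heading)])
    perp = np.array([-math.sin(heading), math.cos(heading)])
    head = pos
    _stamp_disc(img, tuple(head), tpl.head_radius, tpl.body_value)
    # tail polyline from the back of the head, following the truth angles
    seg_len = tpl.tail_length / len(tail_angles)
    p = head - fwd * tpl.head_radius * 0.8
    xs, ys = _grid(img.shape)
    pts = [p]
    for a in tail_angles:
        p = p + seg_len * np.array([math.cos(a), math.sin(a)])
        pts.append(p)
    pts = np.asarray(pts)
    x0 = int(np.clip(pts[:, 0].min() - 4, 0, img.shape[1]))
    x1 = int(np.clip(pts[:, 0].max() + 5, 0, img.shape[1]))
    y0 = int(np.clip(pts[:, 1].min() - 4, 0, img.shape[0]))
    y1 = int(np.clip(pts[:, 1].max() + 5, 0, img.shape[0]))
    if x1 > x0 and y1 > y0:
        d = _dist_to_segments(xs[y0:y1, x0:x1], ys[y0:y1, x0:x1], pts)
        cov = _soft_edge(d, tpl.tail_width / 2)
        patch = img[y0:y1, x0:x1]
        patch[:] = patch * (1 - cov) + tpl.tail_value * cov
    # dark landmarks last so they are not overdrawn
    eye_c = head + fwd * tpl.eye_forward
    _stamp_disc(img, tuple(eye_c + perp * tpl.eye_spacing / 2), tpl.eye_radius, tpl.eye_value)
    _stamp_disc(img, tuple(eye_c - perp * tpl.eye_spacing / 2), tpl.eye_radius, tpl.eye_value)
    _stamp_disc(img, tuple(head - fwd * tpl.bladder_back), tpl.bladder_radius, tpl.bladder_value)


def render_scene(truth: SceneGroundTruth) -> list[Frame]:
    """Render every frame of the scene: dark fish (head disc, darker eyes and
    swim bladder, tail polyline) on a bright background.  Overlapping fish
    are drawn as-is; such frames are flagged in ``truth.overlapping``."""
    frames = []
    rng = np.random.default_rng(truth.seed)
    for i in range(truth.n_frames):
        img = np.full(truth.arena_shape, truth.background, dtype=np.float64)
        for f in range(truth.n_fish):
            _render_fish(img, truth.pos[i, f], truth.heading[i, f],
                         truth.tail_angles[i, f], truth.template)
        if truth.noise_sigma > 0:
            img = img + rng.normal(0, truth.noise_sigma, img.shape)
        img = np.clip(img, 0, 255)
        frames.append(Frame(pixels=img, t=i / truth.fs, frame_id=i))
    return frames
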