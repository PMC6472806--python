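"""Freely-swimming fish tracking: detection from background-subtracted
frames, heading initialization, greedy identity matching and Kalman
smoothing of the kinematic parameters."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .imaging import BackgroundModel, Frame, foreground, update_background
from .tail import TailParams, trace_tail

__all__ = [
    "FishParams",
    "FishState",
    "Detection",
    "detect_fish",
    "initial_tail_direction",
    "assign_identities",
    "track_sequence",
    "bout_kinematics",
    "BoutRecord",
]


@dataclass(frozen=True)
class FishParams:
    area_range: tuple[float, float] = (50.0, 2000.0)
    fg_threshold: float = 25.0          # binarization level on the fg image
    eye_bladder_threshold: float = 60.0  # fg level marking eyes/bladder
    tail_radius: float = 28.0           # ~ tail length in pixels
    n_tail_segments: int = 5
    max_jump: float = 40.0              # px/frame for identity matching
    heading_weight: float = 10.0        # px per radian in the matching cost
    landmark_nms_radius: float = 4.5    # ~ eye diameter
    bg_time_constant: float = 60.0
    bg_init_frames: int = 5
    # Kalman noise (pos px, heading rad)
    process_noise_pos: float = 30.0
    process_noise_heading: float = 3.0
    meas_noise_pos: float = 1.0
    meas_noise_heading: float = 0.1

    def __post_init__(self) -> None:
        if self.area_range[0] >= self.area_range[1]:
            raise ValueError("area_range must satisfy min < max")
        if self.tail_radius <= 0:
            raise ValueError("tail_radius must be > 0")


@dataclass
class FishState:
    id: int
    t: float
    pos_xy: tuple[float, float]
    heading: float                      # radians, unwrapped over time
    theta: np.ndarray | None = None     # tail segment angles
    vel_xy: tuple[float, float] = (0.0, 0.0)
    ang_vel: float = 0.0
    visible: bool = True
    low_confidence: bool = False


@dataclass(frozen=True)
class Detection:
    pos_xy: tuple[float, float]
    heading: float
    theta: np.ndarray | None = None
    low_confidence: bool = False


def _local_maxima(patch: np.ndarray, mask: np.ndarray, threshold: float,
                  nms_radius: float, k: int) -> list[tuple[float, float]]:
    """Up to ``k`` strongest local maxima of ``patch`` inside ``mask``, with
    greedy non-maximum suppression; centers refined by a small-window COM."""
    vals = np.where(mask, patch, -np.inf)
    order = np.argsort(vals, axis=None)[::-1]
    h, w = patch.shape
    picked: list[tuple[float, float]] = []
    for flat in order:
        y, x = divmod(int(flat), w)
        v = vals[y, x]
        if v < threshold or not np.isfinite(v):
            break
        if any((x - px) ** 2 + (y - py) ** 2 < nms_radius ** 2 for px, py in picked):
            continue
        # sub-pixel refinement: intensity-weighted COM in a 5x5 window
        y0, y1 = max(y - 2, 0), min(y + 3, h)
        x0, x1 = max(x - 2, 0), min(x + 3, w)
        win = np.clip(patch[y0:y1, x0:x1], 0, None)
        tot = win.sum()
        if tot > 0:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            picked.append(((win * xs).sum() / tot, (win * ys).sum() / tot))
        else:
            picked.append((float(x), float(y)))
        if len(picked) >= k:
            break
    return picked


def initial_tail_direction(fg: Frame, head_xy: tuple[float, float],
                           params: FishParams) -> tuple[float, bool]:
    """Angle of the strongest foreground sample on the circle of half the
    tail radius around the head; the heading is this angle + pi.

    Returns ``(angle, ok)``; a featureless circle is flagged ``ok=False``
    with the tie broken toward the smallest angle.
    """
    px = np.asarray(fg.pixels, dtype=np.float64)
    h, w = px.shape
    cx, cy = head_xy
    r = params.tail_radius / 2.0
    n = max(int(round(2 * math.pi * r)), 16)
    angles = 2 * math.pi * np.arange(n) / n
    xs = cx + r * np.cos(angles)
    ys = cy + r * np.sin(angles)
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    if not inside.any():
        raise ValueError("sampling circle lies fully outside the frame")
    from .tail import _bilinear  # shared sub-pixel sampler
    vals = _bilinear(px, xs, ys)
    vals[~inside] = -np.inf
    best = int(np.argmax(vals))
    spread = np.nanmax(vals[inside]) - np.nanmin(vals[inside])
    if spread <= 1e-9:
        return float(angles[0]), False
    return float(angles[best]), True


def detect_fish(fg: Frame, params: FishParams) -> list[Detection]:
    """Detect candidate fish in a foreground frame.

    Each above-threshold connected component within ``area_range`` yields one
    detection.  The head center is the mean of the three dark-landmark
    centroids (two eyes + swim bladder, the strongest foreground maxima);
    components lacking three landmarks fall back to the blob centroid and
    principal axis, flagged low-confidence.
    """
    px = np.asarray(fg.pixels, dtype=np.float64)
    mask = px > params.fg_threshold
    labels = label(mask, connectivity=2)
    detections: list[Detection] = []
    for region in regionprops(labels):
        if not (params.area_range[0] <= region.area <= params.area_range[1]):
            continue
        comp_mask = labels == region.label
        peaks = _local_maxima(px, comp_mask, params.eye_bladder_threshold,
                              params.landmark_nms_radius, 3)
        if len(peaks) == 3:
            head = np.mean(np.asarray(peaks), axis=0)
            low_conf = False
        else:
            cy, cx = region.centroid
            head = np.array([cx, cy])
            low_conf = True
        try:
            tail_dir, ok = initial_tail_direction(fg, tuple(head), params)
        except ValueError:
            tail_dir, ok = 0.0, False
        low_conf = low_conf or not ok
        if low_conf and len(peaks) != 3:
            hd = float(region.orientation)
            # regionprops orientation is against the row axis; convert to our
            # (x right, y down, ccw-from-x) convention
            heading = (-hd + math.pi / 2) % (2 * math.pi)
            detections.append(Detection(tuple(head), heading, None, True))
            continue
        tp = TailParams(
            start_xy=tuple(head), tail_dir0=tail_dir,
            tail_length=params.tail_radius, n_segments=params.n_tail_segments,
            method="com",
        )
        trace = trace_tail(fg, tp)
        heading = (trace.theta[0] + math.pi) % (2 * math.pi)
        detections.append(Detection(tuple(head), float(heading), trace.theta, low_conf))
    return detections


def _angdiff(a: float, b: float) -> float:
    return (a - b + math.pi) % (2 * math.pi) - math.pi


def assign_identities(
    prev: list[FishState], detections: list[Detection],
    max_jump: float = 40.0, heading_weight: float = 10.0,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy minimum-cost matching of detections to previous states.

    Cost = Euclidean distance + ``heading_weight`` * |heading difference|;
    pairs farther than ``max_jump`` are rejected.  Returns
    ``(matches, unmatched_detection_indices, unmatched_state_indices)`` where
    matches are ``(state_index, detection_index)`` pairs.
    """
    pairs = []
    for i, s in enumerate(prev):
        for j, d in enumerate(detections):
            dist = math.hypot(s.pos_xy[0] - d.pos_xy[0], s.pos_xy[1] - d.pos_xy[1])
            if dist > max_jump:
                continue
            cost = dist + heading_weight * abs(_angdiff(s.heading, d.heading))
            pairs.append((cost, i, j))
    pairs.sort(key=lambda p: p[0])
    used_s: set[int] = set()
    used_d: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_s or j in used_d:
            continue
        matches.append((i, j))
        used_s.add(i)
        used_d.add(j)
    unmatched_d = [j for j in range(len(detections)) if j not in used_d]
    unmatched_s = [i for i in range(len(prev)) if i not in used_s]
    return matches, unmatched_d, unmatched_s


class _Kalman:
    """Constant-velocity filter over (x, y, heading, vx, vy, heading-rate)."""

    def __init__(self, params: FishParams, pos, heading, t):
        self.x = np.array([pos[0], pos[1], heading, 0.0, 0.0, 0.0])
        self.P = np.diag([4.0, 4.0, 0.5, 100.0, 100.0, 10.0])
        q = [params.process_noise_pos] * 2 + [params.process_noise_heading]
        self.Q_base = np.array(q, dtype=np.float64)
        self.R = np.diag([
            params.meas_noise_pos ** 2, params.meas_noise_pos ** 2,
            params.meas_noise_heading ** 2,
        ])
        self.t = t

    def step(self, z: np.ndarray, t: float) -> np.ndarray:
        dt = max(t - self.t, 1e-6)
        F = np.eye(6)
        F[0, 3] = F[1, 4] = F[2, 5] = dt
        # white-acceleration process noise, discretized per axis
        Q = np.zeros((6, 6))
        for k, qa in enumerate(self.Q_base):
            q2 = qa ** 2
            Q[k, k] = q2 * dt ** 3 / 3
            Q[k, k + 3] = Q[k + 3, k] = q2 * dt ** 2 / 2
            Q[k + 3, k + 3] = q2 * dt
        x_pred = F @ self.x
        P_pred = F @ self.P @ F.T + Q
        H = np.zeros((3, 6))
        H[0, 0] = H[1, 1] = H[2, 2] = 1.0
        z = z.copy()
        # unwrap the heading measurement against the prediction
        z[2] = x_pred[2] + _angdiff(z[2], x_pred[2] % (2 * math.pi))
        y = z - H @ x_pred
        S = H @ P_pred @ H.T + self.R
        K = P_pred @ H.T @ np.linalg.solve(S, np.eye(3))
        self.x = x_pred + K @ y
        self.P = (np.eye(6) - K @ H) @ P_pred
        self.t = t
        return self.x


def estimate_background(frames, step: int = 5) -> np.ndarray:
    """Pixel-wise maximum over a subsample of frames.

    With dark fish on a bright arena the maximum over frames where the fish
    moves recovers the empty arena; useful to seed :func:`track_sequence`
    when no fish-free footage exists.
    """
    bg = None
    for i, f in enumerate(frames):
        if i % step:
            continue
        px = np.asarray(f.pixels, dtype=np.float64)
        bg = px.copy() if bg is None else np.maximum(bg, px)
    if bg is None:
        raise ValueError("no frames given")
    return bg


def track_sequence(
    frames, params: FishParams, smooth: bool = True,
    background0: np.ndarray | None = None,
) -> list[list[FishState]]:
    """Run the full pipeline over a frame sequence.

    Per frame: update background -> foreground -> detect -> match identities
    -> Kalman update.  Detection starts once the background model has seen
    its initialization frames; earlier frames yield empty lists.  Passing a
    fish-free ``background0`` image seeds the model so detection starts on
    the first frame.  The result is deterministic for a fixed input
    sequence.
    """
    model = BackgroundModel(time_constant=params.bg_time_constant,
                            n_init_frames=params.bg_init_frames)
    if background0 is not None:
        model.mean_image = np.asarray(background0, dtype=np.float64).copy()
        model._n_seen = model.n_init_frames
    states: list[FishState] = []
    filters: dict[int, _Kalman] = {}
    next_id = 0
    out: list[list[FishState]] = []
    for frame in frames:
        update_background(model, frame)
        if not model.initialized:
            out.append([])
            continue
        fg = foreground(model, frame)
        detections = detect_fish(fg, params)
        visible_states = [s for s in states if s.visible]
        matches, new_d, lost_s = assign_identities(
            visible_states, detections, params.max_jump, params.heading_weight
        )
        new_states: list[FishState] = []
        for si, dj in matches:
            prev_s = visible_states[si]
            det = detections[dj]
            heading = prev_s.heading + _angdiff(det.heading, prev_s.heading % (2 * math.pi))
            if smooth:
                kf = filters[prev_s.id]
                xs = kf.step(np.array([*det.pos_xy, heading]), frame.t)
                new_states.append(FishState(
                    id=prev_s.id, t=frame.t, pos_xy=(xs[0], xs[1]),
                    heading=float(xs[2]), theta=det.theta,
                    vel_xy=(xs[3], xs[4]), ang_vel=float(xs[5]),
                    visible=True, low_confidence=det.low_confidence,
                ))
            else:
                new_states.append(FishState(
                    id=prev_s.id, t=frame.t, pos_xy=det.pos_xy,
                    heading=heading, theta=det.theta,
                    visible=True, low_confidence=det.low_confidence,
                ))
        for dj in new_d:
            det = detections[dj]
            fid = next_id
            next_id += 1
            filters[fid] = _Kalman(params, det.pos_xy, det.heading, frame.t)
            new_states.append(FishState(
                id=fid, t=frame.t, pos_xy=det.pos_xy, heading=det.heading,
                theta=det.theta, visible=True, low_confidence=det.low_confidence,
            ))
        for si in lost_s:
            prev_s = visible_states[si]
            filters.pop(prev_s.id, None)   # id retired
            new_states.append(FishState(
                id=prev_s.id, t=frame.t, pos_xy=prev_s.pos_xy,
                heading=prev_s.heading, visible=False,
            ))
        states = new_states
        out.append([s for s in new_states])
    return out


@dataclass(frozen=True)
class BoutRecord:
    start_t: float
    end_t: float
    trajectory: np.ndarray      # (n, 2) positions realigned to origin-heading
    speed: np.ndarray           # px/s during the bout
    total_angle_change: float   # unwrapped heading end - start, radians
    interbout_before: float | None = None   # s since the previous bout's end

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def _realign(pos: np.ndarray, heading0: float) -> np.ndarray:
    """Rigid transform: translate the first sample to the origin and rotate
    so the initial heading points along +x."""
    d = pos - pos[0]
    c, s = math.cos(-heading0), math.sin(-heading0)
    R = np.array([[c, -s], [s, c]])
    return d @ R.T


def bout_kinematics(
    t: np.ndarray, pos: np.ndarray, heading: np.ndarray,
    speed_on: float = 20.0, speed_off: float | None = None,
    pad: int = 0,
) -> list[BoutRecord]:
    """Segment a single fish's trajectory into bouts by speed hysteresis.

    A bout starts when speed rises above ``speed_on`` and ends when it drops
    below ``speed_off`` (default ``speed_on / 2``); the boundaries are then
    refined outward to the surrounding quiescence (speed below 5% of
    ``speed_on``) so the slow head and tail of the speed envelope — where
    much of the turning happens — are included.  Each bout is re-aligned by
    a rigid transform so that it starts at the origin heading east.
    """
    t = np.asarray(t, dtype=np.float64)
    pos = np.asarray(pos, dtype=np.float64)
    heading = np.asarray(heading, dtype=np.float64)
    if len(t) < 3:
        return []
    if speed_off is None:
        speed_off = speed_on / 2.0
    dt = np.diff(t)
    speed = np.zeros(len(t))
    speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.where(dt > 0, dt, np.inf)
    bouts: list[tuple[int, int]] = []
    in_bout = False
    start = 0
    for i, v in enumerate(speed):
        if not in_bout and v >= speed_on:
            in_bout = True
            start = i
        elif in_bout and v < speed_off:
            bouts.append((start, i))
            in_bout = False
    if in_bout:
        bouts.append((start, len(t) - 1))
    # refine boundaries outward to near-zero speed, without crossing the
    # neighbouring bout
    floor = 0.05 * speed_on
    refined: list[tuple[int, int]] = []
    for k, (start, end) in enumerate(bouts):
        lo = refined[-1][1] + 1 if refined else 0
        hi = bouts[k + 1][0] - 1 if k + 1 < len(bouts) else len(t) - 1
        while start > lo and speed[start - 1] > floor:
            start -= 1
        while end < hi and speed[end + 1] > floor:
            end += 1
        refined.append((start, end))
    bouts = refined
    records: list[BoutRecord] = []
    prev_end_t: float | None = None
    for start, end in bouts:
        s0 = max(start - pad, 0)
        e1 = min(end + pad, len(t) - 1)
        traj = _realign(pos[s0 : e1 + 1], heading[s0])
        rec = BoutRecord(
            start_t=float(t[start]), end_t=float(t[end]),
            trajectory=traj, speed=speed[s0 : e1 + 1],
            total_angle_change=float(heading[end] - heading[start]),
            interbout_before=None if prev_end_t is None else float(t[start] - prev_end_t),
        )
        records.append(rec)
        prev_end_t = float(t[end])
    return records
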