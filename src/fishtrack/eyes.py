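"""Eye orientation tracking: threshold an eye region, keep the two largest
connected components and fit an ellipse to each by second-order moments."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .imaging import Frame

__all__ = ["EyeROI", "EyeState", "EllipseFit", "segment_eyes", "fit_ellipse", "track_eyes"]

#: moment-anisotropy ratio below which a blob counts as circular-degenerate
CIRCULAR_EPS = 0.02


@dataclass(frozen=True)
class EyeROI:
    """Rectangular eye region with the binarization threshold.

    Pixels strictly *below* ``threshold`` are selected — the eyes are much
    darker than the background in the raw image.
    """

    origin_xy: tuple[int, int]
    width: int
    height: int
    threshold: float
    min_area: int = 20

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        x0, y0 = self.origin_xy
        if not (0 <= x0 and 0 <= y0 and x0 + self.width <= w and y0 + self.height <= h):
            raise ValueError(f"ROI {self} outside frame of shape {shape}")


@dataclass(frozen=True)
class EllipseFit:
    center: tuple[float, float]      # (x, y) pixels
    major: float                     # semi-major axis, pixels
    minor: float                     # semi-minor axis, pixels
    angle: float                     # major-axis orientation, [0, pi)
    degenerate: bool = False         # circular blob: angle unreliable


@dataclass(frozen=True)
class EyeState:
    t: float
    angle_left: float
    angle_right: float
    centers: tuple[tuple[float, float], tuple[float, float]]
    axes: tuple[tuple[float, float], tuple[float, float]]
    valid: bool = True
    # angles unwrapped over time (period pi) for jump-free logging
    unwrapped_left: float = float("nan")
    unwrapped_right: float = float("nan")


def segment_eyes(frame: Frame, roi: EyeROI) -> list[np.ndarray]:
    """Return the two largest 8-connected below-threshold components.

    Each component is an ``(n, 2)`` array of (x, y) pixel coordinates in
    full-frame coordinates, ordered left then right by projection onto the
    image x-axis.  Fewer than two components of ``min_area`` pixels yield an
    empty list (caller sets ``valid=False``).
    """
    roi.validate(frame.shape)
    x0, y0 = roi.origin_xy
    sub = np.asarray(frame.pixels)[y0 : y0 + roi.height, x0 : x0 + roi.width]
    mask = sub < roi.threshold
    labels = label(mask, connectivity=2)
    comps = []
    for region in regionprops(labels):
        if region.area >= roi.min_area:
            comps.append(region)
    if len(comps) < 2:
        return []
    comps.sort(key=lambda r: r.area, reverse=True)
    picked = comps[:2]
    out = []
    for region in picked:
        yx = region.coords  # (row, col)
        pts = np.stack([yx[:, 1] + x0, yx[:, 0] + y0], axis=1).astype(np.float64)
        out.append(pts)
    # left/right by centroid projection on the x-axis
    out.sort(key=lambda p: p[:, 0].mean())
    return out


def fit_ellipse(pixels: np.ndarray, prev_angle: float | None = None) -> EllipseFit:
    """Moment-based ellipse fit to a filled pixel set.

    Semi-axes come from the eigenvalues of the pixel covariance (a filled
    ellipse with semi-axes (a, b) has variances (a^2/4, b^2/4)); the angle is
    the principal-axis orientation folded to [0, pi).  Near-isotropic blobs
    are flagged degenerate and fall back to ``prev_angle`` (or 0).
    """
    pts = np.asarray(pixels, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 pixels to fit an ellipse")
    center = pts.mean(axis=0)
    d = pts - center
    # +1/12 per-pixel variance: treat each pixel as a unit square, which
    # unbiases axes estimated from coarse rasters
    cov = d.T @ d / len(pts) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    lam_minor, lam_major = float(evals[0]), float(evals[1])
    major = 2.0 * math.sqrt(max(lam_major, 0.0))
    minor = 2.0 * math.sqrt(max(lam_minor, 0.0))
    aniso = (lam_major - lam_minor) / max(lam_major, 1e-300)
    if aniso < CIRCULAR_EPS:
        angle = prev_angle % math.pi if prev_angle is not None else 0.0
        return EllipseFit(tuple(center), major, minor, angle, degenerate=True)
    vx, vy = evecs[:, 1]
    angle = math.atan2(vy, vx) % math.pi
    return EllipseFit(tuple(center), major, minor, angle, degenerate=False)


def _unwrap_pi(angle: float, prev_unwrapped: float) -> float:
    """Continue ``angle`` (defined mod pi) nearest to ``prev_unwrapped``."""
    k = round((prev_unwrapped - angle) / math.pi)
    return angle + k * math.pi


def track_eyes(frame: Frame, roi: EyeROI, prev: EyeState | None = None) -> EyeState:
    """Segment and fit both eyes; invalid frames propagate the previous
    angles with ``valid=False`` instead of raising."""
    comps = segment_eyes(frame, roi)
    if len(comps) < 2:
        if prev is not None:
            return EyeState(
                t=frame.t,
                angle_left=prev.angle_left,
                angle_right=prev.angle_right,
                centers=prev.centers,
                axes=prev.axes,
                valid=False,
                unwrapped_left=prev.unwrapped_left,
                unwrapped_right=prev.unwrapped_right,
            )
        nan = float("nan")
        return EyeState(
            t=frame.t, angle_left=nan, angle_right=nan,
            centers=((nan, nan), (nan, nan)), axes=((nan, nan), (nan, nan)),
            valid=False,
        )
    prev_angles = (prev.angle_left, prev.angle_right) if prev is not None else (None, None)
    fits = [fit_ellipse(c, pa) for c, pa in zip(comps, prev_angles)]
    left, right = fits
    if prev is not None and prev.valid and math.isfinite(prev.unwrapped_left):
        uw_l = _unwrap_pi(left.angle, prev.unwrapped_left)
        uw_r = _unwrap_pi(right.angle, prev.unwrapped_right)
    else:
        uw_l, uw_r = left.angle, right.angle
    return EyeState(
        t=frame.t,
        angle_left=left.angle,
        angle_right=right.angle,
        centers=(left.center, right.center),
        axes=((left.major, left.minor), (right.major, right.minor)),
        valid=True,
        unwrapped_left=uw_l,
        unwrapped_right=uw_r,
    )
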