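"""Frame representation, preprocessing and the slowly-updating background model.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are ``(x, y)`` = (column, row), 0-based, origin at the
  top-left corner of the image.
* Angles are measured in radians from the +x (column) axis; a direction
  ``theta`` corresponds to the unit vector ``(cos(theta), sin(theta))`` in
  (x, y) pixel coordinates.
* After preprocessing the internal convention is *bright fish on a dark
  background*; the ``invert`` flag of :class:`PreprocSpec` adapts sources
  recorded the other way round.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Frame",
    "PreprocSpec",
    "BackgroundModel",
    "preprocess",
    "update_background",
    "foreground",
]


@dataclass(frozen=True)
class Frame:
    """A single-channel intensity image with a timestamp.

    Parameters
    ----------
    pixels
        2-D array of intensities.  The nominal range (0-255 or 0-1) is
        carried in ``max_value`` so that inversion is well defined.
    t
        Acquisition time in seconds.
    frame_id
        Monotone frame counter within a sequence.
    max_value
        Upper bound of the intensity range (255.0 by default).
    """

    pixels: np.ndarray
    t: float = 0.0
    frame_id: int = 0
    max_value: float = 255.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("frame pixels must be a non-empty 2-D array")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PreprocSpec:
    """Preprocessing chain: invert, down-scale, blur, clip (in that order).

    ``clip_before_blur`` swaps the last two steps; the default order is
    blur-then-clip.  When ``downsample_factor`` does not divide the image
    size, trailing rows/columns are dropped.
    """

    invert: bool = False
    downsample_factor: int = 1
    blur_sigma: float = 0.0
    clip_level: float = 0.0
    clip_before_blur: bool = False

    def __post_init__(self) -> None:
        if self.downsample_factor < 1 or int(self.downsample_factor) != self.downsample_factor:
            raise ValueError("downsample_factor must be an integer >= 1")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            not self.invert
            and self.downsample_factor == 1
            and self.blur_sigma == 0
            and self.clip_level == 0
        )


def _block_downsample(px: np.ndarray, factor: int) -> np.ndarray:
    """Block-average downsampling; trailing rows/cols that do not fill a
    complete block are dropped."""
    if factor == 1:
        return px
    h, w = px.shape
    h2, w2 = h // factor, w // factor
    if h2 == 0 or w2 == 0:
        raise ValueError(
            f"downsample_factor {factor} larger than image dimensions {px.shape}"
        )
    trimmed = px[: h2 * factor, : w2 * factor]
    return trimmed.reshape(h2, factor, w2, factor).mean(axis=(1, 3))


def preprocess(frame: Frame, spec: PreprocSpec) -> Frame:
    """Apply the preprocessing chain to ``frame`` and return a new frame.

    The input frame is never modified.  With an identity spec the returned
    frame shares the input's pixel values bit-exactly.
    """
    if spec.is_identity:
        return replace(frame, pixels=frame.pixels.copy())

    px = np.asarray(frame.pixels, dtype=np.float64)
    if spec.invert:
        px = frame.max_value - px
    px = _block_downsample(px, spec.downsample_factor)

    def clip(a: np.ndarray) -> np.ndarray:
        return np.where(a < spec.clip_level, 0.0, a)

    if spec.clip_before_blur:
        px = clip(px)
        if spec.blur_sigma > 0:
            px = gaussian_filter(px, spec.blur_sigma)
    else:
        if spec.blur_sigma > 0:
            px = gaussian_filter(px, spec.blur_sigma)
        px = clip(px)
    return replace(frame, pixels=px)


@dataclass
class BackgroundModel:
    """Exponential-moving-average background used by freely-swimming tracking.

    For the first ``n_init_frames`` frames the model accumulates a plain
    running mean; afterwards each frame is blended in with
    ``alpha = dt / time_constant`` (clamped to [0, 1]) where ``dt`` is the
    difference between the current and the previous frame timestamps.
    """

    time_constant: float = 10.0
    n_init_frames: int = 10
    mean_image: np.ndarray | None = None
    _n_seen: int = field(default=0, repr=False)
    _last_t: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.time_constant <= 0:
            raise ValueError("time_constant must be > 0")
        if self.n_init_frames < 1:
            raise ValueError("n_init_frames must be >= 1")

    @property
    def initialized(self) -> bool:
        return self.mean_image is not None and self._n_seen >= self.n_init_frames


def update_background(model: BackgroundModel, frame: Frame) -> BackgroundModel:
    """Fold ``frame`` into the background model (in place) and return it."""
    px = np.asarray(frame.pixels, dtype=np.float64)
    if model.mean_image is None:
        model.mean_image = px.copy()
        model._n_seen = 1
        model._last_t = frame.t
        return model
    if model.mean_image.shape != px.shape:
        raise ValueError(
            f"frame shape {px.shape} does not match model {model.mean_image.shape}"
        )
    if model._n_seen < model.n_init_frames:
        n = model._n_seen
        model.mean_image = (model.mean_image * n + px) / (n + 1)
    else:
        dt = max(frame.t - model._last_t, 0.0)
        alpha = min(dt / model.time_constant, 1.0)
        model.mean_image = (1.0 - alpha) * model.mean_image + alpha * px
    model._n_seen += 1
    model._last_t = frame.t
    return model


def foreground(model: BackgroundModel, frame: Frame) -> Frame:
    """Difference image keeping only pixels darker than the background.

    ``out = max(mean_image - frame, 0)``; a fish darker than the arena shows
    up bright in the result.
    """
    if model.mean_image is None:
        raise ValueError("background model is not initialized")
    px = np.asarray(frame.pixels, dtype=np.float64)
    if model.mean_image.shape != px.shape:
        raise ValueError("frame shape does not match background model")
    return replace(frame, pixels=np.maximum(model.mean_image - px, 0.0))
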