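"""Frame sources: multipage TIFF stacks, video containers and directories of
numbered image files."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

from .imaging import Frame


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr.astype(np.float64)


def iter_frames(source: str | Path, fps: float | None = None) -> Iterator[Frame]:
    """Yield frames from a TIFF stack, a video file or a directory of
    numbered PNG/TIFF files.  Timestamps are synthesized at constant rate
    from ``fps`` (default 60) when the container carries none."""
    src = Path(source)
    fps = fps or 60.0
    if src.is_dir():
        files = sorted(
            p for p in src.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        import imageio.v3 as iio

        for i, p in enumerate(files):
            yield Frame(pixels=_to_gray(iio.imread(p)), t=i / fps, frame_id=i)
    elif src.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(src) as tf:
            for i, page in enumerate(tf.pages):
                yield Frame(pixels=_to_gray(page.asarray()), t=i / fps, frame_id=i)
    else:
        import imageio.v3 as iio

        for i, arr in enumerate(iio.imiter(src)):
            yield Frame(pixels=_to_gray(arr), t=i / fps, frame_id=i)


def write_tiff_stack(frames, path: str | Path) -> Path:
    """Write frames as an 8-bit multipage TIFF."""
    import tifffile

    path = Path(path)
    stack = np.stack([np.clip(f.pixels, 0, 255).astype(np.uint8) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path
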