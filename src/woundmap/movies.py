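"""Reading, writing and in-memory representation of time-lapse movies.

A movie is an ordered stack of same-shaped 2-D grayscale frames plus the two
pieces of acquisition metadata every downstream measurement needs: the pixel
size (µm per pixel) and the frame interval (minutes per frame).  Intensities
are held as floating point in [0, 1], normalized by a *per-movie* (not
per-frame) min-max so that texture codes and segmentation thresholds are
comparable across frames.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "MovieStack",
    "read_movie",
    "write_movie",
    "write_matrix",
    "read_matrix",
]


@dataclass
class MovieStack:
    """An ordered grayscale frame stack with acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``, floating point intensities in [0, 1].
    pixel_size_um
        Physical size of one pixel in µm (> 0).
    frame_interval_min
        Time between consecutive frames in minutes (> 0).
    name
        Identifier used in output file names and reports.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    name: str = "movie"

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"frames must be a (T, H, W) stack, got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValueError(f"a movie needs at least 2 frames, got {frames.shape[0]}")
        if not np.isfinite(frames).all():
            raise ValueError("frames contain non-finite intensities")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be finite and > 0, got {self.pixel_size_um}")
        if not (np.isfinite(self.frame_interval_min) and self.frame_interval_min > 0):
            raise ValueError(f"frame_interval_min must be finite and > 0, got {self.frame_interval_min}")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_interval_hr(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def duration_hr(self) -> float:
        """Elapsed time from the first to the last frame, in hours."""
        return (self.n_frames - 1) * self.frame_interval_hr

    def times_hr(self) -> np.ndarray:
        """Acquisition time of each frame in hours, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_hr

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[np.ndarray] | np.ndarray,
        pixel_size_um: float,
        frame_interval_min: float,
        name: str = "movie",
    ) -> "MovieStack":
        """Build a stack from raw-intensity frames, min-max scaling per movie.

        The scaling is monotone (pixel ordering is preserved) and shared by
        all frames; a constant movie maps to all-zeros.
        """
        stack = np.asarray([np.asarray(f, dtype=np.float64) for f in frames])
        if stack.ndim != 3:
            raise ValueError("all frames must be 2-D and share the same shape")
        lo, hi = float(stack.min()), float(stack.max())
        if hi > lo:
            stack = (stack - lo) / (hi - lo)
        else:
            stack = np.zeros_like(stack)
        return cls(stack, pixel_size_um, frame_interval_min, name)


def _read_image_gray(path: Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        raise ValueError(
            f"{path}: multi-channel image; this pipeline analyses a single "
            "bright-field channel — extract it before loading"
        )
    return np.asarray(img, dtype=np.float64)


def read_movie(
    path: str | os.PathLike,
    pixel_size_um: float,
    frame_interval_min: float,
    name: str | None = None,
) -> MovieStack:
    """Read a movie from a multi-page TIFF or a directory of per-frame images.

    Directory frames are ordered lexicographically by file name.  Arbitrary
    integer bit depths are accepted; intensities are min-max scaled to [0, 1]
    over the whole movie.  Multi-channel input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie path does not exist: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
        )
        if not files:
            raise ValueError(f"no image files found in directory {path}")
        frames = [_read_image_gray(p) for p in files]
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"{path}: expected a stack of 2-D grayscale pages, got shape {stack.shape}")
        frames = list(np.asarray(stack, dtype=np.float64))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")
    return MovieStack.from_frames(
        frames, pixel_size_um, frame_interval_min, name=name or path.stem
    )


def write_movie(movie: MovieStack, path: str | os.PathLike) -> None:
    """Write a movie as a 16-bit multi-page TIFF.

    Intensities in [0, 1] are scaled to the full 16-bit range, so a
    ``write_movie``/``read_movie`` round trip reproduces the stack to
    16-bit quantization (~1.5e-5 in normalized units).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(movie.frames, 0.0, 1.0)
    tifffile.imwrite(path, np.round(data * 65535.0).astype(np.uint16))


def write_matrix(
    matrix: np.ndarray,
    path: str | os.PathLike,
    row_labels: Sequence | None = None,
    col_labels: Sequence | None = None,
) -> None:
    """Write a 2-D real matrix as labeled CSV, lossless to ≥ 6 significant digits.

    NaN-masked matrices are not accepted here: non-finite entries are rejected
    with the offending ``(row, col)`` indices so silent gaps cannot propagate
    into reports.  Use an explicit validity mask alongside the matrix instead.
    """
    import pandas as pd

    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {matrix.shape}")
    bad = np.argwhere(~np.isfinite(matrix))
    if bad.size:
        locs = ", ".join(f"({r}, {c})" for r, c in bad[:20])
        more = "" if len(bad) <= 20 else f" and {len(bad) - 20} more"
        raise ValueError(f"matrix has non-finite entries at {locs}{more}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if row_labels is None:
        row_labels = list(range(matrix.shape[0]))
    if col_labels is None:
        col_labels = list(range(matrix.shape[1]))
    df = pd.DataFrame(matrix, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, float_format="%.12g")


def read_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list, list]:
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(matrix, row_labels, col_labels)``.
    """
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), list(df.index), list(df.columns)
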