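"""Rotation-invariant uniform local binary patterns over cellular pixels.

Each pixel is compared with its 8 neighbors on the unit-radius ring
(axis-aligned neighbors read directly, diagonal ones sampled by bilinear
interpolation at radius 1).  A neighbor at least as bright as the center
contributes a 1-bit.  Patterns with at most two circular 0/1 transitions
("uniform" patterns — there are 58 of them) are coded by their number of
ones (0–8); all other patterns share code 9, for exactly ten possible codes.
The normalized 10-bin histogram of codes over all cellular pixels is a
grayscale-invariant, rotation-invariant implicit descriptor of multi-cellular
morphology; its per-frame series summarizes a whole movie, and the mean
histogram over the contact-to-closure phase is the texture descriptor used
for treatment classification.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from woundmap.movies import MovieStack
from woundmap.strips import PhasePartition

__all__ = [
    "N_CODES",
    "lbp_code",
    "lbp_codes_image",
    "lbp_histogram",
    "lbp_histogram_series",
    "phase_texture_descriptor",
]

N_CODES = 10


def _transitions(pattern: int) -> int:
    """Number of 0/1 transitions in the circular 8-bit pattern."""
    bits = [(pattern >> i) & 1 for i in range(8)]
    return sum(bits[i] != bits[(i + 1) % 8] for i in range(8))


def _build_lut() -> np.ndarray:
    lut = np.empty(256, dtype=np.uint8)
    for pat in range(256):
        if _transitions(pat) <= 2:
            lut[pat] = bin(pat).count("1")
        else:
            lut[pat] = 9
    return lut


_LUT = _build_lut()


def lbp_code(center: float, neighbors: Sequence[float]) -> int:
    """Code in {0..9} for one pixel given its 8 ring neighbors in circular order.

    ``neighbors[i] >= center`` sets bit i (ties count as brighter, so constant
    regions map to code 8).  Uniform patterns (≤ 2 circular transitions) are
    coded by their number of set bits; the rest collapse to code 9.
    """
    neighbors = np.asarray(neighbors, dtype=np.float64)
    if neighbors.shape != (8,):
        raise ValueError("exactly 8 neighbors required")
    pattern = 0
    for i, nb in enumerate(neighbors):
        if nb >= center:
            pattern |= 1 << i
    return int(_LUT[pattern])


def lbp_codes_image(frame: np.ndarray) -> np.ndarray:
    """Per-pixel LBP codes for the interior of a frame, shape (H-2, W-2).

    Border pixels lack a full neighborhood and are excluded.  Diagonal
    neighbors are sampled at exact radius 1 by bilinear interpolation.
    """
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2 or min(f.shape) < 3:
        raise ValueError("frame must be 2-D and at least 3x3")
    c = f[1:-1, 1:-1]
    e = f[1:-1, 2:]
    n = f[:-2, 1:-1]
    w = f[1:-1, :-2]
    s = f[2:, 1:-1]
    g = 1.0 / np.sqrt(2.0)
    a, b = (1.0 - g) * (1.0 - g), (1.0 - g) * g
    d = g * g
    # bilinear samples at the four diagonal ring positions (radius exactly 1)
    ne = a * c + b * (n + e) + d * f[:-2, 2:]
    nw = a * c + b * (n + w) + d * f[:-2, :-2]
    sw = a * c + b * (s + w) + d * f[2:, :-2]
    se = a * c + b * (s + e) + d * f[2:, 2:]
    pattern = np.zeros(c.shape, dtype=np.uint8)
    for i, nb in enumerate((e, ne, n, nw, w, sw, s, se)):
        pattern |= ((nb >= c).astype(np.uint8)) << i
    return _LUT[pattern]


def lbp_histogram(frame: np.ndarray, cellular_mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized 10-bin code histogram over cellular pixels.

    An empty mask yields an all-NaN histogram (undefined, flagged by a
    warning) rather than zeros — a missing observation, not a uniform one.
    """
    codes = lbp_codes_image(frame)
    if cellular_mask is not None:
        interior = np.asarray(cellular_mask, dtype=bool)[1:-1, 1:-1]
        codes = codes[interior]
    codes = codes.ravel()
    if codes.size == 0:
        warnings.warn("no cellular pixels; LBP histogram undefined")
        return np.full(N_CODES, np.nan)
    counts = np.bincount(codes, minlength=N_CODES).astype(np.float64)
    return counts / counts.sum()


def lbp_histogram_series(movie: MovieStack, cellular_masks: np.ndarray | None = None) -> np.ndarray:
    """Histogram per frame, shape (T, 10); rows of empty frames are NaN."""
    out = np.empty((movie.n_frames, N_CODES))
    for t in range(movie.n_frames):
        mask = cellular_masks[t] if cellular_masks is not None else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[t] = lbp_histogram(movie.frames[t], mask)
    return out


def phase_texture_descriptor(H: np.ndarray, phases: PhasePartition, phase: int = 2) -> np.ndarray:
    """Mean LBP histogram over the frames of one healing phase.

    The default (phase 2, first contact to full closure) is the texture
    descriptor used for treatment classification; it still sums to 1.
    """
    H = np.asarray(H, dtype=np.float64)
    if phases.t_contact is None or phases.t_closure is None:
        raise ValueError(
            "phase boundaries undefined for this movie; supply manual phase "
            "frames (PhasePartition) to compute a phase texture descriptor"
        )
    window = phases.window(phase, H.shape[0])
    rows = H[window.start : window.stop]
    rows = rows[np.isfinite(rows).all(axis=1)]
    if rows.size == 0:
        raise ValueError(f"phase {phase} contains no frames with a defined histogram")
    return rows.mean(axis=0)
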