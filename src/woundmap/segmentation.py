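"""Cellular / background segmentation and wound-mask extraction.

Bright-field monolayers carry high intra-cellular texture while the wound
(void) region is nearly uniform, so a local-variance threshold separates the
two.  The segmenter computes a sliding-window variance image, thresholds it
(Otsu by default), then cleans the mask by morphological closing, removal of
small components and filling of small holes.  The wound is the background
component(s) overlapping the initial scratch, tracked across frames by
overlap with the previous wound so fragmentation after first contact does
not re-label noise.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from woundmap.config import RunConfig
from woundmap.movies import MovieStack

__all__ = [
    "local_variance",
    "segment_frame",
    "segment_movie",
    "extract_wound",
    "wound_masks",
]


def local_variance(frame: np.ndarray, window_px: int) -> np.ndarray:
    """Sliding-window intensity variance (uniform window, reflected borders)."""
    frame = np.asarray(frame, dtype=np.float64)
    mean = ndimage.uniform_filter(frame, size=window_px, mode="reflect")
    mean_sq = ndimage.uniform_filter(frame * frame, size=window_px, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def _otsu_variance_threshold(var: np.ndarray) -> float:
    """Automatic cut on a local-variance image.

    Otsu is run on log-variance: texture variance within the monolayer spans
    an order of magnitude, and in linear units Otsu splits the cellular class
    itself instead of separating it from the near-zero-variance wound.
    """
    return float(10.0 ** threshold_otsu(np.log10(var + 1e-12)))


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.concatenate([[False], sizes >= min_px])
    return keep[labels]


def segment_frame(
    frame: np.ndarray,
    window_px: int = 5,
    variance_threshold: float | None = None,
    min_object_px: int = 64,
) -> np.ndarray:
    """Partition one frame into cellular (True) and background (False).

    ``variance_threshold`` fixes the cut on the local-variance image; ``None``
    selects it automatically (Otsu on log-variance).  The thresholded mask is
    cleaned by binary closing, removal of components smaller than one patch
    area and filling of equally small holes.  A constant frame (no texture
    anywhere) yields an all-background mask with a warning rather than an
    error.  Deterministic, and invariant to affine intensity flips of the
    input (variance is).
    """
    var = local_variance(frame, window_px)
    if variance_threshold is None:
        if np.ptp(var) <= 1e-15:
            warnings.warn("frame has uniform local variance; returning all-background mask")
            return np.zeros(frame.shape, dtype=bool)
        variance_threshold = _otsu_variance_threshold(var)
    mask = var > variance_threshold
    if not mask.any():
        warnings.warn("no cellular pixels above the variance threshold")
        return mask
    it = max(window_px // 2, 1)
    # pad with edge values so closing/erosion do not eat the image border
    padded = np.pad(mask, 2 * it, mode="edge")
    padded = ndimage.binary_closing(padded, structure=np.ones((3, 3), dtype=bool), iterations=it)
    # the sliding variance window spreads cellular texture ~window/2 into the
    # background, biasing the cellular boundary outward; erode it back
    padded = ndimage.binary_erosion(padded, structure=np.ones((3, 3), dtype=bool), iterations=it)
    mask = padded[2 * it : -2 * it, 2 * it : -2 * it]
    mask = _drop_small(mask, min_object_px)
    holes = _drop_small(~mask, min_object_px)  # background kept; small holes filled
    return ~holes


def segment_movie(movie: MovieStack, config: RunConfig) -> np.ndarray:
    """Per-frame cellular masks, shape ``(T, H, W)`` bool.

    The variance threshold is selected once per movie — Otsu on the first
    frame's variance image, where a wound is guaranteed to be present — and
    applied to all frames.  A per-frame Otsu would hallucinate a background
    class in fully-healed frames that contain no wound at all; a fixed
    per-movie cut keeps post-closure frames all-cellular.  Override with
    ``config.seg_variance_threshold``.
    """
    window = config.seg_window_px(movie.pixel_size_um)
    patch_px = config.patch_size_px(movie.pixel_size_um)
    min_object = patch_px * patch_px
    thr = config.seg_variance_threshold
    if thr is None:
        var0 = local_variance(movie.frames[0], window)
        if np.ptp(var0) <= 1e-15:
            warnings.warn("first frame has uniform local variance; all-background masks")
            return np.zeros(movie.frames.shape, dtype=bool)
        thr = _otsu_variance_threshold(var0)
    masks = np.empty(movie.frames.shape, dtype=bool)
    for t in range(movie.n_frames):
        masks[t] = segment_frame(movie.frames[t], window, thr, min_object)
    return masks


def extract_wound(
    cellular_mask: np.ndarray,
    prior_wound: np.ndarray | None = None,
    min_area_px: int = 64,
) -> np.ndarray:
    """Wound mask from a cellular mask.

    Background components smaller than ``min_area_px`` (one patch area) are
    intra-monolayer holes, not wound.  With no prior, the wound is the
    largest remaining background component (frame 0: the scratch); with a
    prior, it is the union of components overlapping the previous wound, so
    the wound keeps its identity as it fragments near closure.  An empty
    wound (post-closure) is a valid result.
    """
    background = ~np.asarray(cellular_mask, dtype=bool)
    labels, n = ndimage.label(background)  # 4-connectivity for the void region
    if n == 0:
        return np.zeros_like(background)
    sizes = ndimage.sum_labels(background, labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    if prior_wound is None:
        big = np.argmax(sizes) + 1
        if sizes[big - 1] >= min_area_px:
            keep[big] = True
    else:
        overlap = np.unique(labels[np.asarray(prior_wound, dtype=bool)])
        for lab in overlap:
            if lab > 0 and sizes[lab - 1] >= min_area_px:
                keep[lab] = True
    return keep[labels]


def wound_masks(
    cellular_masks: np.ndarray,
    min_area_px: int = 64,
) -> np.ndarray:
    """Track the wound across a movie's cellular masks, shape ``(T, H, W)``."""
    cellular_masks = np.asarray(cellular_masks, dtype=bool)
    out = np.empty_like(cellular_masks)
    prior: np.ndarray | None = None
    for t in range(cellular_masks.shape[0]):
        out[t] = extract_wound(cellular_masks[t], prior, min_area_px)
        if out[t].any():
            prior = out[t]
    return out
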