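"""Patch-level motion estimation by normalized-cross-correlation block matching.

The frame is tiled into square sub-cellular patches (~18.5 µm a side at the
reference magnification).  Each patch of frame ``t`` is matched against a
search window in frame ``t+1``; the displacement is the NCC arg-max, refined
to sub-pixel precision by 1-D parabolic fits along each axis, and converted
to µm/hour.  Patches that are not cellular, nearly textureless, poorly
matched or whose search window leaves the frame are flagged invalid.

NCC makes the estimate invariant to affine intensity changes with positive
scale applied to either frame, which is what makes bright-field texture
usable without any photometric calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from woundmap.config import RunConfig
from woundmap.movies import MovieStack

__all__ = ["PatchGrid", "VelocityField", "estimate_field", "estimate_movie_fields",
           "toward_wound_components"]


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping tiling of a frame into square patches."""

    patch_size_px: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.patch_size_px < 8:
            raise ValueError(f"patch_size_px must be >= 8, got {self.patch_size_px}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("frame too small for a single patch")

    @classmethod
    def for_frame(cls, frame_shape: tuple[int, int], patch_size_px: int) -> "PatchGrid":
        h, w = frame_shape
        return cls(patch_size_px, h // patch_size_px, w // patch_size_px)

    def centers_px(self) -> tuple[np.ndarray, np.ndarray]:
        """Patch-center coordinates (rows, cols) in pixels, each shape (n_rows, n_cols)."""
        p = self.patch_size_px
        r = np.arange(self.n_rows) * p + (p - 1) / 2.0
        c = np.arange(self.n_cols) * p + (p - 1) / 2.0
        return np.meshgrid(r, c, indexing="ij")


@dataclass
class VelocityField:
    """Per-patch velocities for one frame pair, µm/hour on image axes.

    ``v_row``/``v_col`` are the displacement components along image rows and
    columns.  After :func:`toward_wound_components`, ``v_toward`` is the
    component toward the wound (positive = approaching) and ``v_parallel``
    the signed component along the wound edge; their squared sum equals the
    original squared speed wherever both are defined.
    """

    grid: PatchGrid
    v_row: np.ndarray
    v_col: np.ndarray
    valid: np.ndarray
    score: np.ndarray
    v_toward: Optional[np.ndarray] = None
    v_parallel: Optional[np.ndarray] = None

    def speed(self) -> np.ndarray:
        """Per-patch speed magnitude (µm/hr); NaN where invalid."""
        s = np.hypot(self.v_row, self.v_col)
        return np.where(self.valid, s, np.nan)


def _patch_view(frame: np.ndarray, grid: PatchGrid) -> np.ndarray:
    p = grid.patch_size_px
    sub = frame[: grid.n_rows * p, : grid.n_cols * p]
    return (
        sub.reshape(grid.n_rows, p, grid.n_cols, p)
        .transpose(0, 2, 1, 3)
        .reshape(grid.n_rows, grid.n_cols, p * p)
    )


def _parabolic_offset(s_minus: np.ndarray, s0: np.ndarray, s_plus: np.ndarray) -> np.ndarray:
    denom = s_minus - 2.0 * s0 + s_plus
    with np.errstate(divide="ignore", invalid="ignore"):
        off = 0.5 * (s_minus - s_plus) / denom
    off = np.where(np.isfinite(off) & (denom < 0), off, 0.0)
    return np.clip(off, -0.5, 0.5)


def estimate_field(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    grid: PatchGrid,
    search_radius_px: int,
    pixel_size_um: float,
    frame_interval_min: float,
    cellular_mask: np.ndarray | None = None,
    min_ncc: float = 0.5,
    variance_floor: float = 0.0,
) -> VelocityField:
    """Block-matching velocity field between two consecutive frames.

    For each patch the displacement maximizing the NCC against the ``t+1``
    search window is found (ties broken toward the smallest displacement
    magnitude, a bias to stillness), refined by a parabolic fit, and scaled
    to µm/hr.  Patches are invalid when their center is non-cellular, their
    variance is below ``variance_floor``, their best NCC is below
    ``min_ncc``, or the search window leaves the frame (border patches).
    """
    if frame_t.shape != frame_t1.shape:
        raise ValueError("consecutive frames must share a shape")
    if search_radius_px < 1:
        raise ValueError("search_radius_px must be >= 1")
    r = int(search_radius_px)
    p = grid.patch_size_px
    H, W = frame_t.shape
    n_pix = p * p

    A = _patch_view(np.asarray(frame_t, dtype=np.float64), grid)
    a_mean = A.mean(axis=2, keepdims=True)
    A0 = A - a_mean
    a_var = (A0 * A0).sum(axis=2) / n_pix
    a_norm = np.sqrt((A0 * A0).sum(axis=2))

    padded = np.full((H + 2 * r, W + 2 * r), np.nan)
    padded[r : r + H, r : r + W] = frame_t1

    # shifts ordered by (magnitude, row, col): the first arg-max wins ties,
    # so equal scores resolve toward the smallest displacement
    shifts = sorted(
        ((u, v) for u in range(-r, r + 1) for v in range(-r, r + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]),
    )
    n_shifts = len(shifts)
    scores = np.full((grid.n_rows, grid.n_cols, n_shifts), -np.inf)
    usable = np.zeros((grid.n_rows, grid.n_cols, n_shifts), dtype=bool)
    for k, (u, v) in enumerate(shifts):
        Bfull = padded[r + u : r + u + grid.n_rows * p, r + v : r + v + grid.n_cols * p]
        B = (
            Bfull.reshape(grid.n_rows, p, grid.n_cols, p)
            .transpose(0, 2, 1, 3)
            .reshape(grid.n_rows, grid.n_cols, n_pix)
        )
        ok = ~np.isnan(B).any(axis=2)
        B = np.nan_to_num(B)
        B0 = B - B.mean(axis=2, keepdims=True)
        b_norm = np.sqrt((B0 * B0).sum(axis=2))
        denom = a_norm * b_norm
        with np.errstate(divide="ignore", invalid="ignore"):
            ncc = (A0 * B0).sum(axis=2) / denom
        good = ok & (denom > 1e-12)
        scores[:, :, k] = np.where(good, ncc, -np.inf)
        usable[:, :, k] = good

    best_k = np.argmax(scores, axis=2)
    best_score = np.take_along_axis(scores, best_k[..., None], axis=2)[..., 0]

    shift_arr = np.asarray(shifts)  # (n_shifts, 2)
    du = shift_arr[best_k, 0].astype(np.float64)
    dv = shift_arr[best_k, 1].astype(np.float64)

    # sub-pixel refinement: look up neighbors of the best shift in shift space
    shift_index = {s: k for k, s in enumerate(shifts)}
    idx = np.full((2 * r + 1, 2 * r + 1), -1, dtype=int)
    for (u, v), k in shift_index.items():
        idx[u + r, v + r] = k

    iu = du.astype(int) + r
    iv = dv.astype(int) + r

    def _neighbor_score(ou: int, ov: int) -> np.ndarray:
        nu, nv = iu + ou, iv + ov
        inb = (nu >= 0) & (nu <= 2 * r) & (nv >= 0) & (nv <= 2 * r)
        k = np.where(inb, idx[np.clip(nu, 0, 2 * r), np.clip(nv, 0, 2 * r)], 0)
        s = np.take_along_axis(scores, k[..., None], axis=2)[..., 0]
        return np.where(inb, s, -np.inf)

    # a perfect correlation is already an exact match; the parabola can only
    # move the peak off the sample, so skip refinement there
    sharp = np.isfinite(best_score) & (best_score < 1.0 - 1e-9)
    s_um = _neighbor_score(-1, 0)
    s_up = _neighbor_score(1, 0)
    refinable = np.isfinite(s_um) & np.isfinite(s_up) & sharp
    du = du + np.where(refinable, _parabolic_offset(s_um, best_score, s_up), 0.0)
    s_vm = _neighbor_score(0, -1)
    s_vp = _neighbor_score(0, 1)
    refinable = np.isfinite(s_vm) & np.isfinite(s_vp) & sharp
    dv = dv + np.where(refinable, _parabolic_offset(s_vm, best_score, s_vp), 0.0)

    valid = (
        np.isfinite(best_score)
        & (best_score >= min_ncc)
        & (a_var >= variance_floor)
        & np.take_along_axis(usable, best_k[..., None], axis=2)[..., 0]
    )
    if cellular_mask is not None:
        rr, cc = grid.centers_px()
        centers_cellular = np.asarray(cellular_mask, dtype=bool)[
            np.round(rr).astype(int), np.round(cc).astype(int)
        ]
        valid &= centers_cellular

    scale = pixel_size_um * 60.0 / frame_interval_min  # px/frame -> µm/hr
    v_row = np.where(valid, du * scale, np.nan)
    v_col = np.where(valid, dv * scale, np.nan)
    score_out = np.where(np.isfinite(best_score), best_score, np.nan)
    return VelocityField(grid, v_row, v_col, valid, score_out)


def movie_variance_floor(movie: MovieStack, grid: PatchGrid, frac: float) -> float:
    """Variance floor: ``frac`` × the movie's median patch variance."""
    variances = []
    step = max(movie.n_frames // 10, 1)
    for t in range(0, movie.n_frames, step):
        A = _patch_view(movie.frames[t], grid)
        variances.append(A.var(axis=2).ravel())
    return frac * float(np.median(np.concatenate(variances)))


def estimate_movie_fields(
    movie: MovieStack,
    cellular_masks: np.ndarray | None,
    config: RunConfig,
    search_radius_px: int | None = None,
) -> list[VelocityField]:
    """Velocity fields for all consecutive frame pairs of a movie."""
    patch_px = config.patch_size_px(movie.pixel_size_um)
    grid = PatchGrid.for_frame(movie.frame_shape, patch_px)
    if search_radius_px is None:
        if config.search_radius_um is not None:
            search_radius_px = max(int(np.ceil(config.search_radius_um / movie.pixel_size_um)), 1)
        else:
            search_radius_px = 5
    floor = movie_variance_floor(movie, grid, config.variance_floor_frac)
    fields = []
    for t in range(movie.n_frames - 1):
        mask = cellular_masks[t] if cellular_masks is not None else None
        fields.append(
            estimate_field(
                movie.frames[t],
                movie.frames[t + 1],
                grid,
                search_radius_px,
                movie.pixel_size_um,
                movie.frame_interval_min,
                cellular_mask=mask,
                min_ncc=config.min_ncc,
                variance_floor=floor,
            )
        )
    return fields


def toward_wound_components(field: VelocityField, distance_map_um: np.ndarray,
                            pixel_size_um: float) -> VelocityField:
    """Decompose a field into toward-wound and parallel components.

    The toward-wound direction at a patch center is the negative gradient of
    the distance-from-wound map (down-gradient = approaching the wound), so
    ``v_toward > 0`` means motion toward the wound.  Patches sitting on a
    distance plateau (``|∇D| ≈ 0``, e.g. the ridge equidistant from two
    fronts) have no defined direction and are flagged invalid.  The magnitude
    is preserved: ``v_toward² + v_parallel² = v_row² + v_col²``.
    """
    gr, gc = np.gradient(np.asarray(distance_map_um, dtype=np.float64), pixel_size_um)
    rr, cc = field.grid.centers_px()
    ri = np.round(rr).astype(int)
    ci = np.round(cc).astype(int)
    g_r = gr[ri, ci]
    g_c = gc[ri, ci]
    norm = np.hypot(g_r, g_c)
    defined = norm > 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        ur = g_r / norm
        uc = g_c / norm
    v_toward = -(field.v_row * ur + field.v_col * uc)
    v_parallel = field.v_row * (-uc) + field.v_col * ur
    valid = field.valid & defined
    v_toward = np.where(valid, v_toward, np.nan)
    v_parallel = np.where(valid, v_parallel, np.nan)
    return replace(field, valid=valid, v_toward=v_toward, v_parallel=v_parallel)
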