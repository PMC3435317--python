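"""Distance strips, velocity magnitude maps, healing phases and average-cell
displacement analysis.

The central representation is the velocity magnitude map ``M[t, d]``: the
mean speed of all cellular material at distance-bin ``d`` from the wound edge
at time ``t``.  Distances come from a Euclidean distance transform of the
wound region; each valid motion patch contributes its speed to the bin of
its center.  The healing process is partitioned into three phases — scratch
to first contact of the opposing fronts, contact to full closure, and post
closure — and "average cells" anchored at chosen starting distances are
tracked by accumulating the strip-mean toward-wound velocity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from woundmap.config import RunConfig
from woundmap.motion import VelocityField

__all__ = [
    "DistanceMap",
    "distance_map",
    "movie_distance_maps",
    "VelocityMagnitudeMap",
    "build_velocity_map",
    "PhasePartition",
    "detect_phases",
    "DisplacementSeries",
    "average_cell_displacement",
    "velocity_toward_profile",
]


@dataclass
class DistanceMap:
    """Euclidean distance (µm) from each pixel to the nearest wound pixel.

    ``dist_um`` is defined over the whole raster (zero inside the wound) so
    gradients are well-behaved near the edge; measurements only ever read it
    on cellular pixels.  ``defined`` is False for frames where no wound
    exists (post-closure) and the map is a frozen copy of the last real one.
    """

    dist_um: np.ndarray
    cellular: np.ndarray
    defined: bool = True


def distance_map(cellular_mask: np.ndarray, wound_mask: np.ndarray,
                 pixel_size_um: float) -> DistanceMap:
    """Exact Euclidean distance transform from the wound region, in µm."""
    wound_mask = np.asarray(wound_mask, dtype=bool)
    cellular_mask = np.asarray(cellular_mask, dtype=bool)
    if not wound_mask.any():
        return DistanceMap(np.zeros(wound_mask.shape), cellular_mask, defined=False)
    dist = ndimage.distance_transform_edt(~wound_mask, sampling=pixel_size_um)
    return DistanceMap(dist, cellular_mask, defined=True)


def movie_distance_maps(
    cellular_masks: np.ndarray,
    wound_mask_stack: np.ndarray,
    pixel_size_um: float,
) -> list[DistanceMap]:
    """Per-frame distance maps; after closure the last defined map is frozen.

    Post-closure frames have no wound, yet speeds there are still reported by
    distance from the healed seam, so the final pre-closure geometry carries
    forward (flagged ``defined=False``).
    """
    maps: list[DistanceMap] = []
    last: DistanceMap | None = None
    for t in range(cellular_masks.shape[0]):
        m = distance_map(cellular_masks[t], wound_mask_stack[t], pixel_size_um)
        if not m.defined and last is not None:
            m = DistanceMap(last.dist_um, cellular_masks[t], defined=False)
        maps.append(m)
        if m.defined:
            last = m
    return maps


@dataclass
class VelocityMagnitudeMap:
    """``M[t, d]`` speed matrix (µm/hr) with per-bin patch counts.

    Bins with no contributing patches are NaN (missing, not zero).  Row ``t``
    describes motion between frames ``t`` and ``t+1``; column ``d`` covers
    distances ``[d·w, (d+1)·w)`` for strip width ``w``.
    """

    M: np.ndarray
    counts: np.ndarray
    strip_width_um: float
    frame_interval_min: float

    @property
    def n_frames(self) -> int:
        return self.M.shape[0]

    @property
    def n_bins(self) -> int:
        return self.M.shape[1]

    def bin_centers_um(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.strip_width_um


def _patch_bins(field: VelocityField, dmap: DistanceMap, strip_width_um: float,
                n_bins: int) -> np.ndarray:
    """Distance-bin index per patch (−1 where out of range or non-cellular)."""
    rr, cc = field.grid.centers_px()
    ri, ci = np.round(rr).astype(int), np.round(cc).astype(int)
    d = dmap.dist_um[ri, ci]
    cellular = dmap.cellular[ri, ci]
    bins = np.floor(d / strip_width_um).astype(int)
    bins[(bins >= n_bins) | ~cellular] = -1
    return bins


def _binned_mean(values: np.ndarray, bins: np.ndarray, valid: np.ndarray,
                 n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    ok = valid & (bins >= 0) & np.isfinite(values)
    sums = np.bincount(bins[ok], weights=values[ok], minlength=n_bins)[:n_bins]
    cnt = np.bincount(bins[ok], minlength=n_bins)[:n_bins]
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
    return mean, cnt


def build_velocity_map(
    fields: Sequence[VelocityField],
    dmaps: Sequence[DistanceMap],
    strip_width_um: float,
    max_distance_um: float,
    frame_interval_min: float,
) -> VelocityMagnitudeMap:
    """Assemble the velocity magnitude map from per-frame fields and distances.

    Each valid patch contributes its speed magnitude ``√(v_row² + v_col²)``
    to the strip containing its center.  Frames without any valid patch
    produce an all-NaN row with a warning.
    """
    n_bins = int(math.ceil(max_distance_um / strip_width_um))
    T = len(fields)
    M = np.full((T, n_bins), np.nan)
    counts = np.zeros((T, n_bins), dtype=np.int64)
    for t, (field, dmap) in enumerate(zip(fields, dmaps)):
        bins = _patch_bins(field, dmap, strip_width_um, n_bins)
        speeds = np.hypot(np.nan_to_num(field.v_row), np.nan_to_num(field.v_col))
        M[t], counts[t] = _binned_mean(speeds, bins, field.valid, n_bins)
        if not field.valid.any():
            warnings.warn(f"frame {t}: no valid patches; map column missing")
    return VelocityMagnitudeMap(M, counts, strip_width_um, frame_interval_min)


@dataclass
class PhasePartition:
    """Healing-phase boundaries in frame indices.

    Phase 1 = frames ``[0, t_contact)``, Phase 2 = ``[t_contact, t_closure)``,
    Phase 3 = ``[t_closure, T)``.  Either boundary may be None when the wound
    never reaches that milestone.
    """

    t_contact: Optional[int]
    t_closure: Optional[int]

    def __post_init__(self) -> None:
        if self.t_contact is not None and self.t_closure is not None:
            if not 0 <= self.t_contact <= self.t_closure:
                raise ValueError(
                    f"need 0 <= t_contact <= t_closure, got {self.t_contact}, {self.t_closure}"
                )

    def phase_of_frame(self, t: int) -> int:
        if self.t_contact is None or t < self.t_contact:
            return 1
        if self.t_closure is None or t < self.t_closure:
            return 2
        return 3

    def window(self, phase: int, n_frames: int) -> range:
        """Frame range of a phase; raises if its boundaries are undefined."""
        if phase == 1:
            if self.t_contact is None:
                raise ValueError("t_contact undefined; Phase 1 has no end")
            return range(0, self.t_contact)
        if phase == 2:
            if self.t_contact is None or self.t_closure is None:
                raise ValueError("Phase 2 boundaries undefined")
            return range(self.t_contact, self.t_closure)
        if phase == 3:
            if self.t_closure is None:
                raise ValueError("t_closure undefined; Phase 3 never starts")
            return range(self.t_closure, n_frames)
        raise ValueError(f"phase must be 1, 2 or 3, got {phase}")


def _fronts_connected(cellular: np.ndarray) -> bool:
    """True when a cellular 8-connected path links the left and right image
    borders (the two monolayer fronts are in contact)."""
    labels, n = ndimage.label(cellular, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return False
    left = np.unique(labels[:, 0])
    right = np.unique(labels[:, -1])
    return bool(np.intersect1d(left[left > 0], right[right > 0]).size)


def detect_phases(
    wound_mask_stack: np.ndarray,
    closure_area_fraction: float = 0.01,
    cellular_masks: np.ndarray | None = None,
) -> PhasePartition:
    """Detect first contact and full closure from per-frame wound masks.

    First contact: the first frame where the wound no longer separates the
    two monolayer fronts, i.e. a cellular 8-connected path crosses between
    the image borders flanking the scratch (the wound itself is treated
    4-connected).  Full closure: the first frame whose wound area falls below
    ``closure_area_fraction`` of the frame-0 area.  A movie that starts
    already closed gets ``t_contact = t_closure = 0``; a wound that never
    shrinks leaves both undefined.
    """
    wound_mask_stack = np.asarray(wound_mask_stack, dtype=bool)
    T = wound_mask_stack.shape[0]
    areas = wound_mask_stack.reshape(T, -1).sum(axis=1)
    if areas[0] == 0:
        return PhasePartition(0, 0)
    t_closure = None
    below = np.nonzero(areas < closure_area_fraction * areas[0])[0]
    if below.size:
        t_closure = int(below[0])
    t_contact = None
    for t in range(T):
        cellular = cellular_masks[t] if cellular_masks is not None else ~wound_mask_stack[t]
        if _fronts_connected(cellular):
            t_contact = t
            break
    if t_contact is None and t_closure is not None:
        t_contact = t_closure
    if t_contact is not None and t_closure is not None:
        t_contact = min(t_contact, t_closure)
    return PhasePartition(t_contact, t_closure)


@dataclass
class DisplacementSeries:
    """Cumulative toward-wound displacement R(t) per anchor distance.

    ``R[k, t]`` is the distance (µm) the "average cell" anchored
    ``anchors_um[k]`` from the wound edge has travelled toward the wound by
    frame ``t``; ``R[:, 0] = 0``.
    """

    anchors_um: np.ndarray
    times_hr: np.ndarray
    R: np.ndarray


def _toward_bin_means(
    toward_fields: Sequence[VelocityField],
    dmaps: Sequence[DistanceMap],
    strip_width_um: float,
    n_bins: int,
) -> np.ndarray:
    """Strip-mean toward-wound velocity, shape (T-1, n_bins), NaN if empty."""
    out = np.full((len(toward_fields), n_bins), np.nan)
    for t, (field, dmap) in enumerate(zip(toward_fields, dmaps)):
        if field.v_toward is None:
            raise ValueError("fields must carry toward-wound components")
        bins = _patch_bins(field, dmap, strip_width_um, n_bins)
        out[t], _ = _binned_mean(np.nan_to_num(field.v_toward), bins, field.valid, n_bins)
    return out


def _nearest_defined(row: np.ndarray, b: int) -> float:
    if np.isfinite(row[b]):
        return float(row[b])
    defined = np.nonzero(np.isfinite(row))[0]
    if defined.size == 0:
        return 0.0
    return float(row[defined[np.argmin(np.abs(defined - b))]])


def average_cell_displacement(
    toward_fields: Sequence[VelocityField],
    dmaps: Sequence[DistanceMap],
    anchors_um: Sequence[float],
    phases: PhasePartition,
    strip_width_um: float,
    max_distance_um: float,
    frame_interval_min: float,
    mode: str = "advect",
) -> DisplacementSeries:
    """Track "average cells" by accumulating strip-mean toward-wound velocity.

    For each anchor distance ``d₀`` the per-frame strip-mean toward-wound
    velocity is accumulated: ``R(t) = Σ v̄(τ, bin) Δt`` up to full closure
    (Phases 1–2).  In ``advect`` mode the anchor's strip follows its
    remaining distance ``d₀ − R(τ)`` (floored at 0), i.e. the average cell
    moves through the strips as it advances; ``fixed`` keeps the initial
    strip.  An empty bin at some frame borrows the nearest defined strip.
    """
    anchors = np.asarray(anchors_um, dtype=np.float64)
    if np.any(anchors < 0) or np.any(anchors > max_distance_um):
        raise ValueError("anchors must lie within [0, max_distance_um]")
    if mode not in ("advect", "fixed"):
        raise ValueError("mode must be 'advect' or 'fixed'")
    n_bins = int(math.ceil(max_distance_um / strip_width_um))
    vbar = _toward_bin_means(toward_fields, dmaps, strip_width_um, n_bins)
    T_end = phases.t_closure if phases.t_closure is not None else len(toward_fields)
    T_end = min(T_end, len(toward_fields))
    dt_hr = frame_interval_min / 60.0
    R = np.zeros((anchors.size, T_end + 1))
    for k, d0 in enumerate(anchors):
        r = 0.0
        for t in range(T_end):
            d_now = d0 - r if mode == "advect" else d0
            b = min(int(max(d_now, 0.0) // strip_width_um), n_bins - 1)
            r += _nearest_defined(vbar[t], b) * dt_hr
            R[k, t + 1] = r
    times = np.arange(T_end + 1) * dt_hr
    return DisplacementSeries(anchors, times, R)


def velocity_toward_profile(
    toward_fields: Sequence[VelocityField],
    dmaps: Sequence[DistanceMap],
    anchors_um: Sequence[float],
    strip_width_um: float,
    max_distance_um: float,
    smoothing_window: int = 5,
) -> np.ndarray:
    """Per-anchor toward-wound velocity over time, shape (n_anchors, T-1).

    The strip-mean toward-wound velocity of each anchor's (fixed) strip,
    smoothed by a centered moving average of ``smoothing_window`` frames
    (NaN-aware, shrinking near the ends).
    """
    anchors = np.asarray(anchors_um, dtype=np.float64)
    if np.any(anchors < 0) or np.any(anchors > max_distance_um):
        raise ValueError("anchors must lie within [0, max_distance_um]")
    n_bins = int(math.ceil(max_distance_um / strip_width_um))
    vbar = _toward_bin_means(toward_fields, dmaps, strip_width_um, n_bins)
    T = vbar.shape[0]
    half = max(smoothing_window // 2, 0)
    out = np.full((anchors.size, T), np.nan)
    for k, d0 in enumerate(anchors):
        b = min(int(d0 // strip_width_um), n_bins - 1)
        series = vbar[:, b]
        for t in range(T):
            lo, hi = max(t - half, 0), min(t + half + 1, T)
            window = series[lo:hi]
            if np.isfinite(window).any():
                out[k, t] = np.nanmean(window)
    return out
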