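"""Single-cell morpho-kinetics.

Four measurements live here: (1) single-cell trajectories integrated through
the patch-level velocity fields (forward Euler with bilinear interpolation
between patch centers), which replaces manual tracking; (2) area and
eccentricity of labeled cell masks via the equal-second-moments ellipse;
(3) cell density estimated from mean cell area; (4) the Spearman rank
correlation between density and speed, with an exact permutation p-value at
small n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import regionprops, regionprops_table

from woundmap.motion import VelocityField

__all__ = [
    "CellTrack",
    "estimate_trajectory",
    "cell_shape_measures",
    "measure_labeled_cells",
    "density_from_area",
    "density_speed_correlation",
]


@dataclass
class CellTrack:
    """An estimated trajectory: positions (µm, (y, x)) per frame.

    ``status`` is "complete" when the track covered the requested frame
    range, or "terminated" when it left the region of valid motion patches.
    """

    positions_um: np.ndarray
    start_frame: int
    status: str = "complete"

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]

    def net_displacement_um(self) -> np.ndarray:
        return self.positions_um[-1] - self.positions_um[0]


def _sample_field(field: VelocityField, y_px: float, x_px: float,
                  patch_px: int) -> tuple[float, float] | None:
    """Bilinear velocity (µm/hr) at a pixel position from the patch grid.

    Invalid patches are dropped from the interpolation (weights renormalize
    over valid neighbors); returns None when no valid patch lies within one
    patch radius, which terminates the track.
    """
    g = field.grid
    # continuous patch-grid coordinates of the query point
    gy = (y_px - (patch_px - 1) / 2.0) / patch_px
    gx = (x_px - (patch_px - 1) / 2.0) / patch_px
    i0 = int(np.floor(gy))
    j0 = int(np.floor(gx))
    fy, fx = gy - i0, gx - j0
    pts, wts = [], []
    for di, dj, w in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                      (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        i, j = i0 + di, j0 + dj
        if 0 <= i < g.n_rows and 0 <= j < g.n_cols and field.valid[i, j]:
            pts.append((field.v_row[i, j], field.v_col[i, j]))
            wts.append(w)
    if not pts:
        # fall back to the nearest valid patch within one patch radius
        i_near = int(round(gy))
        j_near = int(round(gx))
        best = None
        for i in range(max(i_near - 1, 0), min(i_near + 2, g.n_rows)):
            for j in range(max(j_near - 1, 0), min(j_near + 2, g.n_cols)):
                if field.valid[i, j]:
                    dist = math.hypot(i - gy, j - gx)
                    if dist <= 1.0 and (best is None or dist < best[0]):
                        best = (dist, i, j)
        if best is None:
            return None
        _, i, j = best
        return float(field.v_row[i, j]), float(field.v_col[i, j])
    wsum = sum(wts)
    if wsum <= 0:
        v = pts[0]
        return float(v[0]), float(v[1])
    vy = sum(w * p[0] for w, p in zip(wts, pts)) / wsum
    vx = sum(w * p[1] for w, p in zip(wts, pts)) / wsum
    return float(vy), float(vx)


def estimate_trajectory(
    fields: Sequence[VelocityField],
    start_point_um: tuple[float, float],
    pixel_size_um: float,
    frame_interval_min: float,
    start_frame: int = 0,
    end_frame: int | None = None,
    cellular_mask: np.ndarray | None = None,
) -> CellTrack:
    """Integrate a single-cell trajectory through the velocity fields.

    Forward Euler: ``position(t+1) = position(t) + v(position(t), t)·Δt``
    with ``v`` bilinearly interpolated between valid patch centers.  The
    track terminates early (status "terminated") if it reaches a region with
    no valid patch within one patch radius.
    """
    if end_frame is None:
        end_frame = len(fields)
    if not 0 <= start_frame < end_frame <= len(fields):
        raise ValueError("invalid frame range")
    y, x = float(start_point_um[0]), float(start_point_um[1])
    if cellular_mask is not None:
        r, c = int(y / pixel_size_um), int(x / pixel_size_um)
        if not (0 <= r < cellular_mask.shape[0] and 0 <= c < cellular_mask.shape[1]
                and cellular_mask[r, c]):
            raise ValueError("start point is not on the cellular region")
    dt_hr = frame_interval_min / 60.0
    patch_px = fields[start_frame].grid.patch_size_px
    positions = [(y, x)]
    status = "complete"
    for t in range(start_frame, end_frame):
        v = _sample_field(fields[t], y / pixel_size_um, x / pixel_size_um, patch_px)
        if v is None:
            status = "terminated"
            break
        y += v[0] * dt_hr
        x += v[1] * dt_hr
        positions.append((y, x))
    return CellTrack(np.asarray(positions), start_frame, status)


def cell_shape_measures(cell_mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Area (µm²) and eccentricity of a single binary cell mask.

    Eccentricity is that of the ellipse with the same second central moments
    as the mask: ``√(1 − (b/a)²)``, 0 for a circle, → 1 for a line segment.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    props = regionprops(cell_mask.astype(np.uint8))[0]
    area_um2 = props.area * pixel_size_um**2
    return float(area_um2), float(props.eccentricity)


def measure_labeled_cells(labels: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Area/eccentricity table for every labeled cell in a label raster."""
    tbl = regionprops_table(np.asarray(labels), properties=("label", "area", "eccentricity", "centroid"))
    df = pd.DataFrame(tbl)
    df["area_um2"] = df.pop("area") * pixel_size_um**2
    df = df.rename(columns={"centroid-0": "row", "centroid-1": "col"})
    return df


def density_from_area(mean_cell_area_um2: float, packing_fraction: float = 0.9) -> float:
    """Cell density (cells per 1000 µm²) from the mean single-cell area.

    A confluent monolayer covers ~``packing_fraction`` of the substrate, so
    density ≈ packing_fraction / mean area.  The packing fraction scales the
    absolute density only; correlations with speed are unaffected by it.
    """
    if not mean_cell_area_um2 > 0:
        raise ValueError(f"mean cell area must be > 0, got {mean_cell_area_um2}")
    if not 0.0 < packing_fraction <= 1.0:
        raise ValueError("packing_fraction must lie in (0, 1]")
    return packing_fraction / mean_cell_area_um2 * 1000.0


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float(xc @ yc / denom) if denom > 0 else np.nan


def density_speed_correlation(
    density: Sequence[float],
    speed: Sequence[float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation between density and speed series.

    Average ranks handle ties.  For ``n <= exact_max_n`` the two-sided
    p-value is exact, by enumerating all n! rank permutations; for larger n
    the usual t-approximation is used.  Constant input leaves rho undefined
    (NaN, NaN) with a warning.
    """
    x = np.asarray(density, dtype=np.float64)
    y = np.asarray(speed, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("density and speed must be 1-D series of equal length")
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series; Spearman correlation undefined")
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n <= exact_max_n:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(rx, ry[list(perm)])
            total += 1
            if abs(r) >= target:
                count += 1
        p = count / total
    else:
        # t-approximation on rho
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)
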