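"""Synthetic scratch-assay movie generator with full ground truth.

The generator emulates a bright-field wound-healing acquisition: a confluent
monolayer with a vertical ~300 µm scratch, imaged every 14.5 minutes, whose
two fronts advance and close the wound.  Three motility regimes are modelled:

``untreated``
    Front layers move fastest and speed decays exponentially with distance
    from the wound edge; the profile is constant in time until closure, after
    which all cells decelerate.
``treated``
    An HGF/SF-like activation wave travels backward from the wound edge at a
    fixed speed; cells accelerate layer by layer as the wave passes, and once
    activated, distant cells hold a speed at least as high as front cells.
    After closure front cells halt first while distant cells decay gradually.
``inhibited``
    A Met-inhibited + HGF/SF-like regime: lower peak speed and steeper
    spatial decay, maximizing the front/distant speed ratio.

The monolayer is modelled per image row as a 1-D chain of material points
advected toward the wound by the prescribed velocity law; the wound edge is
made wavy across rows so that first contact between opposing fronts precedes
full closure, producing a non-degenerate middle healing phase.  Frames are
rendered by sampling a static pseudo-cell blob texture at the advected
material coordinates (backward warping with linear interpolation), so the
rendered motion is exactly the prescribed kinematics.  Everything is a pure
function of ``(scenario, rng_seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from woundmap.movies import MovieStack

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "prescribed_velocity",
    "generate_movie",
    "seed_tracks",
    "label_cell_masks",
    "morphology_program",
]

_REGIMES = ("untreated", "treated", "inhibited")

# Regime motility defaults (µm/hr and µm).  These are the package's standard
# study conditions; tests and the classification benchmarks run on them.
_REGIME_DEFAULTS = {
    "untreated": dict(v_front_um_per_hr=20.0, decay_length_um=100.0,
                      texture_cell_diameter_um=20.0),
    "treated": dict(
        v_front_um_per_hr=30.0,
        decay_length_um=60.0,
        v_activated_um_per_hr=35.0,
        wave_speed_um_per_hr=90.0,
        texture_cell_diameter_um=28.0,
    ),
    "inhibited": dict(v_front_um_per_hr=15.0, decay_length_um=45.0,
                      texture_cell_diameter_um=17.0),
}


@dataclass
class SyntheticScenario:
    """Full parameterization of one synthetic wound-healing movie.

    Geometry defaults give a 512×1024 µm field of view at 4 µm/px with a
    centered 300 µm vertical scratch and ~360 µm of monolayer on either
    side; 60 frames at 14.5 min/frame span ~14 h, long enough for the
    untreated and treated regimes to pass through all three healing phases.
    """

    regime: str = "untreated"
    height_px: int = 128
    width_px: int = 256
    pixel_size_um: float = 4.0
    frame_interval_min: float = 14.5
    n_frames: int = 60
    wound_width_um: float = 300.0
    # motility law (None -> regime default)
    v_front_um_per_hr: Optional[float] = None
    decay_length_um: Optional[float] = None
    v_activated_um_per_hr: Optional[float] = None
    wave_speed_um_per_hr: Optional[float] = None
    activation_gradient: float = 0.25
    wave_width_um: float = 40.0
    post_closure_tau_hr: float = 1.0
    # wound geometry
    edge_waviness_um: float = 40.0
    edge_wave_periods: float = 1.5
    # texture / morphology
    texture_cell_diameter_um: Optional[float] = None  # regime default
    texture_amplitude: float = 0.35
    wound_intensity: float = 0.45
    cell_base_intensity: float = 0.55
    noise_sigma: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}, got {self.regime!r}")
        defaults = _REGIME_DEFAULTS[self.regime]
        for key, val in defaults.items():
            if getattr(self, key) is None:
                setattr(self, key, val)
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel_size_um and frame_interval_min must be > 0")
        width_um = self.width_px * self.pixel_size_um
        if self.wound_width_um + 2 * self.edge_waviness_um >= width_um:
            raise ValueError(
                f"wound of {self.wound_width_um} µm (±{self.edge_waviness_um} µm waviness) "
                f"does not fit inside a {width_um} µm wide frame"
            )
        for key in ("v_front_um_per_hr", "decay_length_um", "wave_width_um",
                    "texture_cell_diameter_um"):
            v = getattr(self, key)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"{key} must be finite and >= 0, got {v}")
        # per-frame displacement sanity: warping breaks down past half a frame
        vmax = self.peak_speed_um_per_hr()
        if vmax * self.frame_interval_min / 60.0 > width_um / 2:
            raise ValueError("prescribed velocities exceed half the frame width per frame")

    def peak_speed_um_per_hr(self) -> float:
        """Largest speed the velocity law can prescribe (for search radii)."""
        v = float(self.v_front_um_per_hr)
        if self.regime == "treated":
            v = max(v, float(self.v_activated_um_per_hr) * (1.0 + self.activation_gradient))
        return v

    @property
    def frame_interval_hr(self) -> float:
        return self.frame_interval_min / 60.0


def prescribed_velocity(scenario: SyntheticScenario, d, t):
    """Speed (µm/hr, toward the wound) prescribed at distance ``d`` and time ``t``.

    ``d`` is the distance (µm) from the current wound edge, ``t`` the time in
    hours since the scratch.  Both may be arrays (broadcast).  This is the
    pre-closure law; the generator additionally applies a per-row post-closure
    deceleration once that row of the wound has healed.

    * untreated / inhibited: ``v_front * exp(-d / decay_length)`` — constant
      in time, front layers fastest.
    * treated: a logistic activation wave of width ``wave_width_um``
      travelling backward at ``wave_speed_um_per_hr`` lifts cells from the
      exponential base profile onto an activated plateau that increases
      mildly with distance, so that once the wave has passed, distant cells
      move at least as fast as front cells.
    """
    d = np.asarray(d, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance d must be >= 0")
    if np.any(t < 0):
        raise ValueError("time t must be >= 0")
    v_front = float(scenario.v_front_um_per_hr)
    lam = float(scenario.decay_length_um)
    base = v_front * np.exp(-d / lam)
    if scenario.regime != "treated":
        v = np.broadcast_to(base, np.broadcast_shapes(d.shape, t.shape)).copy()
        return v if v.ndim else float(v)
    v_act = float(scenario.v_activated_um_per_hr)
    wave_pos = float(scenario.wave_speed_um_per_hr) * t
    sig = 1.0 / (1.0 + np.exp(-(wave_pos - d) / float(scenario.wave_width_um)))
    plateau = v_act * (1.0 + scenario.activation_gradient * d / (d + lam))
    v = base * (1.0 - sig) + plateau * sig
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# kinematics


def _edge_profiles(scenario: SyntheticScenario, rng: np.random.Generator):
    """Initial left/right wound-edge x-positions (µm) per image row."""
    H = scenario.height_px
    width_um = scenario.width_px * scenario.pixel_size_um
    cx = width_um / 2.0
    rows = np.arange(H) / max(H - 1, 1)
    amp = scenario.edge_waviness_um
    ph_w, ph_c = rng.uniform(0, 2 * np.pi, size=2)
    # modulate the scratch *width* directly: the narrowest rows make first
    # contact well before the widest rows close, guaranteeing a non-trivial
    # contact-to-closure phase
    local_width = scenario.wound_width_um + amp * np.sin(
        2 * np.pi * scenario.edge_wave_periods * rows + ph_w
    )
    center = cx + 0.3 * amp * np.sin(
        2 * np.pi * (scenario.edge_wave_periods + 0.7) * rows + ph_c
    )
    left = center - local_width / 2.0
    right = center + local_width / 2.0
    return left, np.maximum(right, left + 4.0 * scenario.pixel_size_um)


@dataclass
class _Kinematics:
    """Integrated material-point kinematics shared by rendering and truth."""

    x0_left: np.ndarray      # (H, J) initial positions µm; j=0 is the front
    x0_right: np.ndarray
    pos_left: np.ndarray     # (T, H, J) positions µm
    pos_right: np.ndarray
    spd_left: np.ndarray     # (T-1, H, J) per-frame mean speed µm/hr (toward wound)
    spd_right: np.ndarray
    meet: np.ndarray         # (H,) meeting x per row (nan if never closed)
    t_close_row: np.ndarray  # (H,) closure time per row, hours (inf if open)


def _integrate(scenario: SyntheticScenario, rng: np.random.Generator) -> _Kinematics:
    H = scenario.height_px
    px = scenario.pixel_size_um
    width_um = scenario.width_px * px
    T = scenario.n_frames
    dt_frame = scenario.frame_interval_hr
    nsub = 4
    dt = dt_frame / nsub

    left0, right0 = _edge_profiles(scenario, rng)
    spacing = px  # one material point per pixel column
    J = int(math.ceil(max(left0.max(), width_um - right0.min()) / spacing)) + 2
    j = np.arange(J)
    x0_left = left0[:, None] - j[None, :] * spacing
    x0_right = right0[:, None] + j[None, :] * spacing

    pos_l = x0_left.copy()
    pos_r = x0_right.copy()
    closed = np.zeros(H, dtype=bool)
    meet = np.full(H, np.nan)
    t_close_row = np.full(H, np.inf)
    lam = float(scenario.decay_length_um)
    tau0 = float(scenario.post_closure_tau_hr)

    out_pos_l = np.empty((T, H, J))
    out_pos_r = np.empty((T, H, J))
    out_pos_l[0], out_pos_r[0] = pos_l, pos_r
    out_spd_l = np.empty((T - 1, H, J))
    out_spd_r = np.empty((T - 1, H, J))

    floor = 0.01  # minimum spacing (µm) keeping the material map monotone
    offs = floor * j

    def _enforce(pos_side, sign):
        # keep each chain monotone away from its front point
        q = sign * pos_side + offs[None, :]
        np.minimum.accumulate(q, axis=1, out=q)
        return sign * (q - offs[None, :])

    for t_idx in range(1, T):
        prev_l, prev_r = pos_l.copy(), pos_r.copy()
        for s in range(nsub):
            tau = (t_idx - 1) * dt_frame + s * dt
            d_l = pos_l[:, :1] - pos_l
            d_r = pos_r - pos_r[:, :1]
            v_l = prescribed_velocity(scenario, np.maximum(d_l, 0.0), tau)
            v_r = prescribed_velocity(scenario, np.maximum(d_r, 0.0), tau)
            if closed.any():
                age = np.maximum(tau - t_close_row[closed, None], 0.0)
                v_l[closed] *= np.exp(-age / (tau0 * (1.0 + d_l[closed] / lam)))
                v_r[closed] *= np.exp(-age / (tau0 * (1.0 + d_r[closed] / lam)))
            pos_l = pos_l + v_l * dt
            pos_r = pos_r - v_r * dt
            # first contact per row
            gap = pos_r[:, 0] - pos_l[:, 0]
            newly = (gap <= 0) & ~closed
            if newly.any():
                meet[newly] = 0.5 * (pos_r[newly, 0] + pos_l[newly, 0])
                t_close_row[newly] = tau + dt
                closed |= newly
            if closed.any():
                pos_l[closed] = np.minimum(pos_l[closed], meet[closed, None])
                pos_r[closed] = np.maximum(pos_r[closed], meet[closed, None])
            pos_l = _enforce(pos_l, 1.0)
            pos_r = _enforce(pos_r, -1.0)
        out_pos_l[t_idx], out_pos_r[t_idx] = pos_l, pos_r
        out_spd_l[t_idx - 1] = (pos_l - prev_l) / dt_frame
        out_spd_r[t_idx - 1] = (prev_r - pos_r) / dt_frame

    return _Kinematics(x0_left, x0_right, out_pos_l, out_pos_r,
                       out_spd_l, out_spd_r, meet, t_close_row)


# ---------------------------------------------------------------------------
# ground truth container


@dataclass
class GroundTruth:
    """Everything the generator knows about a synthetic movie.

    ``velocity(d, t)`` is the prescribed pre-closure law; ``wound_masks`` /
    ``wound_area_um2`` / ``t_contact`` / ``t_closure`` describe the rendered
    wound; ``realized_velocity_map`` bins the actually-integrated material
    speeds by distance from the current edge, which is the reference any
    measured velocity magnitude map should be compared against.
    """

    scenario: SyntheticScenario
    velocity: Callable[[np.ndarray, np.ndarray], np.ndarray]
    wound_masks: np.ndarray          # (T, H, W) bool
    cellular_masks: np.ndarray       # (T, H, W) bool
    wound_area_um2: np.ndarray       # (T,)
    t_contact: Optional[int]
    t_closure: Optional[int]
    left_edges_um: np.ndarray        # (T, H)
    right_edges_um: np.ndarray       # (T, H)
    _kin: _Kinematics = field(repr=False)

    def realized_velocity_map(self, strip_width_um: float, max_distance_um: float):
        """Ground-truth ``M[t, d]``: mean material speed per distance bin.

        Returns ``(map, counts)`` with shape ``(T-1, n_bins)``; bins with no
        material points are NaN.  Distances are measured from the current
        wound edge (the frozen seam after that row has closed), matching the
        measurement convention of the analysis pipeline.
        """
        kin = self._kin
        n_bins = int(math.ceil(max_distance_um / strip_width_um))
        T = self.scenario.n_frames
        out = np.full((T - 1, n_bins), np.nan)
        counts = np.zeros((T - 1, n_bins), dtype=np.int64)
        for t in range(T - 1):
            d_l = kin.pos_left[t, :, :1] - kin.pos_left[t]
            d_r = kin.pos_right[t] - kin.pos_right[t, :, :1]
            d = np.concatenate([d_l.ravel(), d_r.ravel()])
            s = np.concatenate([kin.spd_left[t].ravel(), kin.spd_right[t].ravel()])
            # restrict to material inside the frame
            x = np.concatenate([kin.pos_left[t].ravel(), kin.pos_right[t].ravel()])
            width_um = self.scenario.width_px * self.scenario.pixel_size_um
            ok = (x >= 0) & (x <= width_um) & (d >= 0) & (d < max_distance_um)
            idx = np.floor(d[ok] / strip_width_um).astype(int)
            sums = np.bincount(idx, weights=s[ok], minlength=n_bins)[:n_bins]
            cnt = np.bincount(idx, minlength=n_bins)[:n_bins]
            counts[t] = cnt
            with np.errstate(invalid="ignore"):
                out[t] = np.where(cnt > 0, sums / np.maximum(cnt, 1), np.nan)
        return out, counts

    def velocity_field_stack(self, patch_size_px: int) -> list:
        """Noise-free per-patch velocity fields from the integrated kinematics.

        Builds one :class:`~woundmap.motion.VelocityField` per frame pair by
        sampling the material speeds at every patch center, with the
        toward-wound component already resolved (motion is purely horizontal
        toward the nearer front).  Useful as the measurement-free reference
        for displacement and profile analyses.
        """
        from woundmap.motion import PatchGrid, VelocityField

        sc = self.scenario
        kin = self._kin
        grid = PatchGrid.for_frame((sc.height_px, sc.width_px), patch_size_px)
        rr, cc = grid.centers_px()
        rows = np.round(rr).astype(int)
        x_um = (cc + 0.5) * sc.pixel_size_um
        fields = []
        for t in range(sc.n_frames - 1):
            v_col = np.zeros(rr.shape)
            toward = np.zeros(rr.shape)
            valid = np.zeros(rr.shape, dtype=bool)
            for i in range(grid.n_rows):
                r = rows[i, 0]
                le, re = self.left_edges_um[t, r], self.right_edges_um[t, r]
                xs = x_um[i]
                on_left = xs <= le
                on_right = xs >= re
                # ascending positions for interpolation
                sp_l = np.interp(xs, kin.pos_left[t, r, ::-1], kin.spd_left[t, r, ::-1])
                sp_r = np.interp(xs, kin.pos_right[t, r], kin.spd_right[t, r])
                v_col[i] = np.where(on_left, sp_l, np.where(on_right, -sp_r, 0.0))
                toward[i] = np.where(on_left, sp_l, np.where(on_right, sp_r, 0.0))
                valid[i] = on_left | on_right
            fields.append(VelocityField(
                grid,
                v_row=np.zeros(rr.shape),
                v_col=np.where(valid, v_col, np.nan),
                valid=valid,
                score=np.ones(rr.shape),
                v_toward=np.where(valid, toward, np.nan),
                v_parallel=np.where(valid, 0.0, np.nan),
            ))
        return fields

    def track(self, row_px: int, start_distance_um: float) -> np.ndarray:
        """Ground-truth trajectory (T, 2) in µm ``(y, x)`` for the material
        point of row ``row_px`` starting ``start_distance_um`` behind the
        left wound edge."""
        kin = self._kin
        d0 = kin.x0_left[row_px, 0] - kin.x0_left[row_px]
        jsel = int(np.argmin(np.abs(d0 - start_distance_um)))
        y = (row_px + 0.5) * self.scenario.pixel_size_um
        return np.stack(
            [np.full(self.scenario.n_frames, y), kin.pos_left[:, row_px, jsel]], axis=1
        )


# ---------------------------------------------------------------------------
# texture rendering


def _make_texture(scenario: SyntheticScenario, rng: np.random.Generator,
                  pad_px: int = 0) -> np.ndarray:
    """Static pseudo-cell blob texture in material (frame-0) coordinates.

    ``pad_px`` extends the texture horizontally beyond the frame so that
    material drifting in from outside the field of view stays textured.
    """
    H, W = scenario.height_px, scenario.width_px + 2 * pad_px
    px = scenario.pixel_size_um
    diam_px = max(scenario.texture_cell_diameter_um / px, 2.0)
    tex = np.zeros((H, W))
    step = diam_px
    ys = np.arange(step / 2, H, step)
    xs = np.arange(step / 2, W, step)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    n = yy.size
    cy = yy.ravel() + rng.uniform(-0.35, 0.35, n) * step
    cx = xx.ravel() + rng.uniform(-0.35, 0.35, n) * step
    amp = rng.uniform(0.5, 1.0, n) * rng.choice([-1.0, 1.0], n)
    sig = diam_px / 3.0 * rng.uniform(0.8, 1.2, n)
    r = np.ceil(3 * sig).astype(int)
    for k in range(n):
        y0, x0 = int(round(cy[k])), int(round(cx[k]))
        ylo, yhi = max(y0 - r[k], 0), min(y0 + r[k] + 1, H)
        xlo, xhi = max(x0 - r[k], 0), min(x0 + r[k] + 1, W)
        if ylo >= yhi or xlo >= xhi:
            continue
        gy = np.arange(ylo, yhi) - cy[k]
        gx = np.arange(xlo, xhi) - cx[k]
        tex[ylo:yhi, xlo:xhi] += amp[k] * np.exp(
            -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sig[k] ** 2)
        )
    tex /= max(np.abs(tex).max(), 1e-12)
    # sub-cellular fine detail (organelle-scale): keeps local variance high
    # even where advection stretches the cell-scale blobs
    from scipy import ndimage as _ndi

    fine = _ndi.gaussian_filter(rng.standard_normal((H, W)), sigma=max(diam_px / 8.0, 0.6))
    fine /= max(np.abs(fine).std() * 3.0, 1e-12)
    tex = tex + 0.35 * np.clip(fine, -1.0, 1.0)
    tex /= max(np.abs(tex).max(), 1e-12)
    return scenario.cell_base_intensity + scenario.texture_amplitude * tex


def generate_movie(scenario: SyntheticScenario) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic wound-healing movie and its ground truth.

    Deterministic given ``scenario.rng_seed``: the same scenario generates a
    bit-identical stack every time.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    # fixed draw order keeps determinism independent of internal refactors
    rng_edges, rng_tex, rng_noise = [np.random.default_rng(s) for s in rng.integers(0, 2**31, 3)]

    kin = _integrate(scenario, rng_edges)
    pad = 64  # px of off-frame texture; keeps inflowing material textured
    tex = _make_texture(scenario, rng_tex, pad_px=pad)

    H, W, T = scenario.height_px, scenario.width_px, scenario.n_frames
    px = scenario.pixel_size_um
    xc = (np.arange(W) + 0.5) * px  # pixel-center x in µm
    tex_cols = np.arange(W + 2 * pad, dtype=np.float64)

    frames = np.empty((T, H, W))
    wound_masks = np.zeros((T, H, W), dtype=bool)
    left_edges = kin.pos_left[:, :, 0]
    right_edges = kin.pos_right[:, :, 0]

    for t in range(T):
        frame = np.full((H, W), scenario.wound_intensity)
        for r in range(H):
            le, re = left_edges[t, r], right_edges[t, r]
            # left monolayer: pixels with center <= current edge
            sel = xc <= le
            if sel.any():
                # positions decrease with j; np.interp needs ascending xp
                xp = kin.pos_left[t, r, ::-1]
                fp = kin.x0_left[r, ::-1]
                Xmat = np.interp(xc[sel], xp, fp)
                frame[r, sel] = np.interp(Xmat / px - 0.5 + pad, tex_cols, tex[r])
            sel = xc >= re
            if sel.any():
                xp = kin.pos_right[t, r]
                fp = kin.x0_right[r]
                Xmat = np.interp(xc[sel], xp, fp)
                frame[r, sel] = np.interp(Xmat / px - 0.5 + pad, tex_cols, tex[r])
            if re - le > 0.5 * px:
                wound_masks[t, r] = (xc > le) & (xc < re)
        if scenario.noise_sigma > 0:
            frame = frame + rng_noise.normal(0.0, scenario.noise_sigma, size=(H, W))
        frames[t] = np.clip(frame, 0.0, 1.0)

    wound_area = wound_masks.reshape(T, -1).sum(axis=1) * px * px
    area0 = wound_area[0]
    closed_rows = np.isfinite(kin.meet)
    frame_times = np.arange(T) * scenario.frame_interval_hr
    t_contact: Optional[int] = None
    t_closure: Optional[int] = None
    if area0 == 0:
        t_contact = t_closure = 0
    else:
        if np.isfinite(kin.t_close_row).any():
            first = kin.t_close_row.min()
            idx = int(np.searchsorted(frame_times, first))
            if idx < T:
                t_contact = idx
        below = np.nonzero(wound_area < 0.01 * area0)[0]
        # closure threshold fixed at 1% of the initial area (ground truth);
        # the pipeline's detect_phases applies the configured fraction
        if below.size:
            t_closure = int(below[0])
        if t_contact is not None and t_closure is not None:
            t_contact = min(t_contact, t_closure)

    truth = GroundTruth(
        scenario=scenario,
        velocity=lambda d, t: prescribed_velocity(scenario, d, t),
        wound_masks=wound_masks,
        cellular_masks=~wound_masks,
        wound_area_um2=wound_area,
        t_contact=t_contact,
        t_closure=t_closure,
        left_edges_um=left_edges,
        right_edges_um=right_edges,
        _kin=kin,
    )
    movie = MovieStack.from_frames(
        frames, scenario.pixel_size_um, scenario.frame_interval_min,
        name=f"synthetic-{scenario.regime}-{scenario.rng_seed}",
    )
    return movie, truth


# ---------------------------------------------------------------------------
# ground-truth tracks


def seed_tracks(
    scenario: SyntheticScenario,
    n_cells: int,
    rng: np.random.Generator | int | None = None,
    ground_truth: GroundTruth | None = None,
) -> np.ndarray:
    """Ground-truth trajectories of ``n_cells`` cells, shape ``(n, T, 2)`` µm.

    Cells start at random positions within the left monolayer (rows uniform,
    initial distance from the edge uniform over the covered range) and follow
    the integrated material kinematics exactly.  Reproducible given the same
    rng/seed.  Positions are ``(y, x)`` in µm.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else scenario.rng_seed)
    if ground_truth is None:
        _, ground_truth = generate_movie(scenario)
    kin = ground_truth._kin
    H = scenario.height_px
    max_d = kin.x0_left[:, 0].min() - 10.0  # stay inside the frame
    if max_d <= 0:
        raise ValueError("monolayer too narrow to seed tracks")
    rows = rng.integers(0, H, n_cells)
    dists = rng.uniform(5.0, max_d, n_cells)
    return np.stack([ground_truth.track(int(r), float(d)) for r, d in zip(rows, dists)])


# ---------------------------------------------------------------------------
# single-cell morphology program


def morphology_program(regime: str, d_um, phase: int):
    """Prescribed mean cell area (µm²) and eccentricity at distance ``d_um``
    from the wound edge in healing phase ``phase`` (1, 2 or 3).

    Encodes the regimes' morphological trends: untreated front cells are
    larger and more elongated than distant cells throughout healing and all
    cells shrink and round up after closure; treated cells start like
    untreated ones but in later phases distant cells spread and elongate
    while front cells shrink.
    """
    if regime not in _REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    if phase not in (1, 2, 3):
        raise ValueError("phase must be 1, 2 or 3")
    d = np.clip(np.asarray(d_um, dtype=np.float64), 0.0, 350.0) / 350.0
    A0 = math.pi * (20.0 / 2.0) ** 2  # ~314 µm² for a 20 µm cell
    if regime == "treated":
        if phase == 1:
            area = A0 * (1.5 - 0.5 * d)
            ecc = 0.85 - 0.25 * d
        elif phase == 2:
            area = A0 * (1.0 + 0.8 * d)
            ecc = 0.60 + 0.25 * d
        else:
            area = A0 * (0.8 + 0.6 * d)
            ecc = 0.50 + 0.20 * d
    else:
        scale = 1.0 if regime == "untreated" else 0.7
        if phase in (1, 2):
            area = A0 * (1.0 + scale * (0.4 - 0.4 * d))
            ecc = 0.55 + scale * (0.25 - 0.25 * d)
        else:
            area = A0 * np.full_like(d, 0.9)
            ecc = np.full_like(d, 0.45)
    return area, np.clip(ecc, 0.0, 0.99)


def label_cell_masks(
    truth: GroundTruth,
    frame_index: int,
    n_cells: int = 60,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a labeled single-cell ellipse mask for one frame.

    Stand-in for fluorescently marked single cells: ellipses whose area and
    eccentricity follow :func:`morphology_program` at each cell's distance
    from the wound edge in the frame's healing phase.  Returns a 16-bit label
    raster (0 = unlabeled) and a table with the generating parameters per
    cell (id, row, col, distance µm, area µm², eccentricity, orientation).
    """
    sc = truth.scenario
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else sc.rng_seed + 7)
    t = frame_index
    if truth.t_contact is not None and t >= truth.t_contact:
        phase = 2 if (truth.t_closure is None or t < truth.t_closure) else 3
    else:
        phase = 1
    H, W = sc.height_px, sc.width_px
    px = sc.pixel_size_um
    cellular = truth.cellular_masks[t]
    # distance from the wound edge per pixel, straight-edge approximation per row
    xc = (np.arange(W) + 0.5) * px
    d_img = np.zeros((H, W))
    for r in range(H):
        le, re = truth.left_edges_um[t, r], truth.right_edges_um[t, r]
        d_img[r] = np.where(xc <= le, le - xc, np.where(xc >= re, xc - re, 0.0))

    labels = np.zeros((H, W), dtype=np.uint16)
    rows_out = []
    spacing = max(int(2.2 * sc.texture_cell_diameter_um / px), 4)
    cand_r = np.arange(spacing // 2, H - spacing // 2, spacing)
    cand_c = np.arange(spacing // 2, W - spacing // 2, spacing)
    cand = [(r, c) for r in cand_r for c in cand_c if cellular[r, c]]
    rng.shuffle(cand)
    yy, xx = np.mgrid[0:H, 0:W]
    for lab, (r, c) in enumerate(cand[:n_cells], start=1):
        d = float(d_img[r, c])
        area, ecc = morphology_program(sc.regime, d, phase)
        area, ecc = float(area), float(ecc)
        ratio = math.sqrt(max(1.0 - ecc**2, 1e-6))  # b/a
        a_px = math.sqrt(area / (math.pi * ratio)) / px
        b_px = a_px * ratio
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - c) * ct + (yy - r) * st
        v = -(xx - c) * st + (yy - r) * ct
        inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
        inside &= labels == 0
        labels[inside] = lab
        rows_out.append(dict(label=lab, row=r, col=c, distance_um=d,
                             area_um2=area, eccentricity=ecc, orientation=theta,
                             phase=phase))
    return labels, pd.DataFrame(rows_out)
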