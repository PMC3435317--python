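"""Single-cell morpho-kinetics: tracking, shape, density, correlation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from woundmap.morphology import (
    cell_shape_measures,
    density_from_area,
    density_speed_correlation,
    estimate_trajectory,
    measure_labeled_cells,
)
from woundmap.motion import PatchGrid, VelocityField
from woundmap.synthetic import label_cell_masks


def _uniform_fields(n, grid, v_row, v_col):
    shape = (grid.n_rows, grid.n_cols)
    return [
        VelocityField(grid, np.full(shape, float(v_row)), np.full(shape, float(v_col)),
                      np.ones(shape, bool), np.ones(shape))
        for _ in range(n)
    ]


class TestTrajectory:
    def test_zero_field_track_is_stationary(self):
        grid = PatchGrid.for_frame((64, 64), 8)
        fields = _uniform_fields(5, grid, 0.0, 0.0)
        track = estimate_trajectory(fields, (30.0, 30.0), 1.0, 30.0)
        assert np.allclose(track.positions_um, track.positions_um[0])
        assert track.status == "complete"

    def test_uniform_field_closed_form_displacement(self):
        grid = PatchGrid.for_frame((64, 64), 8)
        fields = _uniform_fields(6, grid, 4.0, -2.0)  # µm/hr
        track = estimate_trajectory(fields, (30.0, 30.0), 1.0, frame_interval_min=30.0)
        # 6 frames * 0.5 h, v = (4, -2) µm/hr -> net (12, -6) µm
        assert np.allclose(track.net_displacement_um(), (12.0, -6.0), atol=1e-6)

    def test_background_start_point_rejected(self):
        grid = PatchGrid.for_frame((64, 64), 8)
        fields = _uniform_fields(3, grid, 0.0, 0.0)
        mask = np.zeros((64, 64), bool)
        with pytest.raises(ValueError, match="cellular"):
            estimate_trajectory(fields, (30.0, 30.0), 1.0, 30.0, cellular_mask=mask)

    def test_estimated_tracks_follow_ground_truth(self, untreated_run, synth_config):
        """DIC-based trajectory estimation stays within one patch of truth."""
        sc, movie, truth, result = untreated_run
        patch_um = synth_config.patch_size_um
        errors = []
        for row, d0 in ((30, 60.0), (64, 120.0), (96, 200.0)):
            gt = truth.track(row, d0)
            start = tuple(gt[0])
            est = estimate_trajectory(
                result.fields, start, movie.pixel_size_um, movie.frame_interval_min,
                end_frame=truth.t_closure,
            )
            n = est.positions_um.shape[0]
            err = np.linalg.norm(est.positions_um - gt[:n], axis=1)
            errors.append(err.mean())
        assert np.mean(errors) <= patch_um

    def test_track_reproducible(self, untreated_run):
        _, movie, _, result = untreated_run
        a = estimate_trajectory(result.fields, (100.0, 200.0), 4.0, 14.5)
        b = estimate_trajectory(result.fields, (100.0, 200.0), 4.0, 14.5)
        assert np.array_equal(a.positions_um, b.positions_um)


class TestShapeMeasures:
    def _disk(self, radius, shape=(64, 64)):
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        c = (shape[0] // 2, shape[1] // 2)
        return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2

    def test_disk_has_near_zero_eccentricity(self):
        area, ecc = cell_shape_measures(self._disk(20), pixel_size_um=1.0)
        assert ecc <= 0.1
        assert area == pytest.approx(np.pi * 400, rel=0.02)

    def test_line_has_near_unit_eccentricity(self):
        mask = np.zeros((60, 60), bool)
        mask[30, 5:55] = True
        _, ecc = cell_shape_measures(mask, 1.0)
        assert ecc >= 0.99

    def test_ellipse_closed_form(self):
        yy, xx = np.mgrid[0:120, 0:120]
        mask = ((xx - 60) / 40.0) ** 2 + ((yy - 60) / 20.0) ** 2 <= 1.0
        _, ecc = cell_shape_measures(mask, 1.0)
        assert ecc == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_scale_invariance_of_eccentricity(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = ((xx - 40) / 25.0) ** 2 + ((yy - 40) / 12.0) ** 2 <= 1.0
        _, e1 = cell_shape_measures(mask, 1.0)
        up = np.kron(mask, np.ones((2, 2), bool))
        _, e2 = cell_shape_measures(up, 1.0)
        assert abs(e1 - e2) <= 0.01

    def test_rotation_invariance_of_eccentricity(self):
        from scipy import ndimage
        yy, xx = np.mgrid[0:100, 0:100]
        mask = ((xx - 50) / 30.0) ** 2 + ((yy - 50) / 15.0) ** 2 <= 1.0
        _, e1 = cell_shape_measures(mask, 1.0)
        rot = ndimage.rotate(mask.astype(float), 37, reshape=True, order=1) > 0.5
        _, e2 = cell_shape_measures(rot, 1.0)
        assert abs(e1 - e2) <= 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cell_shape_measures(np.zeros((8, 8), bool), 1.0)

    def test_labeled_masks_recover_programmed_morphology(self, untreated_run):
        _, movie, truth, _ = untreated_run
        labels, table = label_cell_masks(truth, frame_index=5, n_cells=40, rng=0)
        measured = measure_labeled_cells(labels, movie.pixel_size_um)
        merged = measured.merge(table, on="label", suffixes=("_m", "_p"))
        # rasterized ellipses reproduce programmed areas within discretization
        rel = np.abs(merged.area_um2_m - merged.area_um2_p) / merged.area_um2_p
        assert rel.median() <= 0.15


class TestDensity:
    def test_density_arithmetic(self):
        assert density_from_area(200.0, packing_fraction=1.0) == pytest.approx(5.0)

    def test_inverse_proportionality(self):
        assert density_from_area(400.0, 0.9) == pytest.approx(density_from_area(200.0, 0.9) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            density_from_area(0.0)
        with pytest.raises(ValueError):
            density_from_area(100.0, packing_fraction=1.5)

    def test_density_estimate_matches_blob_counts(self, untreated_run):
        _, movie, truth, _ = untreated_run
        labels, table = label_cell_masks(truth, frame_index=3, n_cells=60, rng=1)
        near = table[table.distance_um < 248.0]
        est = density_from_area(near.area_um2.mean(), packing_fraction=1.0)
        # true count density over the covered area: cells fill area/mean-area
        true = 1000.0 / near.area_um2.mean()
        assert est == pytest.approx(true, rel=0.2)


class TestSpearman:
    def test_perfect_anticorrelation(self):
        rho, p = density_speed_correlation([5, 4, 3, 2, 1], [1, 2, 3, 4, 5])
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_p_at_n5(self):
        _, p = density_speed_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert p == pytest.approx(2 / 120)

    def test_exact_p_matches_enumeration(self, rng):
        x = rng.random(6)
        y = rng.random(6)
        rho, p = density_speed_correlation(x, y)
        # independent brute force over all 6! rankings
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        def _rho(a, b):
            ac, bc = a - a.mean(), b - b.mean()
            return (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        target = abs(_rho(rx, ry))
        hits = sum(
            abs(_rho(rx, ry[list(perm)])) >= target - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert p == pytest.approx(hits / math.factorial(6))

    def test_rho_matches_scipy(self, rng):
        x = rng.random(30)
        y = 0.5 * x + rng.random(30)
        rho, p = density_speed_correlation(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=0.05)

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = density_speed_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho)

    def test_sparser_regions_move_faster_in_untreated_regime(self, untreated_run, synth_config):
        """Front strips are sparser (stretched cells) and faster: negative
        density-speed correlation across distance intervals."""
        from woundmap.synthetic import morphology_program

        _, _, truth, result = untreated_run
        ph = result.phases
        M = result.velocity_map.M
        centers = result.velocity_map.bin_centers_um()
        speeds, densities = [], []
        for b, d in enumerate(centers):
            speed = np.nanmean(M[: ph.t_contact, b])
            if not np.isfinite(speed):
                continue
            area, _ = morphology_program("untreated", d, 1)
            speeds.append(speed)
            densities.append(density_from_area(float(area)))
        rho, _ = density_speed_correlation(densities, speeds)
        assert rho < 0
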