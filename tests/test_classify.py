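"""Descriptor construction, normalization, LOOCV SVM, rank tests, PCA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from woundmap.classify import (
    DescriptorVector,
    exact_ranksum,
    loocv_svm,
    normalize,
    pca2,
    velocity_descriptor,
)
from woundmap.strips import PhasePartition, VelocityMagnitudeMap


def _const_map(T=30, n_bins=12, value=7.0, strip=30.0):
    M = np.full((T, n_bins), float(value))
    return VelocityMagnitudeMap(M, np.ones_like(M, dtype=int), strip, 14.5)


class TestVelocityDescriptor:
    def test_three_phases_six_intervals_is_length_18(self):
        vmap = _const_map()
        vec = velocity_descriptor(vmap, PhasePartition(10, 20), 6, 3)
        assert vec.values.shape == (18,)

    def test_two_phases_six_intervals_is_length_12(self):
        vmap = _const_map()
        vec = velocity_descriptor(vmap, PhasePartition(10, 20), 6, 2)
        assert vec.values.shape == (12,)

    def test_constant_map_gives_constant_descriptor(self):
        vmap = _const_map(value=3.25)
        vec = velocity_descriptor(vmap, PhasePartition(10, 20), 6, 3)
        assert np.allclose(vec.values, 3.25)

    def test_phase_major_ordering(self):
        # phase means 1, 2, 3 in consecutive thirds of the time axis
        M = np.concatenate([np.full((10, 12), k) for k in (1.0, 2.0, 3.0)])
        vmap = VelocityMagnitudeMap(M, np.ones_like(M, int), 30.0, 14.5)
        vec = velocity_descriptor(vmap, PhasePartition(10, 20), 6, 3)
        assert np.allclose(vec.values[:6], 1.0)
        assert np.allclose(vec.values[6:12], 2.0)
        assert np.allclose(vec.values[12:], 3.0)

    def test_wholly_missing_cell_raises_naming_it(self):
        M = np.full((30, 12), 5.0)
        M[:, 10:] = np.nan  # farthest interval has no data
        vmap = VelocityMagnitudeMap(M, np.ones_like(M, int), 30.0, 14.5)
        with pytest.raises(ValueError, match="interval 5"):
            velocity_descriptor(vmap, PhasePartition(10, 20), 6, 3)

    def test_serialization_stable_across_runs(self, untreated_run, synth_config):
        _, _, _, result = untreated_run
        v1 = velocity_descriptor(result.velocity_map, result.phases, 6, 3,
                                 synth_config.max_distance_um)
        v2 = velocity_descriptor(result.velocity_map, result.phases, 6, 3,
                                 synth_config.max_distance_um)
        assert np.array_equal(v1.values, v2.values)


class TestNormalize:
    def test_three_four_five(self):
        assert np.allclose(normalize(np.array([3.0, 4.0])), [0.6, 0.8])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, alpha):
        v = np.random.default_rng(seed).random(12) + 0.05
        assert np.allclose(normalize(v * alpha), normalize(v), atol=1e-12)
        assert np.linalg.norm(normalize(v)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(5))


class TestExactRanksum:
    def test_complete_separation_6v5(self):
        _, p = exact_ranksum([1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14])
        assert p == pytest.approx(2 / 462)
        assert round(p, 4) == 0.0043

    def test_complete_separation_6v6(self):
        _, p = exact_ranksum([1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14, 15])
        assert p == pytest.approx(2 / 924)
        assert round(p, 4) == 0.0022

    def test_identical_groups_saturate(self):
        _, p = exact_ranksum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 6), st.integers(3, 6))
    def test_matches_brute_force_enumeration(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.random(na)
        b = rng.random(nb)
        w, p = exact_ranksum(a, b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        sums = [ranks[list(c)].sum() for c in itertools.combinations(range(na + nb), na)]
        sums = np.asarray(sums)
        expected = 2.0 * min((sums <= w + 1e-9).mean(), (sums >= w - 1e-9).mean())
        assert p == pytest.approx(min(expected, 1.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_exact_mannwhitney(self, seed):
        """Independent oracle for the tie-free case."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=7)
        b = rng.normal(size=6)
        _, p = exact_ranksum(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            exact_ranksum([], [1.0])


class TestLoocvSvm:
    def test_separable_classes_classify_perfectly(self, rng):
        X = np.vstack([
            np.array([1.0, 0.0]) + 0.05 * rng.standard_normal((6, 2)),
            np.array([-1.0, 0.0]) + 0.05 * rng.standard_normal((6, 2)),
        ])
        y = ["a"] * 6 + ["b"] * 6
        res = loocv_svm(X, y)
        assert res.accuracy == 1.0
        assert res.ranksum_p == pytest.approx(2 / 924)

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        X = np.vstack([
            np.array([1.0, 0.0]) + 0.05 * rng.standard_normal((10, 2)),
            np.array([-1.0, 0.0]) + 0.05 * rng.standard_normal((10, 2)),
        ])
        accs = []
        for _ in range(100):
            y = np.array(["a"] * 10 + ["b"] * 10)
            rng.shuffle(y)
            if min((y == "a").sum(), (y == "b").sum()) < 2:
                continue
            accs.append(loocv_svm(X, y).accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_feature_scaling_absorbed_by_standardization(self, rng):
        X = rng.random((10, 4))
        y = ["a"] * 5 + ["b"] * 5
        r1 = loocv_svm(X, y, standardize=True)
        r2 = loocv_svm(X * np.array([1.0, 100.0, 0.01, 5.0]), y, standardize=True)
        assert np.array_equal(r1.predictions, r2.predictions)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_svm(rng.random((5, 3)), ["a"] * 5)

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError):
            loocv_svm(rng.random((5, 3)), ["a", "a", "a", "a", "b"])


class TestPca2:
    def test_planar_data_preserves_pairwise_distances(self, rng):
        coords2 = rng.random((8, 2))
        basis = np.linalg.qr(rng.standard_normal((18, 2)))[0]
        X = coords2 @ basis.T
        proj, ratio = pca2(X)
        d_orig = np.linalg.norm(coords2[:, None] - coords2[None], axis=-1)
        d_proj = np.linalg.norm(proj[:, None] - proj[None], axis=-1)
        assert np.allclose(d_orig, d_proj, atol=1e-9)
        assert ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_spreads_variance(self, rng):
        X = rng.standard_normal((400, 10))
        _, ratio = pca2(X)
        assert np.all(ratio < 0.2)
        assert ratio[0] >= ratio[1]

    def test_deterministic_sign_convention(self, rng):
        X = rng.random((6, 5))
        p1, _ = pca2(X)
        p2, _ = pca2(X)
        assert np.array_equal(p1, p2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pca2(np.ones((4, 3)))


def test_descriptor_vector_validation():
    with pytest.raises(ValueError):
        DescriptorVector("e", "c", np.array([[1.0, 2.0]]))
    with pytest.raises(ValueError):
        DescriptorVector("e", "c", np.array([1.0, np.nan]))
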