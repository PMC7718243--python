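"""ICA + GMM segmentation mechanics and label-assignment rules."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from qmtcest.segmentation import (ICResult, ObservationMatrix,
                                  SegmentationResult, assign_labels,
                                  build_observation_matrix, dice_coefficient,
                                  fit_gmm, nmi_to_reference, quantize,
                                  run_ica, sort_and_weight_ics)


def toy_matrix(data):
    n = data.shape[0]
    side = int(np.ceil(np.sqrt(n)))
    idx = np.argwhere(np.ones((side, side), dtype=bool))[:n]
    return ObservationMatrix(data=data, voxel_index=idx,
                             grid_shape=(side, side))


class TestObservationMatrix:
    def test_shape_two_maps_plus_frames(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        t1 = np.full((4, 4), 0.5)
        t2 = np.full((4, 4), 0.2)
        frames = [np.ones((3, 4, 4)), np.ones((1, 4, 4))]
        m = build_observation_matrix(t1, t2, frames, mask)
        assert m.data.shape == (2, 6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_observation_matrix(np.ones((4, 4)), np.ones((4, 4)), [],
                                     np.zeros((4, 4), dtype=bool))

    def test_row_order_is_row_major(self):
        mask = np.ones((3, 3), dtype=bool)
        t1 = np.arange(9.0).reshape(3, 3)
        m = build_observation_matrix(t1, t1, [], mask)
        assert np.array_equal(m.data[:, 0], np.arange(9.0))

    def test_to_image_round_trip(self):
        mask = np.ones((3, 3), dtype=bool)
        t1 = np.arange(9.0).reshape(3, 3)
        m = build_observation_matrix(t1, t1, [], mask)
        assert np.array_equal(m.to_image(m.data[:, 0]), t1)


class TestICA:
    def test_recovers_independent_sources(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(-1, 1, (3000, 3))
        mixing = np.array([[1.0, 0.4, 0.2],
                           [0.3, 1.0, 0.5],
                           [0.2, 0.3, 1.0]])
        x = s @ mixing.T
        res = run_ica(toy_matrix(x), seed=0)
        corr = np.abs(np.corrcoef(res.scores.T, s.T)[:3, 3:])
        # each source matched by some component up to sign/permutation
        assert np.all(corr.max(axis=0) > 0.95)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (500, 3)) @ rng.normal(size=(3, 3))
        a = run_ica(toy_matrix(x), seed=3)
        b = run_ica(toy_matrix(x), seed=3)
        assert np.array_equal(a.scores, b.scores)

    def test_rank_deficient_input_fails_loudly(self):
        col = np.linspace(0, 1, 200)[:, None]
        x = np.hstack([col, 2 * col, -col])
        with pytest.raises(RuntimeError):
            run_ica(toy_matrix(x), seed=0)


class TestNMISorting:
    def test_identical_image_has_unit_nmi(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=1000)
        assert nmi_to_reference(img, img) == pytest.approx(1.0)

    def test_independent_images_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=5000)
        b = rng.normal(size=5000)
        assert nmi_to_reference(a, b) < 0.05

    def test_constant_image_defined_zero(self):
        assert nmi_to_reference(np.zeros(100), np.arange(100.0)) == 0.0

    def test_matches_entropy_counting_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=2000)
        b = a + rng.normal(0, 0.5, size=2000)
        qa, qb = quantize(a, 8), quantize(b, 8)
        joint = np.zeros((8, 8))
        for x, y in zip(qa, qb):
            joint[x, y] += 1
        joint /= joint.sum()
        pa, pb = joint.sum(1), joint.sum(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.nansum(joint * np.log(joint / np.outer(pa, pb)))
            ha = -np.nansum(pa * np.log(pa))
            hb = -np.nansum(pb * np.log(pb))
        oracle = mi / ((ha + hb) / 2.0)
        got = nmi_to_reference(a, b, bins=8)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_sorting_ascends_and_weights_apply(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=2000)
        ics = ICResult(
            scores=np.column_stack([ref + rng.normal(0, 0.1, 2000),   # high NMI
                                    rng.normal(size=2000),            # low
                                    ref + rng.normal(0, 1.0, 2000)]), # middle
            mixing=np.eye(3), unmixing=np.eye(3),
            nmi_scores=np.full(3, np.nan), weights=np.ones(3))
        out = sort_and_weight_ics(ics, ref, "22Rv1")
        assert np.all(np.diff(out.nmi_scores) >= 0)
        # the noisy-independent component must sort first (IC1)
        assert np.corrcoef(out.scores[:, 0], ref)[0, 1] ** 2 < 0.05
        assert np.allclose(out.weights, [2.0, 3.0, 1.0])


class TestGMM:
    def _clusters(self, seed=0):
        rng = np.random.default_rng(seed)
        centres = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6],
                            [6, 6, 6]], dtype=float)
        x = np.vstack([rng.normal(c, 0.4, size=(120, 3)) for c in centres])
        labels = np.repeat(np.arange(5), 120)
        return x, labels

    def test_separated_clusters_recovered(self):
        x, labels = self._clusters()
        res = fit_gmm(toy_matrix(x), x, seed=0)
        assert adjusted_rand_score(labels, res.voxel_clusters) >= 0.95

    def test_deterministic_under_seed(self):
        x, _ = self._clusters(1)
        a = fit_gmm(toy_matrix(x), x, seed=2)
        b = fit_gmm(toy_matrix(x), x, seed=2)
        assert np.array_equal(a.voxel_clusters, b.voxel_clusters)

    def test_single_component_matches_sample_moments(self):
        rng = np.random.default_rng(6)
        x = rng.normal([1.0, -2.0, 0.5], [0.5, 1.0, 2.0], size=(4000, 3))
        res = fit_gmm(toy_matrix(x), x, k=1, seed=0)
        assert np.allclose(res.cluster_means[0], x.mean(0), rtol=0.01,
                           atol=0.01)
        assert np.allclose(res.cluster_covariances[0], np.cov(x.T),
                           rtol=0.05, atol=0.02)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(toy_matrix(np.zeros((10, 3))), np.zeros((10, 3)))


def manual_result(means, weights=None, n_per=20):
    """A SegmentationResult with the given cluster means for rule tests."""
    means = np.asarray(means, dtype=float)
    k = means.shape[0]
    weights = np.ones(k) / k if weights is None else np.asarray(weights)
    clusters = np.repeat(np.arange(k), n_per)
    post = np.eye(k)[clusters]
    side = int(np.ceil(np.sqrt(k * n_per)))
    idx = np.argwhere(np.ones((side, side), dtype=bool))[:k * n_per]
    obs = ObservationMatrix(data=np.zeros((k * n_per, 3)), voxel_index=idx,
                            grid_shape=(side, side))
    return SegmentationResult(cluster_means=means,
                              cluster_covariances=np.tile(np.eye(3), (k, 1, 1)),
                              cluster_weights=weights, cluster_labels=None,
                              voxel_clusters=clusters, posteriors=post,
                              observation=obs)


class TestAssignLabels:
    def test_largest_ic1_magnitude_is_blood(self):
        means = np.array([[5.0, 1, 1], [1.0, 2, 0], [0.5, -1, 0],
                          [-0.2, 0, 1], [0.1, 3, 2]])
        res = assign_labels(manual_result(means), "DU145")
        assert res.cluster_labels[0] == "blood_edema"

    def test_reflections_put_blood_in_first_octant(self):
        means = np.array([[-3.0, 2, -1], [0.5, -2, 0], [0.2, -1, 0],
                          [0.1, 0.5, 0], [0.3, 2, 0]])
        res = assign_labels(manual_result(means), "DU145")
        assert res.cluster_labels[0] == "blood_edema"
        # reflected blood mean (3, 2, 1): IC1 and IC3 flipped, IC2 kept,
        # so the remaining ranking uses the original IC2 values
        assert res.cluster_labels[1] == "muscle"
        assert res.cluster_labels[4] == "tumour"

    def test_du145_step3_order(self):
        means = np.array([[9.0, 1, 1], [0.1, -2, 0], [0.2, -1, 0],
                          [0.3, 0.5, 0], [0.4, 2, 0]])
        res = assign_labels(manual_result(means), "DU145")
        assert [res.cluster_labels[c] for c in (1, 2, 3, 4)] == \
            ["muscle", "muscle_connective", "necrosis", "tumour"]

    def test_22rv1_step3_order(self):
        means = np.array([[9.0, 1, 1], [0.1, -2, 0], [0.2, -1, 0],
                          [0.3, 0.5, 0], [0.4, 2, 0]])
        res = assign_labels(manual_result(means), "22Rv1")
        assert [res.cluster_labels[c] for c in (1, 2, 3, 4)] == \
            ["tumour", "muscle_connective", "necrosis", "muscle"]

    def test_labels_are_a_bijection(self):
        means = np.array([[9.0, 1, 1], [0.1, -2, 0], [0.2, -1, 0],
                          [0.3, 0.5, 0], [0.4, 2, 0]])
        res = assign_labels(manual_result(means), "22Rv1")
        assert sorted(res.cluster_labels) == [0, 1, 2, 3, 4]
        assert len(set(res.cluster_labels.values())) == 5

    def test_sign_flip_invariance(self):
        """Negating every IC leaves the final voxel labels unchanged."""
        rng = np.random.default_rng(7)
        centres = np.array([[6, 0.2, 0], [0, -2, 0], [0.2, -1, 0.5],
                            [-0.1, 0.5, 1], [0.1, 2, -0.5]])
        x = np.vstack([rng.normal(c, 0.15, size=(80, 3)) for c in centres])
        mat = toy_matrix(x)
        a = assign_labels(fit_gmm(mat, x, seed=1), "22Rv1")
        b = assign_labels(fit_gmm(mat, -x, seed=1), "22Rv1")
        la = np.array([a.cluster_labels[c] for c in a.voxel_clusters])
        lb = np.array([b.cluster_labels[c] for c in b.voxel_clusters])
        assert np.array_equal(la, lb)


class TestDice:
    def test_perfect_and_empty(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        assert dice_coefficient(m, m) == 1.0
        assert dice_coefficient(np.zeros_like(m), np.zeros_like(m)) == 0.0

    def test_half_overlap(self):
        a = np.array([[True, True, False, False]])
        b = np.array([[True, False, True, False]])
        assert dice_coefficient(a, b) == pytest.approx(0.5)
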