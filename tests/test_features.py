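import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from shapetraj.features import (
    ClusterModel,
    amplitude_and_orientation,
    cluster_mean_vectors,
    cluster_parametrisation,
    similarity_matrix,
)


class TestSimilarity:
    def test_diagonal_is_four_for_nonzero_momenta(self, rng):
        x = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        s = similarity_matrix(x, b)
        np.testing.assert_allclose(np.diag(s), 4.0, rtol=1e-12)

    def test_coincident_points_opposite_momenta(self):
        x = np.zeros((2, 3))
        b = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        s = similarity_matrix(x, b)
        assert s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_printed_arithmetic_example(self):
        # unit separation, identical unit momenta: -5 + 4 - 0 = -1
        x = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 1.0, 0], [0.0, 1.0, 0]])
        s = similarity_matrix(x, b, normalise_dist=False)
        assert s[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_distance_normalisation(self):
        x = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        b = np.ones((2, 3))
        s = similarity_matrix(x, b, normalise_dist=True, lambda_v=11.0)
        assert s[0, 1] == pytest.approx(-5.0 + 4.0, abs=1e-12)

    def test_zero_momentum_cosine_convention(self):
        x = np.zeros((2, 3))
        b = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        s = similarity_matrix(x, b)
        # cos(0-vector, anything) = 0 -> 2*(0+1) - |0 - 1| = 1
        assert s[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.isfinite(s).all()


def planted_blobs(rng, n_per=12, separation=8.0):
    x = np.vstack(
        [
            rng.normal(0, 0.5, size=(n_per, 3)),
            rng.normal(0, 0.5, size=(n_per, 3)) + [separation, 0, 0],
        ]
    )
    b = np.vstack(
        [
            np.tile([1.0, 0, 0], (n_per, 1)),
            np.tile([0, 1.0, 0], (n_per, 1)),
        ]
    )
    truth = np.repeat([0, 1], n_per)
    return x, b, truth


class TestSpectralClustering:
    def test_planted_partition_recovered_exactly(self, rng):
        x, b, truth = planted_blobs(rng)
        s = similarity_matrix(x, b, normalise_dist=False)
        model = cluster_parametrisation(s, n_clusters=2, seed=0, n_init=50)
        agree = max(
            np.mean(model.labels == truth), np.mean(model.labels == 1 - truth)
        )
        assert agree == 1.0

    def test_each_point_its_own_cluster_when_k_equals_n(self, rng):
        x = rng.normal(size=(5, 3)) * 5
        b = rng.normal(size=(5, 3))
        s = similarity_matrix(x, b)
        model = cluster_parametrisation(s, n_clusters=5, seed=0, n_init=10)
        assert len(np.unique(model.labels)) == 5

    def test_seeded_determinism_and_partition_stability(self, rng):
        x, b, truth = planted_blobs(rng)
        s = similarity_matrix(x, b, normalise_dist=False)
        m1 = cluster_parametrisation(s, n_clusters=2, seed=7, n_init=30)
        m2 = cluster_parametrisation(s, n_clusters=2, seed=7, n_init=30)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        m3 = cluster_parametrisation(s, n_clusters=2, seed=8, n_init=30)
        agree = max(
            np.mean(m3.labels == m1.labels), np.mean(m3.labels == 1 - m1.labels)
        )
        assert agree == 1.0  # same partition under a different seed

    def test_too_many_clusters_rejected(self, rng):
        s = similarity_matrix(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            cluster_parametrisation(s, n_clusters=4, seed=0, n_init=5)


class TestClusterMeans:
    def test_constant_rows_give_that_vector(self):
        model = ClusterModel(
            labels=np.array([0, 0, 1, 1]),
            similarity=np.zeros((4, 4)),
            n_clusters=2,
            seed=0,
            n_init=1,
            inertia=0.0,
        )
        theta = np.tile([1.0, 2.0, 3.0], (4, 1))
        nu = cluster_mean_vectors(model, theta)
        np.testing.assert_allclose(nu, [[1, 2, 3], [1, 2, 3]])

    def test_opposite_vectors_cancel(self):
        model = ClusterModel(
            labels=np.array([0, 0]),
            similarity=np.zeros((2, 2)),
            n_clusters=1,
            seed=0,
            n_init=1,
            inertia=0.0,
        )
        theta = np.array([[1.0, 1, 1], [-1.0, -1, -1]])
        np.testing.assert_allclose(cluster_mean_vectors(model, theta), [[0, 0, 0]])

    def test_matches_pandas_groupby_oracle(self, rng):
        labels = rng.integers(0, 4, 40)
        while len(np.unique(labels)) < 4:
            labels = rng.integers(0, 4, 40)
        theta = rng.normal(size=(40, 3))
        model = ClusterModel(
            labels=labels,
            similarity=np.zeros((40, 40)),
            n_clusters=4,
            seed=0,
            n_init=1,
            inertia=0.0,
        )
        nu = cluster_mean_vectors(model, theta)
        oracle = (
            pd.DataFrame(theta)
            .groupby(labels)
            .mean()
            .sort_index()
            .to_numpy()
        )
        np.testing.assert_allclose(nu, oracle, atol=1e-12)


class TestDescriptors:
    def test_amplitude_and_axis_angles_closed_form(self):
        nu = np.zeros((2, 1, 3))
        nu[0, 0] = [3.0, 0, 0]
        nu[1, 0] = [0.0, 0, 0]
        table = amplitude_and_orientation(nu)
        assert table["amp_c1"][0] == pytest.approx(3.0)
        assert table["amp_c1"][1] == pytest.approx(0.0)

    def test_shared_direction_gives_zero_orientation_scores(self, rng):
        d = np.array([0.6, 0.8, 0.0])
        nu = np.tile(d, (10, 1, 1)) * rng.uniform(0.5, 2.0, size=(10, 1, 1))
        table = amplitude_and_orientation(nu)
        np.testing.assert_allclose(table["ori_c1"], 0.0, atol=1e-12)

    def test_rotated_directions_separate_groups(self, rng):
        n = 50
        d0 = np.array([0.25, 0.55, 0.8])
        d0 /= np.linalg.norm(d0)
        R = Rotation.from_rotvec(np.deg2rad(30) * np.array([1.0, 0, 0]))
        nu = np.zeros((2 * n, 1, 3))
        for i in range(2 * n):
            d = d0 if i < n else R.apply(d0)
            wob = Rotation.from_rotvec(rng.normal(0, np.deg2rad(5), 3))
            nu[i, 0] = wob.apply(d)  # fixed amplitude 1: orientation-only effect
        table = amplitude_and_orientation(nu)
        from scipy import stats as sps

        t_ori = sps.ttest_ind(table["ori_c1"][:n], table["ori_c1"][n:]).statistic
        assert abs(t_ori) > 5
        # amplitudes are identical by construction: no group difference
        amp_gap = abs(table["amp_c1"][:n].mean() - table["amp_c1"][n:].mean())
        assert amp_gap < 1e-9

    def test_amplitude_orientation_uncorrelated_on_isotropic_input(self, rng):
        nu = rng.normal(size=(1000, 1, 3))
        table = amplitude_and_orientation(nu)
        r = np.corrcoef(table["amp_c1"], table["ori_c1"])[0, 1]
        assert abs(r) < 0.1

    def test_global_rotation_leaves_descriptors_stable(self, rng):
        nu = rng.normal(size=(30, 2, 3))
        R = Rotation.from_rotvec(np.deg2rad(15) * np.array([0.3, 0.5, 0.8]))
        nu_rot = R.apply(nu.reshape(-1, 3)).reshape(nu.shape)
        t0 = amplitude_and_orientation(nu)
        t1 = amplitude_and_orientation(nu_rot)
        for k in (1, 2):
            np.testing.assert_allclose(
                t1[f"amp_c{k}"], t0[f"amp_c{k}"], atol=1e-6
            )
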