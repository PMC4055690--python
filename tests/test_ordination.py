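import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ampdyn.io_formats import DistanceMatrix
from ampdyn.ordination import cap, mantel, nmds, pcoa, procrustes


def euclidean_matrix(points, metric="bray_curtis"):
    ids = [f"s{i}" for i in range(len(points))]
    values = squareform(pdist(np.asarray(points, dtype=float)))
    return DistanceMatrix(ids, values / max(values.max(), 1.0), metric)


class TestPcoa:
    def test_zero_matrix_gives_zero_configuration(self):
        D = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        res = pcoa(D, k=2)
        assert np.allclose(res.configuration, 0.0)

    def test_collinear_points_recovered(self):
        points = np.array([[0.0], [1.0], [2.5], [4.0]])
        D = euclidean_matrix(points)
        res = pcoa(D)
        eigval = res.eigenvalues
        assert (eigval > 1e-10).sum() == 1
        rec = squareform(pdist(res.configuration))
        assert np.allclose(rec, D.values, atol=1e-10)

    def test_planar_configuration_two_axes(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(6, 2))
        res = pcoa(euclidean_matrix(points))
        eigval = res.eigenvalues
        assert (eigval > 1e-10).sum() == 2
        assert eigval[:2].sum() == pytest.approx(eigval[eigval > 0].sum())

    def test_eigenvalues_decreasing(self):
        rng = np.random.default_rng(1)
        res = pcoa(euclidean_matrix(rng.normal(size=(7, 3))))
        assert (np.diff(res.eigenvalues) <= 1e-12).all()


class TestNmds:
    def test_embeddable_configuration_reaches_low_stress(self):
        rng = np.random.default_rng(0)
        D = euclidean_matrix(rng.normal(size=(10, 2)))
        res = nmds(D, k=2, n_starts=4, seed=0)
        assert res.stress < 0.01

    def test_stress_trace_non_increasing(self):
        rng = np.random.default_rng(1)
        D = euclidean_matrix(rng.normal(size=(9, 4)))
        res = nmds(D, k=2, n_starts=2, seed=1)
        trace = np.array(res.stress_trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_rank_only_dependence(self):
        rng = np.random.default_rng(2)
        D = euclidean_matrix(rng.normal(size=(9, 3)))
        transformed = DistanceMatrix(D.sample_ids, D.values**1.7, D.metric)
        s1 = nmds(D, k=2, n_starts=8, seed=3).stress
        s2 = nmds(transformed, k=2, n_starts=8, seed=3).stress
        assert s1 == pytest.approx(s2, abs=5e-3)

    def test_two_clusters_separate_on_first_axis(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            a = rng.normal(0.0, 0.05, size=(5, 2))
            b = rng.normal(0.0, 0.05, size=(5, 2)) + 10.0
            D = euclidean_matrix(np.vstack([a, b]))
            res = nmds(D, k=2, n_starts=4, seed=seed)
            axis = res.configuration[:, 0]
            gap_ok = (axis[:5].max() < axis[5:].min()) or (axis[5:].max() < axis[:5].min())
            assert gap_ok

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(DistanceMatrix(list("abc"), np.zeros((3, 3))), k=2)


class TestProcrustes:
    def test_congruent_configurations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        Y = 3.0 * X @ R + np.array([5.0, -2.0])
        res = procrustes(X, Y, n_perm=99, seed=0)
        assert res.m2 == pytest.approx(0.0, abs=1e-12)
        assert res.correlation == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_minimum_p_is_permutation_bound(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        res = procrustes(X, X.copy(), n_perm=199, seed=0)
        assert res.p == pytest.approx(1 / 200)

    def test_column_padding(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        Y = rng.normal(size=(8, 2))
        res = procrustes(X, Y, n_perm=0, seed=0)
        assert 0.0 <= res.m2 <= 1.0

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(3)
        X = rng.normal(size=(9, 2))
        Y = rng.normal(size=(9, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        res = procrustes(X, Y, n_perm=0, seed=0)
        assert res.m2 == pytest.approx(disparity, abs=1e-10)


class TestMantel:
    def test_identity(self):
        rng = np.random.default_rng(0)
        D = euclidean_matrix(rng.normal(size=(8, 2)))
        res = mantel(D, D, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        D1 = euclidean_matrix(rng.normal(size=(7, 2)))
        values = np.clip(0.1 + 0.5 * D1.values, 0, 1)
        np.fill_diagonal(values, 0.0)
        res = mantel(D1, DistanceMatrix(D1.sample_ids, values, D1.metric), n_perm=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        values = np.full((4, 4), 0.3)
        np.fill_diagonal(values, 0.0)
        rng_D = euclidean_matrix(np.random.default_rng(0).normal(size=(4, 2)))
        D = DistanceMatrix(rng_D.sample_ids, values)
        with pytest.raises(ValueError, match="constant"):
            mantel(rng_D, D, n_perm=10)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(4)
        D1 = euclidean_matrix(rng.normal(size=(4, 2)))
        D2 = euclidean_matrix(rng.normal(size=(4, 2)))
        res = mantel(D1, D2, exact=True)
        # independent enumeration with plain numpy
        iu = np.triu_indices(4, k=1)
        v1 = D1.values[iu]
        r_obs = np.corrcoef(v1, D2.values[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            permuted = D2.values[np.ix_(perm, perm)]
            if np.corrcoef(v1, permuted[iu])[0, 1] >= r_obs - 1e-15:
                count += 1
        assert res.p == pytest.approx(count / len(perms))
        assert res.r == pytest.approx(r_obs)


class TestCap:
    def _community_matrix(self, seed=0, n=16):
        rng = np.random.default_rng(seed)
        gradient = np.linspace(-1, 1, n)
        points = np.column_stack([gradient, 0.3 * rng.normal(size=n)])
        return euclidean_matrix(points), gradient

    def test_informative_constraint_is_significant(self):
        D, gradient = self._community_matrix()
        res = cap(D, gradient[:, None], n_perm=199, seed=0)
        assert res.p <= 0.05
        assert res.proportion_constrained > 0.5

    def test_constant_constraint_rejected(self):
        D, _ = self._community_matrix()
        with pytest.raises(ValueError, match="constraints"):
            cap(D, np.ones((D.n, 1)), n_perm=10)

    def test_collinear_column_dropped(self):
        D, gradient = self._community_matrix()
        X = np.column_stack([gradient, 2.0 * gradient])
        res = cap(D, X, n_perm=49, seed=0)
        assert res.rank == 1

    def test_temperature_recovered_from_simulation(self, default_experiment):
        from ampdyn.beta import distance_matrix

        exp = default_experiment
        table = exp.tables["V4"]
        order = sorted(table.sample_ids)
        D = distance_matrix(table.select_samples(order), "bray_curtis")
        X = exp.design.covariate_matrix(["temperature", "mlss", "svi", "bod"], order)
        res = cap(D, X, n_perm=199, seed=0)
        assert res.p <= 0.05

    def test_cross_check_against_vegan_style_inertia(self):
        # constrained + residual inertia must add to total PCoA inertia
        D, gradient = self._community_matrix(seed=2)
        res = cap(D, gradient[:, None], n_perm=0, seed=0)
        from ampdyn.ordination import pcoa_axes

        _, total = pcoa_axes(D)
        constrained = res.proportion_constrained * total
        assert 0.0 < constrained < total
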