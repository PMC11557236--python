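"""Global analysis: ensembles, correlation vectors, UPGMA, SVD, ANOVA."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import leaves_list

from poroident import (Grid1D, ParameterSpace, Protocol, SampleSet,
                       cluster_parameters, correlation_vectors, full_factorial,
                       run_ensemble, sensitivity_indices, svd_identifiability)
from poroident.global_identifiability import (CorrelationMatrix,
                                              EnsembleResult,
                                              unsigned_cosine_distance)

from _oracles import naive_upgma_heights, pearson_two_pass


def synthetic_ensemble(space, design, fn, n_times=6):
    """Fabricate an EnsembleResult whose F_z obeys a known function."""
    t = np.linspace(1.0, 10.0, n_times)
    F = np.stack([fn(row, t) for row in design.data])
    return EnsembleResult(
        samples=design, times=t, segments=["ramp 1"] * n_times, forces=F,
        retained=np.arange(design.n_samples), excluded=[])


@pytest.fixture(scope="module")
def small_space(space):
    return ParameterSpace.subset(space, ["E", "nu", "k0"])


class TestRunEnsemble:
    def test_small_factorial_smoke(self, space, coarse_grid):
        sub = ParameterSpace.subset(space, ["k0", "fcd0"])
        design = full_factorial(sub, 3)
        data = np.tile(space.midpoint, (design.n_samples, 1))
        data[:, space.index("k0")] = design.data[:, 0]
        data[:, space.index("fcd0")] = design.data[:, 1]
        samples = SampleSet(data, space.names, "factorial", levels=3)
        ens = run_ensemble(samples, grid=coarse_grid)
        assert ens.n_retained == 9
        assert not ens.excluded
        assert ens.forces.shape == (9, 72)
        assert np.all(np.isfinite(ens.forces))

    def test_invalid_sample_lands_in_exclusion_log(self, space, coarse_grid):
        data = np.tile(space.midpoint, (3, 1))
        data[1, space.index("nu")] = 0.6  # violates nu < 0.5
        samples = SampleSet(data, space.names, "uniform", seed=0)
        ens = run_ensemble(samples, grid=coarse_grid)
        assert ens.n_retained == 2
        assert len(ens.excluded) == 1
        assert ens.excluded[0][0] == samples.ids[1]
        assert "error" in ens.excluded[0][1]

    def test_cache_makes_reruns_idempotent(self, space, coarse_grid, tmp_path):
        samples = SampleSet(np.tile(space.midpoint, (2, 1)) *
                            [[1.0], [1.001]], space.names, "uniform", seed=0)
        cache = tmp_path / "cache.npz"
        first = run_ensemble(samples, grid=coarse_grid, cache_path=cache)
        second = run_ensemble(samples, grid=coarse_grid, cache_path=cache)
        assert first.n_simulated == 2
        assert second.n_simulated == 0
        assert np.array_equal(first.forces, second.forces)


class TestCorrelationVectors:
    def test_perfect_linear_dependence(self, small_space):
        design = full_factorial(small_space, 3)
        ens = synthetic_ensemble(small_space, design,
                                 lambda row, t: 2.0 * row[0] + 5.0 + 0.0 * t)
        corr = correlation_vectors(ens)
        assert np.allclose(corr.values[0], 1.0, atol=1e-12)

    def test_unused_parameter_exactly_zero_on_balanced_design(self,
                                                              small_space):
        design = full_factorial(small_space, 3)
        ens = synthetic_ensemble(small_space, design,
                                 lambda row, t: row[0] * t)
        corr = correlation_vectors(ens)
        assert np.all(corr.values[1] == 0.0)
        assert np.all(corr.values[2] == 0.0)

    def test_matches_two_pass_oracle(self, small_space, rng):
        data = small_space.unscale(rng.random((8, 3)))
        design = SampleSet(data, small_space.names, "uniform", seed=0)
        ens = synthetic_ensemble(small_space, design,
                                 lambda row, t: np.sin(row[0] / 100.0) * t
                                 + row[2] * 50.0)
        corr = correlation_vectors(ens)
        for i in range(3):
            for jt in range(ens.times.size):
                expected = pearson_two_pass(data[:, i], ens.forces[:, jt])
                assert corr.values[i, jt] == pytest.approx(expected,
                                                           abs=1e-12)

    def test_affine_rescaling_invariance(self, small_space):
        design = full_factorial(small_space, 3)
        fn = lambda row, t: row[0] * t + row[2] * 1e5
        ens_nat = synthetic_ensemble(small_space, design, fn)
        scaled_design = SampleSet(small_space.scale(design.data),
                                  small_space.names, "factorial", levels=3)
        ens_scl = EnsembleResult(
            samples=scaled_design, times=ens_nat.times,
            segments=ens_nat.segments, forces=ens_nat.forces,
            retained=ens_nat.retained, excluded=[])
        assert np.allclose(correlation_vectors(ens_nat).values,
                           correlation_vectors(ens_scl).values, atol=1e-12)

    def test_too_few_samples_rejected(self, small_space):
        design = SampleSet(np.tile(small_space.midpoint, (2, 1)),
                           small_space.names, "uniform", seed=0)
        ens = synthetic_ensemble(small_space, design, lambda row, t: t)
        with pytest.raises(ValueError, match="3 retained"):
            correlation_vectors(ens)


class TestClustering:
    def test_unsigned_distance_definition(self, rng):
        u = rng.standard_normal(10)
        assert unsigned_cosine_distance(u, u) == pytest.approx(0.0, abs=1e-14)
        assert unsigned_cosine_distance(u, -u) == pytest.approx(0.0, abs=1e-14)
        v = rng.standard_normal(10)
        d = unsigned_cosine_distance(u, v)
        assert 0.0 <= d <= 1.0

    def test_duplicated_parameter_merges_at_zero_height(self):
        vals = np.array([[1.0, 0.5, -0.2, 0.1],
                         [2.0, 1.0, -0.4, 0.2],  # clone (scaled copy)
                         [0.0, 1.0, 1.0, -1.0]])
        corr = CorrelationMatrix(vals, ("a", "b", "c"), [str(i) for i in
                                                         range(4)])
        tree = cluster_parameters(corr)
        assert tree.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        # the zero-height merge joins the clone pair a, b
        left, right = int(tree.linkage_matrix[0, 0]), int(
            tree.linkage_matrix[0, 1])
        assert {tree.leaf_names[left], tree.leaf_names[right]} == {"a", "b"}

    def test_merge_heights_match_naive_upgma(self, rng):
        vals = rng.standard_normal((5, 12))
        corr = CorrelationMatrix(vals, ("p1", "p2", "p3", "p4", "p5"),
                                 [str(i) for i in range(12)])
        tree = cluster_parameters(corr)
        P = 5
        D = np.zeros((P, P))
        order = sorted(corr.parameter_names)
        V = vals[[corr.parameter_names.index(n) for n in order]]
        for i in range(P):
            for j in range(P):
                if i != j:
                    D[i, j] = unsigned_cosine_distance(V[i], V[j])
        assert np.allclose(sorted(tree.merge_heights), naive_upgma_heights(D),
                           atol=1e-12)

    def test_heights_non_decreasing_with_all_leaves(self, rng):
        vals = rng.standard_normal((6, 20))
        corr = CorrelationMatrix(vals, tuple(f"q{i}" for i in range(6)),
                                 [str(i) for i in range(20)])
        tree = cluster_parameters(corr)
        assert np.all(np.diff(tree.merge_heights) >= -1e-12)
        assert sorted(tree.leaf_order()) == sorted(corr.parameter_names)
        assert len(leaves_list(tree.linkage_matrix)) == 6

    def test_zero_norm_vector_flagged_no_direct_effect(self):
        vals = np.array([[1.0, 2.0, 3.0],
                         [0.0, 0.0, 0.0],
                         [3.0, -1.0, 0.5]])
        corr = CorrelationMatrix(vals, ("a", "b", "c"), ["0", "1", "2"])
        tree = cluster_parameters(corr)
        assert tree.no_effect == ("b",)
        # distance 1 to every other parameter
        i = tree.leaf_names.index("b")
        from scipy.spatial.distance import squareform
        D = squareform(tree.distances)
        assert np.allclose(np.delete(D[i], i), 1.0)


class TestSVD:
    def test_rank_deficiency_gives_zero_eigenvalue(self):
        vals = np.array([[1.0, 0.0, 1.0], [1.0, 0.0, 1.0],
                         [0.0, 1.0, 0.0]])
        rep = svd_identifiability(CorrelationMatrix(vals, ("a", "b", "c"),
                                                    ["0", "1", "2"]))
        assert rep.eigenvalues[-1] == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_rows_share_spectrum_equally(self):
        vals = np.eye(4, 9)
        rep = svd_identifiability(CorrelationMatrix(
            vals, ("a", "b", "c", "d"), [str(i) for i in range(9)]))
        assert np.allclose(rep.normalized_pct, 25.0, atol=1e-9)
        assert rep.n_identifiable == 4

    def test_matches_gram_matrix_eigendecomposition(self, rng):
        vals = rng.standard_normal((4, 10))
        corr = CorrelationMatrix(vals, ("a", "b", "c", "d"),
                                 [str(i) for i in range(10)])
        rep = svd_identifiability(corr)
        gram_eigs = np.sort(np.linalg.eigvalsh(vals @ vals.T))[::-1]
        assert np.allclose(rep.eigenvalues, gram_eigs, atol=1e-10)

    def test_recovers_rank_of_linear_weight_matrix(self, small_space):
        # F(t) = sum_i w_i(t) theta_i with a rank-2 weight matrix
        design = full_factorial(small_space, 3)
        t = np.linspace(1.0, 10.0, 8)
        w = np.stack([t, t ** 2, t + 0.5 * t ** 2])  # rank 2
        ens = synthetic_ensemble(small_space, design,
                                 lambda row, tt: row @ np.stack(
                                     [tt, tt ** 2, tt + 0.5 * tt ** 2]),
                                 n_times=8)
        rep = svd_identifiability(correlation_vectors(ens))
        rank = int(np.sum(rep.eigenvalues > 1e-10 * rep.eigenvalues[0]))
        assert rank == np.linalg.matrix_rank(w)

    def test_normalization_and_orthonormality(self, rng):
        vals = rng.standard_normal((6, 15))
        rep = svd_identifiability(CorrelationMatrix(
            vals, tuple(f"p{i}" for i in range(6)),
            [str(i) for i in range(15)]))
        assert rep.normalized_pct.sum() == pytest.approx(100.0, abs=1e-9)
        VtV = rep.eigenvectors.T @ rep.eigenvectors
        assert np.allclose(VtV, np.eye(6), atol=1e-10)

    def test_raw_singular_value_switch(self, rng):
        vals = rng.standard_normal((4, 7))
        corr = CorrelationMatrix(vals, ("a", "b", "c", "d"),
                                 [str(i) for i in range(7)])
        sq = svd_identifiability(corr)
        raw = svd_identifiability(corr, use_squares=False)
        assert np.allclose(raw.eigenvalues ** 2, sq.eigenvalues, rtol=1e-12)


class TestSensitivityIndices:
    def test_additive_model_first_order_sums_to_one(self, small_space):
        design = full_factorial(small_space, 3)
        ens = synthetic_ensemble(
            small_space, design,
            lambda row, t: np.sin(row[0]) + (row[1] + 0.01) ** 2 + 0.0 * t)
        sens = sensitivity_indices(ens)
        assert not sens.unbalanced
        S, ST = sens.first_order, sens.total
        assert np.allclose(S[0] + S[1], 1.0, atol=1e-10)
        assert np.allclose(S, ST, atol=1e-10)

    def test_pure_interaction_has_zero_first_order_indices(self, small_space):
        # centred levels: theta scaled to {-1, 0, 1} per factor
        design = full_factorial(small_space, 3)
        x = 2.0 * small_space.scale(design.data) - 1.0
        ens = synthetic_ensemble(small_space, design, lambda row, t: 0 * t)
        ens.forces = np.outer(x[:, 0] * x[:, 1], np.ones(ens.times.size))
        sens = sensitivity_indices(ens)
        assert np.allclose(sens.first_order[:2], 0.0, atol=1e-12)
        assert np.allclose(sens.total[:2], 1.0, atol=1e-12)

    def test_unused_parameter_has_zero_indices(self, small_space):
        design = full_factorial(small_space, 3)
        ens = synthetic_ensemble(small_space, design,
                                 lambda row, t: row[0] * t)
        sens = sensitivity_indices(ens)
        assert np.allclose(sens.first_order[1], 0.0, atol=1e-12)
        assert np.allclose(sens.total[1], 0.0, atol=1e-12)

    def test_first_order_bounded_by_total(self, small_space, rng):
        design = full_factorial(small_space, 3)
        ens = synthetic_ensemble(
            small_space, design,
            lambda row, t: row[0] * t + row[0] * row[1] * 0.3
            + np.cos(row[2] * 1e3))
        sens = sensitivity_indices(ens)
        assert np.all(sens.first_order <= sens.total + 1e-10)
        assert np.all(sens.first_order.sum(axis=0) <= 1.0 + 1e-10)

    def test_exclusions_set_unbalanced_flag(self, small_space):
        design = full_factorial(small_space, 3)
        t = np.linspace(1, 10, 4)
        F = np.stack([row[0] * t for row in design.data[:-1]])
        ens = EnsembleResult(samples=design, times=t, segments=["ramp 1"] * 4,
                             forces=F, retained=np.arange(26),
                             excluded=[("s26", "solver divergence")])
        assert sensitivity_indices(ens).unbalanced
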