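"""PCA, ESOM training, structure matrices and cluster extraction."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from das28ml.structure import (
    ClusterAssignment,
    DegenerateInputError,
    ESOMConfig,
    ESOMModel,
    assign_bmu,
    assign_bmus,
    cluster_stage_association,
    extract_clusters,
    p_matrix,
    pareto_radius,
    pca_project,
    scale_0_100,
    structure_matrices,
    train_esom,
    u_matrix,
    u_star_matrix,
    unscale_0_100,
)


class TestPCA:
    def test_perfectly_correlated_pair_concentrates_variance(self):
        x = np.arange(10.0)
        res = pca_project(np.column_stack([x, 3 * x + 1]))
        assert res.eigenvalues[0] == pytest.approx(2.0)

    def test_eigenvalue_sum_equals_dimension(self):
        rng = np.random.default_rng(1)
        res = pca_project(rng.normal(size=(40, 4)))
        assert res.eigenvalues.sum() == pytest.approx(4.0, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_matches_independent_eigensolver_on_hand_matrix(self):
        """3 x 2 example against a from-scratch correlation eigensolve."""
        M = np.array([[1.0, 2.0], [2.0, 1.0], [4.0, 6.0]])
        res = pca_project(M)
        Z = (M - M.mean(0)) / M.std(0, ddof=1)
        corr = Z.T @ Z / 2
        expected = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(res.eigenvalues, expected, atol=1e-9)

    def test_contributions_sum_to_100_per_component(self):
        rng = np.random.default_rng(2)
        res = pca_project(rng.normal(size=(30, 4)))
        assert np.allclose(res.contributions.sum(axis=0), 100.0, atol=1e-6)

    def test_constant_column_rejected(self):
        with pytest.raises(DegenerateInputError):
            pca_project(np.column_stack([np.arange(5.0), np.full(5, 2.0)]))


class TestScaling:
    def test_linear_map(self):
        scaled, _ = scale_0_100(np.array([[1.0], [2.0], [3.0]]))
        assert scaled.ravel().tolist() == [0.0, 50.0, 100.0]

    def test_constant_column_maps_to_zero(self):
        scaled, _ = scale_0_100(np.full((4, 1), 7.0))
        assert (scaled == 0).all()

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4)) * [1, 10, 100, 0.01]
        scaled, mm = scale_0_100(X)
        assert np.allclose(unscale_0_100(scaled, mm), X, atol=1e-9)


class TestESOM:
    def test_default_grid_has_4000_prototypes(self):
        assert ESOMConfig().n_neurons == 4000

    def test_prototype_dimension_matches_input(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        model = train_esom(X, ESOMConfig(rows=5, cols=6, epochs=2, seed=0))
        assert model.weights.shape == (30, 3)

    def test_training_on_repeated_point_converges(self):
        """Prototypes collapse toward a single repeated training point.

        The per-epoch worst prototype-to-point distance shrinks monotonically
        and ends below 1% of its initial value (spread random init).
        """
        x = np.array([5.0, -2.0, 7.0])
        X = np.tile(x, (40, 1))
        cfg = ESOMConfig(rows=10, cols=12, epochs=20, seed=1)
        rng = np.random.default_rng(99)
        init = rng.uniform(-10, 10, size=(cfg.n_neurons, 3))
        d0 = np.linalg.norm(init - x, axis=1).max()
        history = []
        train_esom(
            X,
            cfg,
            init_weights=init,
            epoch_callback=lambda e, w: history.append(
                np.linalg.norm(w - x, axis=1).max()
            ),
        )
        assert np.all(np.diff(history) <= 1e-12)
        assert history[-1] < 0.01 * d0

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(5).normal(size=(15, 2))
        cfg = ESOMConfig(rows=6, cols=8, epochs=3, seed=9)
        assert np.array_equal(train_esom(X, cfg).weights, train_esom(X, cfg).weights)

    def test_neighborhood_preservation_on_blobs(self):
        """Within-blob BMU grid distances are smaller than between-blob ones."""
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (30, 4))
        b = rng.normal(8, 1, (30, 4))
        Ds, _ = scale_0_100(np.vstack([a, b]))
        model = train_esom(Ds, ESOMConfig(rows=15, cols=20, seed=11))
        bmus = assign_bmus(model, Ds)
        pos = np.column_stack(divmod(bmus, 20)).astype(float)

        def tor_dist(p, q, rows=15, cols=20):
            dr = min(abs(p[0] - q[0]), rows - abs(p[0] - q[0]))
            dc = min(abs(p[1] - q[1]), cols - abs(p[1] - q[1]))
            return np.hypot(dr, dc)

        within = [tor_dist(pos[i], pos[j]) for i in range(30) for j in range(i + 1, 30)]
        between = [tor_dist(pos[i], pos[j]) for i in range(30) for j in range(30, 60)]
        assert np.mean(within) < np.mean(between)


class TestBMU:
    @pytest.fixture()
    def model(self):
        weights = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        return ESOMModel(weights=weights, config=ESOMConfig(rows=2, cols=3, epochs=1))

    def test_exact_prototype_match(self, model):
        assert assign_bmu(model, np.array([4.0])) == (1, 1)

    def test_single_neuron_grid(self):
        m = ESOMModel(weights=np.array([[1.0, 1.0]]), config=ESOMConfig(rows=1, cols=1))
        assert assign_bmu(m, np.array([9.0, 9.0])) == (0, 0)

    def test_tie_breaks_to_lowest_row_major_index(self, model):
        # 0.5 is equidistant from prototypes 0 and 1
        assert assign_bmu(model, np.array([0.5])) == (0, 0)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(DegenerateInputError):
            assign_bmu(model, np.array([1.0, 2.0]))


class TestUMatrix:
    def test_identical_prototypes_give_zero_heights(self):
        m = ESOMModel(weights=np.ones((12, 2)), config=ESOMConfig(rows=3, cols=4))
        assert (u_matrix(m) == 0).all()

    def test_1x2_grid_wrap_deduplicated(self):
        """Hand enumeration: each neuron's only distinct neighbor is the other."""
        m = ESOMModel(
            weights=np.array([[0.0], [3.0]]), config=ESOMConfig(rows=1, cols=2)
        )
        assert u_matrix(m).ravel().tolist() == [3.0, 3.0]

    def test_matches_brute_force_neighbor_average(self):
        """Exact agreement with a from-scratch toroidal Moore-neighbor mean."""
        rng = np.random.default_rng(21)
        for trial in range(5):
            W = rng.normal(size=(20, 3))
            m = ESOMModel(weights=W, config=ESOMConfig(rows=4, cols=5))
            got = u_matrix(m)
            grid = W.reshape(4, 5, 3)
            for r in range(4):
                for c in range(5):
                    nbrs = {
                        ((r + dr) % 4, (c + dc) % 5)
                        for dr in (-1, 0, 1)
                        for dc in (-1, 0, 1)
                        if (dr, dc) != (0, 0)
                    } - {(r, c)}
                    brute = np.mean(
                        [np.linalg.norm(grid[r, c] - grid[i, j]) for i, j in nbrs]
                    )
                    assert got[r, c] == pytest.approx(brute, abs=1e-9)


class TestParetoRadius:
    def test_two_points(self):
        assert pareto_radius(np.array([[0.0, 0.0], [3.0, 4.0]])) == pytest.approx(5.0)

    def test_equals_brute_force_percentile(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(10, 4))
        d = pdist(X)
        assert pareto_radius(X) == pytest.approx(np.percentile(d[d > 0], 20), abs=1e-12)
        assert pareto_radius(X) > 0

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            pareto_radius(np.ones((5, 3)))


class TestPMatrix:
    @pytest.fixture()
    def model(self):
        return ESOMModel(
            weights=np.array([[1.0], [10.0]]), config=ESOMConfig(rows=1, cols=2)
        )

    def test_hand_enumeration_boundary_inclusive(self, model):
        data = np.array([[0.0], [1.0], [2.0]])
        counts = p_matrix(model, data, r=1.0)
        assert counts.ravel().tolist() == [3, 0]

    def test_huge_radius_counts_everything(self, model):
        data = np.random.default_rng(0).normal(size=(7, 1))
        assert (p_matrix(model, data, r=1e6) == 7).all()

    def test_empty_data_counts_zero(self, model):
        assert (p_matrix(model, np.empty((0, 1)), r=1.0) == 0).all()

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(41)
        W = rng.normal(size=(12, 3))
        m = ESOMModel(weights=W, config=ESOMConfig(rows=3, cols=4))
        X = rng.normal(size=(25, 3))
        r = 1.3
        got = p_matrix(m, X, r).ravel()
        brute = [(np.linalg.norm(X - w, axis=1) <= r).sum() for w in W]
        assert got.tolist() == brute


class TestUStar:
    def test_mean_density_keeps_u(self):
        u = np.array([[2.0, 2.0, 2.0]])
        p = np.array([[3.0, 1.0, 5.0]])  # mean 3
        got = u_star_matrix(u, p)
        assert got[0, 0] == pytest.approx(2.0)

    def test_max_density_suppresses_u(self):
        u = np.array([[2.0, 2.0, 2.0]])
        p = np.array([[3.0, 1.0, 5.0]])
        assert u_star_matrix(u, p)[0, 2] == pytest.approx(0.0)

    def test_sparse_region_amplified_hand_value(self):
        # f = (1 - 5) / (3 - 5) = 2 at the p=1 neuron
        u = np.array([[2.0, 2.0, 2.0]])
        p = np.array([[3.0, 1.0, 5.0]])
        assert u_star_matrix(u, p)[0, 1] == pytest.approx(4.0)

    def test_uniform_density_falls_back_to_u_with_warning(self):
        u = np.array([[1.0, 2.0]])
        p = np.array([[4.0, 4.0]])
        with pytest.warns(UserWarning):
            got = u_star_matrix(u, p)
        assert np.array_equal(got, u)


class TestClusterExtraction:
    def test_identical_patients_form_one_cluster(self):
        X = np.tile([50.0, 50.0, 50.0, 50.0], (20, 1))
        model = train_esom(X, ESOMConfig(rows=6, cols=8, epochs=3, seed=2))
        u = u_matrix(model)
        bmus = assign_bmus(model, X)
        # uniform data: use U directly (P-matrix density is degenerate)
        asg = extract_clusters(u, bmus, model.config)
        assert len(asg.cluster_sizes) == 1
        assert not asg.is_outlier.any()

    def test_two_blob_recovery(self):
        """Two well-separated Gaussian blobs are recovered with ARI >= 0.9."""
        from sklearn.metrics import adjusted_rand_score

        seed = 7
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (60, 4))
        b = rng.normal(8, 1, (60, 4))
        truth = np.array([0] * 60 + [1] * 60)
        Ds, _ = scale_0_100(np.vstack([a, b]))
        model = train_esom(Ds, ESOMConfig(rows=20, cols=30, seed=seed + 100))
        sm = structure_matrices(model, Ds)
        asg = extract_clusters(sm.u_star, assign_bmus(model, Ds), model.config)
        assert adjusted_rand_score(truth, asg.labels) >= 0.9

    def test_planted_far_pair_flagged_as_outlier_group(self):
        rng = np.random.default_rng(0)
        bulk = rng.normal(0, 1, (60, 4))
        far = np.array([[12.0, 12, 12, 12], [12.3, 12, 12, 11.7]])
        Ds, _ = scale_0_100(np.vstack([bulk, far]))
        model = train_esom(Ds, ESOMConfig(rows=20, cols=30, seed=1))
        sm = structure_matrices(model, Ds)
        asg = extract_clusters(sm.u_star, assign_bmus(model, Ds), model.config)
        assert asg.is_outlier[-2:].all()
        assert asg.labels[-2] == asg.labels[-1]
        assert asg.cluster_sizes[asg.labels[-1]] == 2

    def test_empty_bmus_rejected(self):
        with pytest.raises(DegenerateInputError):
            extract_clusters(np.zeros((3, 3)), np.array([], dtype=int), ESOMConfig(rows=3, cols=3))


class TestClusterStageAssociation:
    def _assignment(self, labels):
        labels = np.asarray(labels)
        sizes = {int(g): int((labels == g).sum()) for g in np.unique(labels)}
        return ClusterAssignment(
            labels=labels,
            is_outlier=np.zeros(labels.size, bool),
            cluster_sizes=sizes,
            basin_grid=np.zeros((1, 1), int),
            min_cluster_size=3,
            threshold=0.0,
        )

    def test_diagonal_table_hand_value(self):
        asg = self._assignment([1] * 10 + [2] * 10)
        stages = np.array(["remission"] * 10 + ["low"] * 10)
        res = cluster_stage_association(asg, stages)
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1

    def test_independent_rows_give_zero(self):
        asg = self._assignment([1] * 20 + [2] * 20)
        stages = np.array((["remission"] * 10 + ["low"] * 10) * 2)
        assert cluster_stage_association(asg, stages)["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_3x3_table_df(self):
        asg = self._assignment([1] * 15 + [2] * 15 + [3] * 15)
        rng = np.random.default_rng(0)
        stages = rng.choice(["remission", "low", "moderate"], size=45)
        # ensure every stage appears in the kept table
        stages[:3] = ["remission", "low", "moderate"]
        res = cluster_stage_association(asg, stages)
        assert res["df"] == 4

    def test_small_clusters_excluded(self):
        asg = self._assignment([1] * 10 + [2] * 10 + [3] * 2)
        stages = np.array(["remission"] * 10 + ["low"] * 10 + ["moderate"] * 2)
        res = cluster_stage_association(asg, stages)
        # cluster 3 and its stage column drop out entirely
        assert res["table"].shape == (2, 2)
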