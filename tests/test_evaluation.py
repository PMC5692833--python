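import numpy as np
import pytest

import basisbrain as bb
from basisbrain.errors import DegenerateDataError, ParameterError


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "y,y_hat,expected",
        [
            ([0, 1, 2], [0, 1, 2], 1.0),
            ([0, 1, 2], [1, 1, 1], 0.0),  # predicting the mean
            ([0, 1, 2], [0, 1, 1], 0.5),
        ],
    )
    def test_known_values(self, y, y_hat, expected):
        assert bb.explained_variance(np.array(y, float), np.array(y_hat, float)) == (
            pytest.approx(expected)
        )

    def test_constant_target_rejected(self):
        with pytest.raises(DegenerateDataError):
            bb.explained_variance(np.ones(5), np.zeros(5))

    def test_can_be_negative_out_of_sample(self):
        assert bb.explained_variance(np.array([0.0, 1.0]), np.array([5.0, -5.0])) < 0


class TestSpatialSubsampleCV:
    def test_partition_contract_and_reproducibility(self, small_basis, small_cohort):
        data, _ = small_cohort
        t1 = bb.spatial_subsample_cv(
            small_basis, data, fractions=[0.5], repeats=2, seed=7
        )
        t2 = bb.spatial_subsample_cv(
            small_basis, data, fractions=[0.5], repeats=2, seed=7
        )
        assert t1.equals(t2)
        t3 = bb.spatial_subsample_cv(
            small_basis, data, fractions=[0.5], repeats=2, seed=8
        )
        assert not np.allclose(t1["ev"], t3["ev"])

    def test_noiseless_self_consistency(self, small_basis):
        data, _ = bb.simulate_cohort(
            small_basis, np.eye(small_basis.M), np.inf, 4, seed=70
        )
        table = bb.spatial_subsample_cv(
            small_basis, data, fractions=[0.5], repeats=2, seed=0
        )
        assert (table["ev"] > 0.99).all()

    def test_fraction_one_matches_direct_fit(self, small_basis, small_cohort):
        data, _ = small_cohort
        table = bb.spatial_subsample_cv(
            small_basis, data, fractions=[1.0], repeats=1, seed=0
        )
        _, post, _ = bb.fit_empirical_bayes(small_basis, data)
        Y_hat = small_basis.matrix @ post.W_bar
        direct = [
            bb.explained_variance(data.values[:, s], Y_hat[:, s])
            for s in range(data.S)
        ]
        assert np.allclose(np.sort(table["ev"].to_numpy()), np.sort(direct), atol=1e-8)

    def test_invalid_fraction_rejected(self, small_basis, small_cohort):
        data, _ = small_cohort
        with pytest.raises(ParameterError):
            bb.spatial_subsample_cv(small_basis, data, fractions=[1.5])


class TestRelevanceRanking:
    def test_tie_break_identity_permutation(self):
        h = bb.Hyperparameters(np.ones(4), 1.0)
        rank = bb.rank_by_relevance(h)
        assert np.array_equal(rank.order, np.arange(4))
        assert np.allclose(rank.scores, 1.0)

    def test_order_by_prior_variance(self):
        h = bb.Hyperparameters(np.array([10.0, 1.0, 100.0]), 1.0)
        rank = bb.rank_by_relevance(h)
        # variances 0.1, 1, 0.01 -> order (col 1, col 0, col 2)
        assert np.array_equal(rank.order, [1, 0, 2])
        assert rank.scores.max() == pytest.approx(1.0)
        assert rank.alpha_ratio.max() == pytest.approx(1.0)

    def test_scale_invariance(self):
        h1 = bb.Hyperparameters(np.array([2.0, 8.0, 1.0]), 1.0)
        h2 = bb.Hyperparameters(np.array([20.0, 80.0, 10.0]), 1.0)
        r1, r2 = bb.rank_by_relevance(h1), bb.rank_by_relevance(h2)
        assert np.array_equal(r1.order, r2.order)
        assert np.allclose(r1.scores, r2.scores)

    def test_full_bayes_mode(self, small_basis, small_cohort):
        data, _ = small_cohort
        samples, _ = bb.run_chain(small_basis, data, n_burn=50, n_samples=100, seed=1)
        rank = bb.rank_by_relevance(samples)
        assert rank.order.size == small_basis.M
        assert rank.scores.max() == pytest.approx(1.0)


class TestComplexityCurve:
    def test_full_order_reproduces_full_model_ev(self, small_basis, small_cohort):
        data, _ = small_cohort
        hyper, post, _ = bb.fit_empirical_bayes(small_basis, data)
        ranking = bb.rank_by_relevance(hyper)
        curve = bb.complexity_curve(
            small_basis, data, ranking, model_orders=[small_basis.M]
        )
        Y_hat = small_basis.matrix @ post.W_bar
        direct = np.mean(
            [
                bb.explained_variance(data.values[:, s], Y_hat[:, s])
                for s in range(data.S)
            ]
        )
        assert curve.ev_mean[0] == pytest.approx(direct, abs=1e-6)

    def test_tracks_nested_ols_oracle(self, small_basis):
        # noiseless data: in-sample EV of the Bayesian fit should track the
        # non-decreasing nested-OLS curve within 0.02
        data, _ = bb.simulate_cohort(
            small_basis, np.eye(small_basis.M), 1e6, 5, seed=80
        )
        hyper, _, _ = bb.fit_empirical_bayes(small_basis, data)
        ranking = bb.rank_by_relevance(hyper)
        orders = [2, 4, 6, 8]
        curve = bb.complexity_curve(small_basis, data, ranking, orders)
        ols_ev = []
        for m_prime in orders:
            cols = ranking.order[:m_prime]
            X = small_basis.matrix[:, cols]
            W_ols, *_ = np.linalg.lstsq(X, data.values, rcond=None)
            Y_hat = X @ W_ols
            ols_ev.append(
                np.mean(
                    [
                        bb.explained_variance(data.values[:, s], Y_hat[:, s])
                        for s in range(data.S)
                    ]
                )
            )
        assert np.all(np.diff(ols_ev) >= -1e-10)
        assert np.max(np.abs(curve.ev_mean - np.array(ols_ev))) < 0.02

    def test_zero_order_rejected(self, small_basis, small_cohort):
        data, _ = small_cohort
        ranking = bb.rank_by_relevance(bb.Hyperparameters(np.ones(small_basis.M), 1.0))
        with pytest.raises(ParameterError):
            bb.complexity_curve(small_basis, data, ranking, model_orders=[0])


class TestStructureCoefficients:
    def test_single_basis_model_gives_unit_coefficient(self, toy_mask):
        basis = bb.random_smooth_basis(toy_mask, 1, seed=90)
        Y_hat = basis.matrix * 3.0  # predictions proportional to the column
        sc = bb.structure_coefficients(basis, Y_hat)
        assert sc[0, 0] == pytest.approx(1.0)

    def test_orthogonal_column_gives_zero(self):
        rng = np.random.default_rng(91)
        Q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        Q = Q - Q.mean(axis=0)
        basis = bb.BasisSet(Q, list("abc"))
        Y_hat = Q[:, [0]]
        sc = bb.structure_coefficients(basis, Y_hat)
        assert abs(sc[1, 0]) < 0.05
        assert abs(sc[2, 0]) < 0.05

    def test_hand_computed_three_voxel_case(self):
        phi = np.array([[1.0], [2.0], [4.0]])
        y_hat = np.array([[0.0], [1.0], [2.0]])
        basis = bb.BasisSet(phi, ["a"])
        sc = bb.structure_coefficients(basis, y_hat)
        expected = np.corrcoef(phi[:, 0], y_hat[:, 0])[0, 1]
        assert sc[0, 0] == pytest.approx(expected, abs=1e-12)


class TestSplitReproducibility:
    def test_noiseless_shared_structure_gives_r_one(self, small_basis):
        # reproducibility measures the cohort's shared weight structure:
        # identical subject weights, no noise -> both halves recover the
        # same vector exactly
        w0 = np.random.default_rng(99).standard_normal(small_basis.M)
        data, _ = bb.simulate_cohort(
            small_basis, 1e-16 * np.eye(small_basis.M), np.inf, 8, seed=100,
            mean_W=w0,
        )
        r = bb.split_reproducibility(small_basis, data, seed=0)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_high_snr_reproducible(self, small_basis):
        # shared structure 10x stronger than per-subject variation: the
        # mean-weight vectors should replicate across halves (r > 0.9)
        w0 = np.random.default_rng(98).standard_normal(small_basis.M)
        data, _ = bb.simulate_cohort(
            small_basis, 0.1 * np.eye(small_basis.M), 25.0, 12, seed=101,
            mean_W=w0,
        )
        r = bb.split_reproducibility(small_basis, data, seed=0)
        assert r > 0.9

    def test_pure_noise_gives_low_r(self, toy_mask):
        # with no shared signal the two halves' mean weights decorrelate;
        # use enough basis columns that a chance |r| > 0.5 is rare
        basis = bb.random_smooth_basis(toy_mask, 20, seed=95)
        rs = []
        for rep in range(10):
            Y = np.random.default_rng(200 + rep).standard_normal((basis.V, 8))
            data = bb.DataMatrix(Y, [f"s{i}" for i in range(8)])
            rs.append(bb.split_reproducibility(basis, data, seed=rep))
        assert np.mean(np.abs(np.asarray(rs)) < 0.5) >= 0.9

    def test_too_few_subjects(self, small_basis):
        data = bb.DataMatrix(
            np.random.default_rng(0).standard_normal((small_basis.V, 3)), list("abc")
        )
        with pytest.raises(ParameterError):
            bb.split_reproducibility(small_basis, data)
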