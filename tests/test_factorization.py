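import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from wheezefactor.factorization import (
    CLRNMF,
    FactorizationResult,
    factorize,
    global_objective,
    initial_factors,
    kl_divergence,
    spectral_energy_distribution,
    spectral_smoothness,
    spectral_sparseness,
    temporal_smoothness,
)


class TestKLDivergence:
    def test_zero_at_equality(self, rng):
        X = rng.random((5, 7)) + 0.1
        assert kl_divergence(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_hand_value(self):
        # 2*ln2 - 2 + 1
        assert kl_divergence(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(
            2 * np.log(2) - 1, abs=1e-12
        )

    def test_zero_entry_convention(self):
        # where X == 0 the term reduces to Xhat
        assert kl_divergence(np.array([[0.0]]), np.array([[3.0]])) == pytest.approx(3.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones((2, 2)), np.ones((2, 3)))

    @given(seed=st.integers(0, 1000))
    def test_non_negative(self, seed):
        r = np.random.default_rng(seed)
        assert kl_divergence(r.random((4, 4)), r.random((4, 4)) + 0.01) >= 0


class TestPenalties:
    def test_sparseness_is_entry_sum(self):
        assert spectral_sparseness(np.array([[1.0, 2.0], [3.0, 4.0]])) == 10.0
        assert spectral_sparseness(np.zeros((3, 3))) == 0.0

    @given(c=st.floats(min_value=0, max_value=100))
    def test_sparseness_homogeneous(self, c):
        B = np.array([[0.5, 1.5], [2.0, 0.0]])
        assert spectral_sparseness(c * B) == pytest.approx(c * spectral_sparseness(B))

    def test_temporal_constant_rows_cost_nothing(self):
        assert temporal_smoothness(np.full((3, 6), 2.5)) == 0.0

    def test_temporal_hand_value(self):
        # one row [0, 1]: sigma^2 = 0.5, squared step = 1 -> cost 2
        assert temporal_smoothness(np.array([[0.0, 1.0]])) == pytest.approx(2.0)

    def test_spectral_hand_value(self):
        assert spectral_smoothness(np.array([[0.0], [1.0]])) == pytest.approx(2.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_smoothness_scale_invariant(self, c):
        A = np.array([[0.2, 0.9, 0.4], [1.0, 1.0, 0.5]])
        assert temporal_smoothness(c * A) == pytest.approx(temporal_smoothness(A))
        assert spectral_smoothness(c * A.T) == pytest.approx(spectral_smoothness(A.T))

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            temporal_smoothness(np.ones((2, 1)))

    def test_zero_rows_contribute_nothing(self):
        A = np.vstack([np.zeros(4), [0.0, 1.0, 0.0, 1.0]])
        assert temporal_smoothness(A) == pytest.approx(
            temporal_smoothness(A[1:2])
        )


class TestGlobalObjective:
    def test_penalty_free_limit_is_kl(self, rng):
        X = rng.random((6, 5)) + 0.1
        res = FactorizationResult(
            rng.random((6, 2)), rng.random((6, 3)), rng.random((2, 5)), rng.random((3, 5))
        )
        assert global_objective(X, res, 0, 0, 0) == pytest.approx(
            kl_divergence(X, res.Xhat)
        )

    def test_vanishes_on_smooth_exact_fit(self):
        # X = BR @ AR with constant columns/rows and BW = 0: every term is zero
        BR = np.full((4, 2), 1.0)
        AR = np.full((2, 3), 0.5)
        res = FactorizationResult(np.zeros((4, 1)), BR, np.zeros((1, 3)), AR)
        assert global_objective(BR @ AR, res) == pytest.approx(0.0, abs=1e-9)

    def test_matches_sum_of_hand_computed_terms(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        BW = np.array([[0.0], [1.0]])     # psi = 1, phi_spectral = 2
        AW = np.array([[0.0, 1.0]])       # phi_temporal = 2
        BR = np.array([[0.0], [1.0]])     # phi_spectral = 2
        AR = np.array([[1.0, 1.0]])
        res = FactorizationResult(BW, BR, AW, AR)
        expected = kl_divergence(X, res.Xhat) + 0.5 * 1 + 0.5 * 2 + 0.5 * 2
        assert global_objective(X, res) == pytest.approx(expected, rel=1e-12)


class TestFactorize:
    def test_factors_stay_non_negative(self, rng):
        X = rng.random((20, 9))
        res = factorize(X, n_wheeze_components=2, n_resp_components=4,
                        max_iter=30, random_state=0)
        for M in (res.BW, res.BR, res.AW, res.AR):
            assert np.all(M >= 0)

    def test_objective_monotone_on_small_instance(self, rng):
        X = rng.random((30, 12))
        X /= X.mean()
        m = CLRNMF(n_wheeze_components=2, n_resp_components=8, random_state=3).fit(X)
        tr = m.objective_trajectory_
        assert np.all(np.diff(tr) <= 1e-9 * np.abs(tr[:-1]))

    def test_single_frame_matrix_supported(self, rng):
        # 100 ms segments produce T = 1; temporal smoothness is inactive there
        X = rng.random((20, 1)) + 0.1
        res = factorize(X, n_wheeze_components=2, n_resp_components=4,
                        max_iter=10, random_state=0)
        assert res.AW.shape == (2, 1) and np.all(np.isfinite(res.BW))

    def test_invalid_config_rejected(self, rng):
        with pytest.raises(ValueError):
            CLRNMF(max_iter=0).fit(rng.random((5, 5)))
        with pytest.raises(ValueError):
            CLRNMF(alpha=-1.0).fit(rng.random((5, 5)))
        with pytest.raises(ValueError):
            CLRNMF().fit(np.zeros((5, 5)))

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.random((15, 6))
        r1 = factorize(X, random_state=11)
        r2 = factorize(X, random_state=11)
        np.testing.assert_array_equal(r1.BW, r2.BW)
        np.testing.assert_array_equal(r1.AR, r2.AR)

    def test_early_stop_with_tolerance(self, rng):
        X = rng.random((10, 5)) + 0.5
        m = CLRNMF(n_wheeze_components=1, n_resp_components=2, tol=1e-3,
                   max_iter=200, random_state=0).fit(X)
        assert m.n_iter_ < 200

    @pytest.mark.parametrize("weight", ["alpha", "beta"])
    def test_stronger_penalty_reduces_its_target(self, weight, rng):
        # trend over seeds: alpha suppresses psi(BW), beta suppresses phi(BR)
        X = rng.random((40, 10)) + 0.05
        X /= X.mean()
        lows, highs = [], []
        for seed in range(10):
            vals = {}
            for w in (0.0, 2.0):
                m = CLRNMF(n_wheeze_components=2, n_resp_components=6,
                           **{weight: w}, random_state=seed).fit(X)
                vals[w] = (spectral_sparseness(m.wheeze_basis_) if weight == "alpha"
                           else spectral_smoothness(m.resp_basis_))
            lows.append(vals[0.0])
            highs.append(vals[2.0])
        assert np.mean(highs) < np.mean(lows)

    def test_sklearn_protocol(self, rng):
        m = CLRNMF(alpha=0.7, random_state=5)
        params = m.get_params()
        assert params["alpha"] == 0.7
        m2 = clone(m)
        assert m2.get_params() == params
        X = rng.random((10, 4))
        xi = m.fit_transform(X)
        assert xi.shape == (10,) and np.all(xi >= 0)


class TestSpectralEnergyDistribution:
    def test_row_sums(self):
        res = FactorizationResult(
            np.array([[1.0, 0.0], [0.0, 2.0]]), np.zeros((2, 1)),
            np.zeros((2, 1)), np.zeros((1, 1)),
        )
        np.testing.assert_array_equal(spectral_energy_distribution(res).xi, [1.0, 2.0])

    def test_zero_column_is_inert(self, rng):
        BW = rng.random((5, 3))
        BW[:, 1] = 0.0
        res = FactorizationResult(BW, np.zeros((5, 1)), np.zeros((3, 2)), np.zeros((1, 2)))
        dropped = FactorizationResult(
            BW[:, [0, 2]], np.zeros((5, 1)), np.zeros((2, 2)), np.zeros((1, 2))
        )
        np.testing.assert_array_equal(
            spectral_energy_distribution(res).xi, spectral_energy_distribution(dropped).xi
        )

    def test_matches_matrix_vector_product(self, rng):
        BW = rng.random((5, 3))
        res = FactorizationResult(BW, np.zeros((5, 1)), np.zeros((3, 2)), np.zeros((1, 2)))
        np.testing.assert_allclose(
            spectral_energy_distribution(res).xi, BW @ np.ones(3)
        )


def test_initial_factors_positive_and_deterministic():
    a = initial_factors(np.random.default_rng(9), 6, 4, 2, 3)
    b = initial_factors(np.random.default_rng(9), 6, 4, 2, 3)
    for m1, m2 in zip(a, b):
        assert np.all(m1 > 0)
        np.testing.assert_array_equal(m1, m2)
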