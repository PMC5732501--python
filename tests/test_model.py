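"""BYM model: likelihood, ICAR conditional, sampler behaviour, rebalancing."""

import numpy as np
import pytest

import bymweights as bw
from conftest import make_posterior


class TestInternalStandardisation:
    @pytest.mark.parametrize("y,P,expect", [
        ((1, 3), (100, 300), (1.0, 3.0)),
        ((2, 2), (100, 300), (1.0, 3.0)),
    ])
    def test_examples(self, y, P, expect):
        assert np.allclose(bw.internal_standardisation(y, P), expect)

    def test_total_identity(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(5, 30)
        P = rng.uniform(50, 500, 30)
        E = bw.internal_standardisation(y, P)
        assert E.sum() == pytest.approx(y.sum(), rel=1e-12)

    def test_nonpositive_population(self):
        with pytest.raises(ValueError):
            bw.internal_standardisation([1, 2], [100, 0])


class TestPoissonLoglik:
    @pytest.mark.parametrize("y", [0, 1])
    def test_unit_rate(self, y):
        assert bw.poisson_loglik([y], [1.0], [0.0]) == pytest.approx(-1.0)

    def test_additivity(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(4, 10)
        E = rng.uniform(1, 5, 10)
        eta = rng.normal(size=10)
        total = bw.poisson_loglik(y, E, eta)
        parts = sum(bw.poisson_loglik([y[i]], [E[i]], [eta[i]]) for i in range(10))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            bw.poisson_loglik([-1], [1.0], [0.0])


def dense_conditional_oracle(w, sigma2, gamma, i):
    """Generic GMRF conditional from the precision matrix Q = (D − W)/σ²."""
    q = (np.diag(w.sum(axis=1)) - w) / sigma2
    mean = -(q[i] @ gamma - q[i, i] * gamma[i]) / q[i, i]
    return mean, 1.0 / q[i, i]


class TestIcarConditional:
    def test_single_neighbour(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        mean, var = bw.icar_conditional([0.3, -0.7], w, 2.0, 0)
        assert mean == pytest.approx(-0.7)
        assert var == pytest.approx(2.0)

    def test_equal_weights_average(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[0, 2] = w[2, 0] = 1.0
        mean, _ = bw.icar_conditional([0.0, 0.4, 0.8], w, 1.0, 0)
        assert mean == pytest.approx(0.6)

    def test_island_error(self):
        w = np.zeros((2, 2))
        with pytest.raises(ValueError, match="island"):
            bw.icar_conditional([0.0, 0.0], w, 1.0, 0)

    def test_chain_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = rng.uniform(0.5, 2.0)
        gamma = rng.normal(size=4)
        for i in range(4):
            mean, var = bw.icar_conditional(gamma, w, 1.7, i)
            om, ov = dense_conditional_oracle(w, 1.7, gamma, i)
            assert mean == pytest.approx(om, abs=1e-10)
            assert var == pytest.approx(ov, abs=1e-10)


@pytest.fixture(scope="module")
def small_fit():
    """A quick deterministic fit on a 4×4 lattice used by several tests."""
    geom = bw.grid_lattice(4, 4)
    rng = np.random.default_rng(7)
    x = rng.normal(size=16)
    E = np.full(16, 8.0)
    y = rng.poisson(E * np.exp(0.2 + 0.5 * x))
    data = bw.AreaDataset(area_ids=list(geom.area_ids), y=y, E=E, x=x)
    wm = bw.build_weights("A1", geom)
    cfg = bw.BYMConfig(chains=2, iterations=1000, burn_in=500, thin=5, seed=21)
    return data, wm, cfg, bw.fit_bym(data, wm, cfg)


class TestFitBym:
    def test_reproducible(self, small_fit):
        data, wm, cfg, post = small_fit
        again = bw.fit_bym(data, wm, cfg)
        assert np.array_equal(post.alpha, again.alpha)
        assert np.array_equal(post.gamma, again.gamma)

    def test_gamma_sums_to_zero(self, small_fit):
        _, _, _, post = small_fit
        assert np.max(np.abs(post.gamma.sum(axis=2))) < 1e-8

    def test_stored_dimensions(self, small_fit):
        data, wm, cfg, post = small_fit
        assert post.alpha.shape == (2, cfg.iterations // cfg.thin)
        assert post.gamma.shape == (2, 200, 16)

    def test_model_b_null_data(self):
        # y == round(E), no covariate: alpha posterior centred near 0
        geom = bw.grid_lattice(4, 4)
        E = np.full(16, 10.0)
        data = bw.AreaDataset(area_ids=list(geom.area_ids),
                              y=np.round(E).astype(int), E=E, x=np.zeros(16))
        cfg = bw.BYMConfig(chains=2, iterations=4000, burn_in=2000, thin=5,
                           seed=3, include_structured=False)
        post = bw.fit_bym(data, None, cfg)
        assert np.all(post.gamma == 0)
        assert abs(post.alpha.mean()) < 3 * post.alpha.std()

    def test_structured_requires_weights(self, small_fit):
        data, _, cfg, _ = small_fit
        with pytest.raises(ValueError, match="weights"):
            bw.fit_bym(data, None, cfg)

    def test_standardised_weights_rejected(self, small_fit):
        data, wm, cfg, _ = small_fit
        with pytest.raises(ValueError, match="unstandardised"):
            bw.fit_bym(data, bw.row_standardise(wm), cfg)


class TestExcessVariation:
    def test_symmetric_split(self):
        rng = np.random.default_rng(3)
        gamma = rng.normal(size=(1, 10, 5))
        post = make_posterior(np.zeros((1, 10)), np.zeros((1, 10)), gamma, gamma.copy())
        assert bw.excess_variation(post).psi == pytest.approx(0.5)

    def test_no_structured_variation(self):
        rng = np.random.default_rng(4)
        gamma = np.ones((1, 10, 4)) * 0.7          # medians identical across areas
        eps = rng.normal(size=(1, 10, 4)) + np.arange(4)
        post = make_posterior(np.zeros((1, 10)), np.zeros((1, 10)), gamma, eps)
        assert bw.excess_variation(post).psi == pytest.approx(0.0)

    def test_all_structured(self):
        gamma = np.tile(np.array([1.0, 2.0, 3.0]), (1, 8, 1))
        eps = np.zeros((1, 8, 3))
        post = make_posterior(np.zeros((1, 8)), np.zeros((1, 8)), gamma, eps)
        assert bw.excess_variation(post).psi == pytest.approx(1.0)

    def test_degenerate_posterior(self):
        post = make_posterior(np.zeros((1, 5)), np.zeros((1, 5)),
                              np.zeros((1, 5, 3)), np.zeros((1, 5, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            bw.excess_variation(post)


class TestRebalance:
    def test_identity_at_zero(self, small_fit):
        _, _, _, post = small_fit
        out = bw.rebalance(post, 0.0)
        assert np.array_equal(out.gamma, post.gamma)
        assert np.array_equal(out.eps, post.eps)

    def test_printed_update(self):
        gamma = np.full((1, 1, 1), 1.0)
        eps = np.full((1, 1, 1), 2.0)
        post = make_posterior(np.zeros((1, 1)), np.zeros((1, 1)), gamma, eps)
        out = bw.rebalance(post, 0.5)
        assert out.gamma[0, 0, 0] == 0.0
        assert out.eps[0, 0, 0] == 3.0

    def test_conserves_sum_and_eta(self, small_fit):
        _, _, _, post = small_fit
        psi = bw.excess_variation(post).psi
        out = bw.rebalance(post, psi)
        # algebraically exact; one floating-point rounding per component
        assert np.allclose(out.gamma + out.eps, post.gamma + post.eps,
                           rtol=0, atol=1e-12)
        assert np.allclose(out.eta(), post.eta(), rtol=0, atol=1e-12)

    def test_invalid_psi(self, small_fit):
        _, _, _, post = small_fit
        with pytest.raises(ValueError):
            bw.rebalance(post, 1.5)


class TestBYMConfigValidation:
    def test_iterations_thin_consistency(self):
        with pytest.raises(ValueError):
            bw.BYMConfig(iterations=1001, thin=5)

    def test_positive_priors(self):
        with pytest.raises(ValueError):
            bw.BYMConfig(var_alpha=0.0)


class TestAreaDataset:
    def test_internal_standardisation_fallback(self):
        data = bw.AreaDataset(area_ids=["a", "b"], y=np.array([2, 2]),
                              P=np.array([100.0, 300.0]))
        assert np.allclose(data.E, [1.0, 3.0])

    def test_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            bw.AreaDataset(area_ids=["a", "a"], y=np.array([1, 2]),
                           E=np.array([1.0, 1.0]))

    def test_non_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            bw.AreaDataset(area_ids=["a", "b"], y=np.array([1.5, 2.0]),
                           E=np.array([1.0, 1.0]))
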