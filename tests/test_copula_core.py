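import numpy as np
import pytest
import scipy.stats
from scipy.special import ndtr, ndtri

from copulagcn import autodiff as ad
from copulagcn import copula_core as cc
from copulagcn.cellgraph import CellGraph
from copulagcn.data_io import ValidationError


def _chain_graph(n):
    edges = np.array([(i, i + 1) for i in range(n - 1)])
    return CellGraph(n=n, edges=edges, weights=np.ones(n - 1), neighbor_k=1)


def _random_graph(n, rng, p=0.4):
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.uniform() < p]
    if not edges:
        edges = [(0, 1)]
    return CellGraph(n=n, edges=np.array(edges),
                     weights=np.ones(len(edges)), neighbor_k=1)


class TestPoissonPIT:
    def test_closed_form_y1_lam1_mid(self):
        pit = cc.poisson_pit(np.array([1]), np.array([1.0]), mode="mid")
        assert pit.u[0] == pytest.approx(np.exp(-1) + 0.5 * np.exp(-1),
                                         abs=1e-12)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 4.0])
    def test_closed_form_y0_mid(self, lam):
        pit = cc.poisson_pit(np.array([0]), np.array([lam]), mode="mid")
        assert pit.u[0] == pytest.approx(0.5 * np.exp(-lam), abs=1e-12)

    def test_random_mode_is_uniform(self):
        rng = np.random.default_rng(7)
        lam = np.full(10_000, 2.5)
        y = rng.poisson(lam)
        pit = cc.poisson_pit(y, lam, mode="random", rng=rng)
        assert scipy.stats.kstest(pit.u, "uniform").pvalue > 0.01

    def test_values_strictly_inside_unit_interval(self):
        pit = cc.poisson_pit(np.array([0, 50]), np.array([40.0, 1e-6]),
                             mode="mid")
        assert np.all(pit.u > 0) and np.all(pit.u < 1)

    @pytest.mark.parametrize("y,lam,err", [
        (np.array([1.5]), np.array([1.0]), "integers"),
        (np.array([1]), np.array([0.0]), "positive"),
        (np.array([-1]), np.array([1.0]), "non-negative"),
    ])
    def test_invalid_inputs(self, y, lam, err):
        with pytest.raises(ValidationError, match=err):
            cc.poisson_pit(y, lam, mode="mid")


class TestPairwiseEdgeScore:
    def test_positive_and_symmetric(self, rng):
        params = cc.PairwiseRegressor.init(5, rng=rng)
        params.w2 = rng.normal(size=params.w2.shape)
        params.b2 = 0.3
        xi, xj = rng.normal(size=5), rng.normal(size=5)
        a = cc.pairwise_edge_score(xi, xj, params)
        b = cc.pairwise_edge_score(xj, xi, params)
        assert a > 0
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_final_layer_gives_log_two(self, rng):
        params = cc.PairwiseRegressor.init(4, rng=rng)  # w2, b2 start at 0
        x = rng.normal(size=(2, 4))
        assert cc.pairwise_edge_score(x[0], x[1], params) == pytest.approx(
            np.log(2.0), abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        params = cc.PairwiseRegressor.init(4, rng=rng)
        with pytest.raises(ValidationError):
            cc.pairwise_edge_score(np.ones(3), np.ones(3), params)


class TestBuildPrecision:
    def test_empty_graph_gives_identity(self, rng):
        g = CellGraph(n=3, edges=np.empty((0, 2)), weights=np.empty(0),
                      neighbor_k=1)
        params = cc.PairwiseRegressor.init(2, rng=rng)
        model = cc.build_precision(g, rng.normal(size=(3, 2)), params)
        np.testing.assert_allclose(model.K, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(model.R, np.eye(3), atol=1e-12)

    def test_two_node_hand_algebra(self):
        g = CellGraph(n=2, edges=np.array([[0, 1]]), weights=np.ones(1),
                      neighbor_k=1)
        K = cc.precision_from_scores(g, np.array([0.3]))
        np.testing.assert_allclose(K, [[1.3, -0.3], [-0.3, 1.3]], atol=1e-12)
        np.testing.assert_allclose(np.linalg.eigvalsh(K), [1.0, 1.6],
                                   atol=1e-12)

    def test_laplacian_structure_invariants(self, rng):
        # spot-check here; the acceptance suite runs 200 draws
        for trial in range(20):
            n = int(rng.integers(4, 16))
            g = _random_graph(n, rng)
            params = cc.PairwiseRegressor.init(3, rng=rng)
            params.w2 = rng.normal(size=params.w2.shape)
            params.b2 = float(rng.normal())
            model = cc.build_precision(g, rng.normal(size=(n, 3)), params)
            model.validate()
            ones = np.ones(n)
            np.testing.assert_allclose(model.K @ ones, ones, atol=1e-8)
            assert np.linalg.eigvalsh(model.K).min() >= 1 - 1e-8


class TestGaussianCopulaLogdensity:
    def test_independence_copula_has_zero_logdensity(self, rng):
        for _ in range(10):
            u = rng.uniform(0.05, 0.95, size=6)
            assert cc.gaussian_copula_logdensity(u, np.eye(6)) == \
                pytest.approx(0.0, abs=1e-12)

    def test_bivariate_closed_form_at_median(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = cc.gaussian_copula_logdensity(np.array([0.5, 0.5]), r)
        assert out == pytest.approx(-0.5 * np.log(0.75), abs=1e-10)

    def test_factorization_against_multivariate_normal(self, rng):
        # log c(u;R) = log N(z; 0, R) - sum log N(z_i; 0, 1)
        for _ in range(10):
            n = int(rng.integers(2, 7))
            a = rng.normal(size=(n, n + 2))
            r = cc._correlation_from_cov(a @ a.T + 0.5 * np.eye(n))
            u = rng.uniform(0.05, 0.95, size=n)
            z = ndtri(u)
            expected = (scipy.stats.multivariate_normal(np.zeros(n), r)
                        .logpdf(z) -
                        scipy.stats.norm.logpdf(z).sum())
            assert cc.gaussian_copula_logdensity(u, r) == \
                pytest.approx(expected, abs=1e-8)

    def test_non_positive_definite_rejected(self):
        r = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValidationError):
            cc.gaussian_copula_logdensity(np.array([0.4, 0.6]), r)


class TestCopulaNLLObserved:
    def test_full_block_equals_direct_density(self, rng):
        g = _random_graph(5, rng)
        params = cc.PairwiseRegressor.init(2, rng=rng)
        params.w2 = rng.normal(size=params.w2.shape)
        model = cc.build_precision(g, rng.normal(size=(5, 2)), params)
        u = rng.uniform(0.1, 0.9, size=5)
        nll = cc.copula_nll_observed(u, model, np.arange(5))
        assert nll == pytest.approx(
            -cc.gaussian_copula_logdensity(u, model.R), abs=1e-10)

    def test_independence_gives_zero(self, rng):
        g = CellGraph(n=4, edges=np.empty((0, 2)), weights=np.empty(0),
                      neighbor_k=1)
        model = cc.build_precision(g, rng.normal(size=(4, 2)),
                                   cc.PairwiseRegressor.init(2, rng=rng))
        u = rng.uniform(0.2, 0.8, size=2)
        assert cc.copula_nll_observed(u, model, np.array([1, 3])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_chain_subset_matches_explicit_inversion(self, rng):
        g = _chain_graph(3)
        params = cc.PairwiseRegressor.init(2, rng=rng)
        params.w2 = rng.normal(size=params.w2.shape)
        feats = rng.normal(size=(3, 2))
        model = cc.build_precision(g, feats, params)
        obs = np.array([0, 2])
        u = rng.uniform(0.2, 0.8, size=2)
        # oracle: invert the full 3x3 K explicitly, standardize the block
        sigma = np.linalg.inv(model.K)
        s00 = sigma[np.ix_(obs, obs)]
        d = np.sqrt(np.diag(s00))
        r00 = s00 / np.outer(d, d)
        expected = -cc.gaussian_copula_logdensity(u, r00)
        assert cc.copula_nll_observed(u, model, obs) == \
            pytest.approx(expected, abs=1e-10)

    def test_marginalization_consistency_on_random_models(self, rng):
        # deleting unobserved rows/cols of Sigma (not K) is the marginal
        for _ in range(5):
            g = _random_graph(6, rng)
            params = cc.PairwiseRegressor.init(3, rng=rng)
            params.w2 = rng.normal(size=params.w2.shape)
            model = cc.build_precision(g, rng.normal(size=(6, 3)), params)
            obs = np.sort(rng.choice(6, size=4, replace=False))
            u = rng.uniform(0.1, 0.9, size=4)
            sub_sigma = model.Sigma[np.ix_(obs, obs)]
            r_sub = cc._correlation_from_cov(sub_sigma)
            assert cc.copula_nll_observed(u, model, obs) == pytest.approx(
                -cc.gaussian_copula_logdensity(u, r_sub), abs=1e-8)

    def test_empty_observed_set_rejected(self, rng):
        g = _chain_graph(3)
        model = cc.build_precision(g, rng.normal(size=(3, 2)),
                                   cc.PairwiseRegressor.init(2, rng=rng))
        with pytest.raises(ValidationError):
            cc.copula_nll_observed(np.array([]), model, np.array([]))


class TestConditionalAdjustedScores:
    def _two_node_model(self, w):
        g = CellGraph(n=2, edges=np.array([[0, 1]]), weights=np.ones(1),
                      neighbor_k=1)
        K = cc.precision_from_scores(g, np.array([w]))
        sigma = np.linalg.inv(K)
        return cc.DependenceModel(K=K, Sigma=sigma,
                                  R=cc._correlation_from_cov(sigma),
                                  source_graph=g)

    def test_independence_reduces_to_marginal(self, rng):
        g = CellGraph(n=3, edges=np.empty((0, 2)), weights=np.empty(0),
                      neighbor_k=1)
        model = cc.build_precision(g, rng.normal(size=(3, 2)),
                                   cc.PairwiseRegressor.init(2, rng=rng))
        lam = np.array([0.7, 2.0])
        p = cc.conditional_adjusted_scores(
            np.array([0.4]), lam, model, np.array([0]), np.array([1, 2]))
        np.testing.assert_allclose(p, 1 - np.exp(-lam), atol=1e-9)

    def test_bivariate_conditioning_formula(self):
        # edge weight 1 gives correlation rho = 0.5; observe z1 = 1
        model = self._two_node_model(1.0)
        assert model.R[0, 1] == pytest.approx(0.5, abs=1e-12)
        lam = np.array([1.3])
        u_obs = np.array([ndtr(1.0)])
        p = cc.conditional_adjusted_scores(u_obs, lam, model,
                                           np.array([0]), np.array([1]))
        m, v = 0.5 * 1.0, 1 - 0.5 ** 2
        expected = 1 - ndtr((ndtri(np.exp(-lam[0])) - m) / np.sqrt(v))
        assert p[0] == pytest.approx(expected, abs=1e-10)

    def test_vanishing_rate_sends_probability_to_zero(self, rng):
        g = CellGraph(n=2, edges=np.empty((0, 2)), weights=np.empty(0),
                      neighbor_k=1)
        model = cc.build_precision(g, rng.normal(size=(2, 2)),
                                   cc.PairwiseRegressor.init(2, rng=rng))
        p = cc.conditional_adjusted_scores(
            np.array([0.5]), np.array([1e-9]), model,
            np.array([0]), np.array([1]))
        assert p[0] < 1e-6

    def test_overlapping_index_sets_rejected(self):
        model = self._two_node_model(0.5)
        with pytest.raises(ValidationError):
            cc.conditional_adjusted_scores(np.array([0.5]), np.array([1.0]),
                                           model, np.array([0]),
                                           np.array([0]))


class TestTrainingOps:
    """The fast Schur-complement loss op against the dense reference."""

    def _reference(self, graph, w, z, obs):
        K = cc.precision_from_scores(graph, w)
        sigma = np.linalg.inv(K)
        r00 = cc._correlation_from_cov(sigma[np.ix_(obs, obs)])
        total = 0.0
        for col in range(z.shape[1]):
            total += -cc.gaussian_copula_logdensity(
                ndtr(z[:, col]), r00)
        return total / (z.shape[1] * len(obs))

    def test_value_matches_reference(self, rng):
        g = _random_graph(9, rng)
        obs = np.array([0, 2, 3, 5, 6, 8])
        w = rng.uniform(0.1, 1.5, g.n_edges)
        z = rng.normal(size=(6, 3)) * 0.8
        op = cc.CopulaNLL(g.edges, 9, obs)
        val = op(ad.Tensor(w), ad.Tensor(z))
        assert val.value == pytest.approx(self._reference(g, w, z, obs),
                                          abs=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        g = _random_graph(8, rng)
        obs = np.array([0, 1, 3, 4, 6, 7])
        w0 = rng.uniform(0.2, 1.2, g.n_edges)
        z0 = rng.normal(size=(6, 2)) * 0.7
        wt = ad.Tensor(w0, requires_grad=True)
        zt = ad.Tensor(z0, requires_grad=True)
        cc.CopulaNLL(g.edges, 8, obs)(wt, zt).backward()
        eps = 1e-6
        for e in range(g.n_edges):
            dw = np.zeros_like(w0)
            dw[e] = eps
            fd = (self._reference(g, w0 + dw, z0, obs) -
                  self._reference(g, w0 - dw, z0, obs)) / (2 * eps)
            assert wt.grad[e] == pytest.approx(fd, abs=1e-7)
        for i in range(z0.shape[0]):
            dz = np.zeros_like(z0)
            dz[i, 1] = eps
            fd = (self._reference(g, w0, z0 + dz, obs) -
                  self._reference(g, w0, z0 - dz, obs)) / (2 * eps)
            assert zt.grad[i, 1] == pytest.approx(fd, abs=1e-7)

    def test_all_nodes_observed_case(self, rng):
        g = _random_graph(7, rng)
        obs = np.arange(7)
        w = rng.uniform(0.1, 1.0, g.n_edges)
        z = rng.normal(size=(7, 2)) * 0.6
        val = cc.CopulaNLL(g.edges, 7, obs)(ad.Tensor(w), ad.Tensor(z))
        assert val.value == pytest.approx(self._reference(g, w, z, obs),
                                          abs=1e-9)

    def test_single_precision_close_to_double(self, rng):
        g = _random_graph(10, rng)
        obs = np.arange(7)
        w = rng.uniform(0.2, 1.0, g.n_edges)
        z = rng.normal(size=(7, 2)) * 0.5
        v64 = cc.CopulaNLL(g.edges, 10, obs, dtype=np.float64)(
            ad.Tensor(w), ad.Tensor(z))
        v32 = cc.CopulaNLL(g.edges, 10, obs, dtype=np.float32)(
            ad.Tensor(w), ad.Tensor(z))
        assert v32.value == pytest.approx(v64.value, abs=1e-4)

    def test_pit_z_gradient_matches_finite_differences(self, rng):
        lam0 = rng.uniform(0.2, 3.0, size=7)
        y = rng.poisson(lam0)
        lt = ad.Tensor(lam0, requires_grad=True)
        ad.total(ad.tanh(cc.PoissonPITZ(y)(lt))).backward()

        def f(lam):
            u = np.where(y > 0, scipy.stats.poisson.cdf(y - 1, lam), 0.0) \
                + 0.5 * scipy.stats.poisson.pmf(y, lam)
            return np.tanh(ndtri(u)).sum()

        eps = 1e-6
        for i in range(7):
            d = np.zeros(7)
            d[i] = eps
            fd = (f(lam0 + d) - f(lam0 - d)) / (2 * eps)
            assert lt.grad[i] == pytest.approx(fd, abs=1e-6)
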