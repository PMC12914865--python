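"""Gaussian copula machinery on the cell-cell graph.

The dependence between cells is modeled by a Gaussian copula whose
precision matrix is tied to the graph: K = I_n + D_hat - A_hat, where
A_hat puts a positive learned weight softplus(h(x_i, x_j)) on every graph
edge (h a two-layer perceptron on the pair of node feature vectors,
symmetrized over argument order) and zero elsewhere, and D_hat is the
corresponding degree matrix. Since D_hat - A_hat is a weighted graph
Laplacian (positive semi-definite, annihilates constants), K is symmetric
positive definite with smallest eigenvalue >= 1 and K 1 = 1 by
construction.

Discrete Poisson marginals enter the copula through the distributional
transform u = F(y-1; lambda) + v * p(y; lambda), which is exactly
Uniform(0,1) when v ~ Uniform(0,1) and is evaluated at the deterministic
midpoint v = 1/2 during training.

Everything here is plain NumPy/SciPy; the training-time fast path with
hand-derived gradients lives in the two `autodiff.Op` subclasses at the
bottom.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.stats
from scipy.special import expit, ndtr, ndtri

from . import autodiff
from .cellgraph import CellGraph
from .data_io import ValidationError

U_EPS = 1e-12   # PIT clamp: u in [U_EPS, 1 - U_EPS]
Z_MAX = 8.0     # clamp on latent normal scores before quadratic forms


# ---------------------------------------------------------------------------
# probability integral transform for Poisson marginals
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PITVector:
    """Distributional-transform values u in the open unit interval."""

    u: np.ndarray
    mode: str
    source_labels: np.ndarray
    source_rates: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if np.any(self.u <= 0) or np.any(self.u >= 1):
            raise ValidationError("PIT values must lie strictly in (0, 1)")


def poisson_pit(y: np.ndarray, lam: np.ndarray, mode: str = "mid",
                rng: np.random.Generator | None = None) -> PITVector:
    """Distributional transform of Poisson observations.

    u_i = F(y_i - 1; lambda_i) + v * p(y_i; lambda_i) with F the Poisson
    CDF (F(-1) = 0) and p the pmf; v = 1/2 in ``mid`` mode (deterministic,
    used in training), v ~ Uniform(0,1) per entry in ``random`` mode
    (exactly uniform, used for diagnostics). Output clamped into (0, 1).
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= 0):
        raise ValidationError("Poisson rates must be positive")
    if not np.issubdtype(y.dtype, np.integer):
        if np.any(y != np.floor(y)):
            raise ValidationError("observations must be integers")
        y = y.astype(np.int64)
    if np.any(y < 0):
        raise ValidationError("observations must be non-negative")
    if mode == "mid":
        v = 0.5
    elif mode == "random":
        if rng is None:
            raise ValidationError("random mode requires an rng")
        v = rng.uniform(size=np.broadcast(y, lam).shape)
    else:
        raise ValueError(f"unknown PIT mode {mode!r}")
    cdf_left = np.where(y > 0, scipy.stats.poisson.cdf(y - 1, lam), 0.0)
    pmf = scipy.stats.poisson.pmf(y, lam)
    u = np.clip(cdf_left + v * pmf, U_EPS, 1 - U_EPS)
    return PITVector(u=u, mode=mode, source_labels=y, source_rates=lam)


# ---------------------------------------------------------------------------
# pairwise precision regressor
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairwiseRegressor:
    """Two-layer perceptron h(x_i, x_j) -> scalar, on concatenated features.

    The first-layer weight is stored split by argument (W_left applies to
    x_i, W_right to x_j) so that per-node projections can be shared across
    edges. The final layer initializes to zero, so every edge starts at
    softplus(0) = ln 2 and the initial precision matrix is a uniformly
    weighted graph Laplacian plus identity.
    """

    W_left: np.ndarray
    W_right: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    @staticmethod
    def init(n_features: int, hidden: int = 32,
             rng: np.random.Generator | None = None) -> "PairwiseRegressor":
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (2 * n_features + hidden))
        return PairwiseRegressor(
            W_left=rng.normal(0, scale, (n_features, hidden)),
            W_right=rng.normal(0, scale, (n_features, hidden)),
            b1=np.zeros(hidden),
            w2=np.zeros(hidden),
            b2=0.0,
        )

    def raw(self, xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
        """Unsymmetrized h(x_i, x_j); operates on batches of row pairs."""
        pre = xi @ self.W_left + xj @ self.W_right + self.b1
        return np.tanh(pre) @ self.w2 + self.b2


def pairwise_edge_score(x_i: np.ndarray, x_j: np.ndarray,
                        params: PairwiseRegressor) -> float:
    """softplus of the order-symmetrized regressor output; always > 0."""
    x_i = np.atleast_2d(np.asarray(x_i, dtype=np.float64))
    x_j = np.atleast_2d(np.asarray(x_j, dtype=np.float64))
    if x_i.shape[1] != params.W_left.shape[0] or x_j.shape[1] != params.W_left.shape[0]:
        raise ValidationError("feature dimension does not match regressor input")
    raw = 0.5 * (params.raw(x_i, x_j) + params.raw(x_j, x_i))
    return float(np.logaddexp(0.0, raw[0]))


def edge_scores(features: np.ndarray, edges: np.ndarray,
                params: PairwiseRegressor) -> np.ndarray:
    """Vectorized softplus-symmetrized scores for an (E, 2) edge array."""
    x = np.asarray(getattr(features, "values", features), dtype=np.float64)
    if len(edges) == 0:
        return np.empty(0)
    xi, xj = x[edges[:, 0]], x[edges[:, 1]]
    raw = 0.5 * (params.raw(xi, xj) + params.raw(xj, xi))
    return np.logaddexp(0.0, raw)


# ---------------------------------------------------------------------------
# precision / covariance / correlation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DependenceModel:
    """Precision matrix K = I + D_hat - A_hat with its Sigma and R."""

    K: np.ndarray
    Sigma: np.ndarray
    R: np.ndarray
    source_graph: CellGraph
    regressor_params: PairwiseRegressor | None = None

    def validate(self, tol: float = 1e-8) -> None:
        K = self.K
        if not np.allclose(K, K.T, atol=tol):
            raise ValidationError("K not symmetric")
        ones = np.ones(K.shape[0])
        if not np.allclose(K @ ones, ones, atol=tol):
            raise ValidationError("K 1 != 1")
        w = np.linalg.eigvalsh(K)
        if w.min() < 1 - tol:
            raise ValidationError(f"min eigenvalue of K is {w.min()} < 1")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ValidationError("diag(R) != 1")


def precision_from_scores(graph: CellGraph, scores: np.ndarray) -> np.ndarray:
    """Dense K = I + D_hat - A_hat from per-edge positive scores."""
    n = graph.n
    K = np.zeros((n, n))
    if len(scores):
        i, j = graph.edges[:, 0], graph.edges[:, 1]
        K[i, j] = -scores
        K[j, i] = -scores
        deg = np.zeros(n)
        np.add.at(deg, i, scores)
        np.add.at(deg, j, scores)
    else:
        deg = np.zeros(n)
    K[np.diag_indices(n)] = 1.0 + deg
    return K


def _correlation_from_cov(sigma: np.ndarray) -> np.ndarray:
    s = np.sqrt(np.diag(sigma))
    r = sigma / np.outer(s, s)
    np.fill_diagonal(r, 1.0)
    return r


def build_precision(graph: CellGraph, features: np.ndarray,
                    params: PairwiseRegressor) -> DependenceModel:
    """Regress edge weights from node-feature pairs and assemble K, Sigma, R."""
    w = edge_scores(features, graph.edges, params)
    K = precision_from_scores(graph, w)
    Sigma = np.linalg.inv(K)
    R = _correlation_from_cov(Sigma)
    model = DependenceModel(K=K, Sigma=Sigma, R=R, source_graph=graph,
                            regressor_params=params)
    return model


# ---------------------------------------------------------------------------
# copula density and losses
# ---------------------------------------------------------------------------

def _z_from_u(u: np.ndarray) -> np.ndarray:
    return np.clip(ndtri(np.clip(u, U_EPS, 1 - U_EPS)), -Z_MAX, Z_MAX)


def gaussian_copula_logdensity(u, R: np.ndarray) -> float:
    """log c(u; R) = -1/2 log det R - 1/2 z^T (R^-1 - I) z, z = ndtri(u)."""
    u = u.u if isinstance(u, PITVector) else np.asarray(u, dtype=np.float64)
    z = _z_from_u(u)
    try:
        cf = scipy.linalg.cho_factor(R, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError("correlation matrix not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    quad = z @ scipy.linalg.cho_solve(cf, z) - z @ z
    return float(-0.5 * logdet - 0.5 * quad)


def copula_nll_observed(u_obs, model: DependenceModel,
                        obs_index: np.ndarray) -> float:
    """Negative log copula density of the observed block.

    The Gaussian copula marginalizes to the Gaussian copula of the
    sub-correlation: extract Sigma's observed block and re-standardize.
    """
    obs_index = np.asarray(obs_index, dtype=np.int64)
    if obs_index.size == 0:
        raise ValidationError("obs_index must be non-empty")
    sigma00 = model.Sigma[np.ix_(obs_index, obs_index)]
    r00 = _correlation_from_cov(sigma00)
    return -gaussian_copula_logdensity(u_obs, r00)


def conditional_adjusted_scores(u_obs, lam_miss: np.ndarray,
                                model: DependenceModel,
                                obs_index: np.ndarray,
                                miss_index: np.ndarray) -> np.ndarray:
    """Dependence-adjusted P(y_i = 1) for unobserved nodes.

    Conditions the latent Gaussian on the observed nodes' transformed
    labels: with z_obs = ndtri(u_obs), the conditional mean is
    m = R10 R00^-1 z_obs and variance v = diag(R11 - R10 R00^-1 R01); the
    adjusted probability is 1 - Phi((ndtri(e^-lambda) - m) / sqrt(v)),
    since under a Poisson marginal P(y = 0) = e^-lambda.
    """
    obs_index = np.asarray(obs_index, dtype=np.int64)
    miss_index = np.asarray(miss_index, dtype=np.int64)
    if np.intersect1d(obs_index, miss_index).size:
        raise ValidationError("observed and missing index sets overlap")
    u = u_obs.u if isinstance(u_obs, PITVector) else np.asarray(u_obs, float)
    lam = np.asarray(lam_miss, dtype=np.float64)
    z_obs = _z_from_u(u)
    R = model.R
    r00 = R[np.ix_(obs_index, obs_index)]
    r10 = R[np.ix_(miss_index, obs_index)]
    r11 = R[np.ix_(miss_index, miss_index)]
    cf = scipy.linalg.cho_factor(r00, lower=True)
    solve = scipy.linalg.cho_solve
    m = r10 @ solve(cf, z_obs)
    v = np.diag(r11) - np.einsum("ij,ij->i", r10, solve(cf, r10.T).T)
    if np.any(v <= 0):
        import warnings
        warnings.warn("conditional variance clamped at 1e-10")
    v = np.maximum(v, 1e-10)
    thresh = ndtri(np.clip(np.exp(-lam), U_EPS, 1 - U_EPS))
    if m.ndim == 2:  # one column of observed z per label
        v = v[:, None]
        thresh = np.atleast_2d(thresh.T).T if thresh.ndim == 2 else thresh[:, None]
    p = 1.0 - ndtr((thresh - m) / np.sqrt(v))
    return np.clip(p, U_EPS, 1 - U_EPS)


# ---------------------------------------------------------------------------
# training-time differentiable ops
# ---------------------------------------------------------------------------

def _poisson_pmf(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln, xlogy
    return np.exp(xlogy(y, lam) - lam - gammaln(y + 1.0))


class PoissonPITZ(autodiff.Op):
    """y, lambda -> z = ndtri(midpoint distributional transform).

    Differentiable in lambda: du/dlambda = -(p(y-1) + p(y)) / 2 (Poisson
    CDF identity dF(k)/dlambda = -p(k)), dz/du = 1/phi(z). Gradient is
    zeroed where the clamps bind.
    """

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=np.int64)

    def forward(self, lam: np.ndarray) -> np.ndarray:
        from scipy.special import gammaincc
        y = self.y
        # Poisson CDF F(y-1; lam) = Q(y, lam) (regularized upper gamma)
        cdf_left = np.where(y > 0, gammaincc(np.maximum(y, 1), lam), 0.0)
        pmf = _poisson_pmf(y, lam)
        u_raw = cdf_left + 0.5 * pmf
        self.interior = (u_raw > U_EPS) & (u_raw < 1 - U_EPS)
        u = np.clip(u_raw, U_EPS, 1 - U_EPS)
        self.z = np.clip(ndtri(u), -Z_MAX, Z_MAX)
        self.interior &= np.abs(self.z) < Z_MAX
        pmf_left = np.where(y > 0, _poisson_pmf(np.maximum(y - 1, 0), lam), 0.0)
        self.du_dlam = -0.5 * (pmf_left + pmf)
        return self.z

    def backward(self, grad):
        phi = np.exp(-0.5 * self.z ** 2) / np.sqrt(2 * np.pi)
        return (grad * self.interior * self.du_dlam / phi,)


class CopulaNLL(autodiff.Op):
    """(edge weights, z_obs) -> averaged negative log copula density.

    Computes -log c(u_obs; R00) for each label column of z_obs, averaged
    over labels and divided by the number of observed nodes. R00 is the
    re-standardized observed block of Sigma = K^-1, with K = I + L(w)
    assembled from the edge weights. Sigma00^-1 is obtained directly as
    the Schur complement K00 - K01 K11^-1 K10, so the cost is cubic in the
    block sizes rather than requiring the full n x n inverse, and the
    gradient with respect to the edge weights is assembled in closed form.
    """

    def __init__(self, edges: np.ndarray, n: int, obs_index: np.ndarray,
                 dtype=np.float64):
        self.edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        self.n = n
        self.dtype = dtype
        self.obs = np.asarray(obs_index, dtype=np.int64)
        if self.obs.size == 0:
            raise ValidationError("obs_index must be non-empty")
        mask = np.ones(n, dtype=bool)
        mask[self.obs] = False
        self.miss = np.flatnonzero(mask)

    @staticmethod
    def _spd_inverse(M: np.ndarray):
        """(logdet, inverse) of an SPD matrix via Cholesky + LAPACK potri."""
        potrf, potri = scipy.linalg.get_lapack_funcs(("potrf", "potri"), (M,))
        c, info = potrf(M, lower=1)
        if info != 0:
            raise ValidationError("matrix not positive definite")
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        inv, info = potri(c, lower=1)
        if info != 0:
            raise ValidationError("inversion from Cholesky factor failed")
        inv = np.tril(inv) + np.tril(inv, -1).T
        return logdet, inv

    def forward(self, w: np.ndarray, z: np.ndarray):
        n, obs, miss = self.n, self.obs, self.miss
        self._z_was_1d = z.ndim == 1
        Z = (z if z.ndim == 2 else z[:, None]).astype(self.dtype)
        w = w.astype(self.dtype)
        m, L = Z.shape
        K = np.zeros((n, n), dtype=self.dtype)
        if len(w):
            i, j = self.edges[:, 0], self.edges[:, 1]
            K[i, j] = -w
            K[j, i] = -w
            deg = np.zeros(n, dtype=self.dtype)
            np.add.at(deg, i, w)
            np.add.at(deg, j, w)
            K[np.diag_indices(n)] = 1.0 + deg
        else:
            K[np.diag_indices(n)] = 1.0
        if miss.size:
            K10 = K[np.ix_(miss, obs)]
            cf11 = scipy.linalg.cho_factor(K[np.ix_(miss, miss)], lower=True)
            P = scipy.linalg.cho_solve(cf11, K10)           # K11^-1 K10
            M = K[np.ix_(obs, obs)] - K10.T @ P             # = Sigma00^-1
        else:
            P = None
            M = K[np.ix_(obs, obs)]
        logdetM, C = self._spd_inverse(M)                   # C = Sigma00
        d = np.diag(C).copy()
        s = np.sqrt(d)
        W = s[:, None] * Z                                  # scaled scores
        MW = M @ W
        quads = np.einsum("ij,ij->j", W, MW)
        nll = 0.5 * (-logdetM - np.sum(np.log(d))) * L \
            + 0.5 * np.sum(quads - np.einsum("ij,ij->j", Z, Z))
        self._cache = (M, C, d, s, Z, W, MW, P)
        self._scale = 1.0 / (L * m)
        return np.float64(nll * self._scale)

    def backward(self, grad):
        M, C, d, s, Z, W, MW, P = self._cache
        m, L = Z.shape
        cot = self.dtype(float(grad) * self._scale)
        # dNLL/dM: -L/2 C (logdet) + 1/2 W W^T (quadratics)
        G = cot * (-0.5 * L * C + 0.5 * (W @ W.T))
        # via d = diag(C): -L/(2d) from -sum log d, plus quadratic term
        g_d = cot * (-0.5 * L / d + 0.5 * np.einsum("ij,ij->i", Z, MW) / s)
        G -= (C * g_d) @ C                                  # d(diag(M^-1)) chain
        gz = cot * (s[:, None] * MW - Z)
        # Gradient on K entries: GK = [[G, -GP'], [-PG', PGP']] in
        # (obs, miss) block order; G is symmetric so GK is too, and only
        # its diagonal and the graph's edge entries are ever needed:
        # dNLL/dw_e = GK[ii] + GK[jj] - 2 GK[ij] for edge e = (i, j).
        n, obs, miss = self.n, self.obs, self.miss
        pos = np.full(n, -1, dtype=np.int64)   # node -> position in its block
        pos[obs] = np.arange(obs.size)
        in_obs = np.zeros(n, dtype=bool)
        in_obs[obs] = True
        diag_full = np.zeros(n, dtype=self.dtype)
        diag_full[obs] = np.diag(G)
        if miss.size:
            pos[miss] = np.arange(miss.size)
            Q = P @ G                                        # (miss x obs)
            diag_full[miss] = np.einsum("ij,ij->i", Q, P)
        if len(self.edges):
            i, j = self.edges[:, 0], self.edges[:, 1]
            gij = np.empty(len(self.edges), dtype=self.dtype)
            oo = in_obs[i] & in_obs[j]
            gij[oo] = G[pos[i[oo]], pos[j[oo]]]
            if miss.size:
                om = in_obs[i] & ~in_obs[j]
                mo = ~in_obs[i] & in_obs[j]
                mm = ~in_obs[i] & ~in_obs[j]
                # obs-miss entry is -(GP')[a,b] = -Q[b,:] . e_a
                gij[om] = -Q[pos[j[om]], pos[i[om]]]
                gij[mo] = -Q[pos[i[mo]], pos[j[mo]]]
                if mm.any():
                    gij[mm] = np.einsum(
                        "ij,ij->i", Q[pos[i[mm]]], P[pos[j[mm]]])
            gw = diag_full[i] + diag_full[j] - 2.0 * gij
        else:
            gw = np.empty(0)
        gw = gw.astype(np.float64)
        gz = gz.astype(np.float64)
        return gw, (gz[:, 0] if self._z_was_1d else gz)
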