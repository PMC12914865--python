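"""GCN trunk and task head producing per-cell, per-label marginal outputs.

A single raw score s per (cell, label) feeds both marginal readings of
the label: the Bernoulli probability sigmoid(s) used by the binary
cross-entropy term, and the Poisson rate softplus(s) whose distributional
transform enters the copula. The trunk is a standard two-layer GCN
(H1 = relu(S X W0), H2 = S H1 W1) over the symmetric-normalized
adjacency S; the head is a one-hidden-layer perceptron with one output
column per label. Dropout (after the first GCN layer) is active only in
training mode.

Forward passes are written on :class:`~copulagcn.autodiff.Tensor` so the
same code serves inference (via the wrappers returning plain arrays) and
training (gradients through autodiff).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse
import scipy.special

from . import autodiff as ad
from .copula_core import PairwiseRegressor
from .data_io import ValidationError


@dataclasses.dataclass
class MarginalOutputs:
    """Raw scores with their Bernoulli and Poisson readings (cells x labels)."""

    scores: np.ndarray
    probs: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        if not (self.scores.shape == self.probs.shape == self.rates.shape):
            raise ValidationError("inconsistent output shapes")
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            raise ValidationError("probabilities must be strictly in (0,1)")
        if np.any(self.rates <= 0):
            raise ValidationError("rates must be positive")


@dataclasses.dataclass
class ModelParams:
    """All trainable parameters; the pairwise regressor handle is shared
    with the dependence model."""

    W0: ad.Tensor
    W1: ad.Tensor
    Wh: ad.Tensor
    bh: ad.Tensor
    Wo: ad.Tensor
    bo: ad.Tensor
    pair_W_left: ad.Tensor
    pair_W_right: ad.Tensor
    pair_b1: ad.Tensor
    pair_w2: ad.Tensor
    pair_b2: ad.Tensor
    intercept: ad.Tensor  # used by the copula-only ablation

    def trainable(self, mode: str = "full") -> list[ad.Tensor]:
        if mode == "copula_only":
            return [self.intercept, self.pair_W_left, self.pair_W_right,
                    self.pair_b1, self.pair_w2, self.pair_b2]
        base = [self.W0, self.W1, self.Wh, self.bh, self.Wo, self.bo]
        if mode == "gcn_only":
            return base
        return base + [self.pair_W_left, self.pair_W_right, self.pair_b1,
                       self.pair_w2, self.pair_b2]

    def regressor(self) -> PairwiseRegressor:
        return PairwiseRegressor(
            W_left=self.pair_W_left.value, W_right=self.pair_W_right.value,
            b1=self.pair_b1.value, w2=self.pair_w2.value.ravel(),
            b2=float(np.ravel(self.pair_b2.value)[0]))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


def init_params(n_features: int, n_labels: int, rng: np.random.Generator,
                hidden_dim: int = 64, head_dim: int = 32,
                pair_hidden: int = 32) -> ModelParams:
    """Glorot-initialized parameters; pairwise final layer starts at zero
    (edges begin at the uniform softplus(0) = ln 2 weight)."""
    pair_scale = np.sqrt(2.0 / (2 * n_features + pair_hidden))
    t = lambda v: ad.Tensor(v, requires_grad=True)
    return ModelParams(
        W0=t(_glorot(rng, n_features, hidden_dim)),
        W1=t(_glorot(rng, hidden_dim, hidden_dim)),
        Wh=t(_glorot(rng, hidden_dim, head_dim)),
        bh=t(np.zeros(head_dim)),
        Wo=t(_glorot(rng, head_dim, n_labels)),
        bo=t(np.zeros(n_labels)),
        pair_W_left=t(rng.normal(0, pair_scale, (n_features, pair_hidden))),
        pair_W_right=t(rng.normal(0, pair_scale, (n_features, pair_hidden))),
        pair_b1=t(np.zeros(pair_hidden)),
        pair_w2=t(np.zeros((pair_hidden, 1))),
        pair_b2=t(np.zeros(1)),
        intercept=t(np.zeros((1, n_labels))),
    )


def gcn_forward_graph(X: ad.Tensor | np.ndarray, S: scipy.sparse.spmatrix,
                      params: ModelParams,
                      dropout_mask: np.ndarray | None = None) -> ad.Tensor:
    """H2 = S relu(S X W0) W1, with optional dropout mask after layer 1."""
    X = ad.as_tensor(X)
    if X.shape[1] != params.W0.shape[0]:
        raise ValidationError(
            f"feature dim {X.shape[1]} != W0 input {params.W0.shape[0]}")
    h1 = ad.relu(ad.sparse_matmul(S, ad.matmul(X, params.W0)))
    if dropout_mask is not None:
        h1 = ad.mul(h1, dropout_mask)
    return ad.sparse_matmul(S, ad.matmul(h1, params.W1))


def task_head_graph(embeddings: ad.Tensor, params: ModelParams) -> ad.Tensor:
    """Raw scores: relu hidden layer then per-label linear output."""
    h = ad.relu(ad.add(ad.matmul(embeddings, params.Wh), params.bh))
    return ad.add(ad.matmul(h, params.Wo), params.bo)


def gcn_forward(features: np.ndarray, S: scipy.sparse.spmatrix,
                params: ModelParams) -> np.ndarray:
    """Inference-mode trunk forward returning a plain array."""
    x = np.asarray(getattr(features, "values", features), dtype=np.float64)
    return gcn_forward_graph(x, S, params).value


def task_head(embeddings: np.ndarray, params: ModelParams) -> MarginalOutputs:
    """Inference-mode head forward (dropout off, deterministic)."""
    scores = task_head_graph(ad.as_tensor(embeddings), params).value
    return outputs_from_scores(scores)


def outputs_from_scores(scores: np.ndarray) -> MarginalOutputs:
    probs = np.clip(scipy.special.expit(scores), 1e-12, 1 - 1e-12)
    rates = np.maximum(np.logaddexp(0.0, scores), 1e-12)
    return MarginalOutputs(scores=scores, probs=probs, rates=rates)


def bce_loss_graph(scores: ad.Tensor, y: np.ndarray,
                   mask: np.ndarray) -> ad.Tensor:
    """Mean binary cross-entropy over masked cells and all labels.

    Evaluated from raw scores via softplus for numerical stability:
    -[y log sigmoid(s) + (1-y) log(1 - sigmoid(s))] = softplus(s) - y s.
    """
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size == 0:
        raise ValidationError("mask must be non-empty")
    s = ad.take_rows(scores, mask)
    y_obs = np.asarray(y, dtype=np.float64)[mask]
    return ad.mean(ad.add(ad.softplus(s), ad.mul(s, -y_obs)))


def bce_loss(probs: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Numpy BCE on probabilities (clamped), matching bce_loss_graph."""
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size == 0:
        raise ValidationError("mask must be non-empty")
    p = np.clip(np.asarray(probs, dtype=np.float64)[mask], 1e-12, 1 - 1e-12)
    yv = np.asarray(y, dtype=np.float64)[mask]
    return float(-np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p)))


@dataclasses.dataclass
class LossBreakdown:
    total: float
    bce: float
    copula_nll: float
    weight: float


def total_loss(bce: float, copula_nll: float, weight: float) -> LossBreakdown:
    """L_total = weight * copula_nll + bce (weight 0 = plain GCN objective)."""
    for name, v in (("bce", bce), ("copula_nll", copula_nll), ("weight", weight)):
        if not np.isfinite(v):
            raise ValidationError(f"non-finite loss term: {name} = {v}")
    return LossBreakdown(total=weight * copula_nll + bce, bce=bce,
                         copula_nll=copula_nll, weight=weight)
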