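"""End-to-end training, cross-validated evaluation and ablations.

Training is full-batch Adam on L_total = copula_weight * L_copula + L_BCE
over the observed (training-fold) nodes. Three modes:

``full``        GCN marginal scores + copula dependence (the model).
``gcn_only``    copula weight forced to zero; plain GCN classifier.
``copula_only`` the GCN trunk is replaced by one learnable intercept per
                label (constant scores across cells) and only the copula
                likelihood is optimized. At prediction time the constant
                marginal probabilities carry no between-cell information,
                so rank metrics sit at the all-ties convention value 0.5.

One master seed drives fold assignment, parameter initialization, dropout
and the per-epoch copula node subsample through named child streams, so a
run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np
import scipy.stats
import sklearn.metrics
import sklearn.model_selection

from . import autodiff as ad
from . import marginal_model as mm
from .cellgraph import CellGraph, gcn_normalized_adjacency
from .copula_core import (CopulaNLL, PoissonPITZ, build_precision,
                          conditional_adjusted_scores, poisson_pit)
from .data_io import MetricsReport, ValidationError

MODES = ("full", "gcn_only", "copula_only")
MAX_FULL_COPULA_NODES = 4000  # above this, subsample nodes for the copula term


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 0.01
    seed: int = 0
    copula_weight: float = 1.0
    mode: str = "full"
    folds: int = 5
    conditional_prediction: bool = False
    copula_subsample: int = 2048
    hidden_dim: int = 64
    head_dim: int = 32
    pair_hidden: int = 32
    dropout: float = 0.5
    weight_decay: float = 5e-4
    copula_precision: str = "single"  # linear algebra dtype of the loss op

    @property
    def copula_dtype(self):
        return np.float32 if self.copula_precision == "single" else np.float64

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if self.copula_precision not in ("single", "double"):
            raise ValidationError("copula_precision must be single or double")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("folds", "init", "dropout", "subsample", "pit")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def encode_labels(labels: np.ndarray):
    """One-vs-rest binary matrix with stable sorted label-column order."""
    order = sorted(set(str(x) for x in labels))
    if len(order) < 2:
        raise ValidationError("need at least 2 label categories")
    y = np.zeros((len(labels), len(order)))
    for c, lab in enumerate(order):
        y[np.asarray([str(x) for x in labels]) == lab, c] = 1.0
    return y, order


def stratified_kfold(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Per-cell fold index in 0..folds-1, stratified by label, seeded."""
    labels = np.asarray([str(x) for x in labels])
    values, counts = np.unique(labels, return_counts=True)
    small = values[counts < folds]
    if small.size:
        raise ValidationError(
            f"class {small[0]!r} has fewer than {folds} members")
    seed32 = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    skf = sklearn.model_selection.StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=seed32)
    assignment = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test] = fold
    return assignment


def _dropout_mask(rng, shape, rate: float) -> np.ndarray | None:
    if rate <= 0:
        return None
    return (rng.uniform(size=shape) >= rate) / (1.0 - rate)


def _forward_scores(X, S, params: mm.ModelParams, config: TrainConfig,
                    n: int, dropout_rng=None) -> ad.Tensor:
    if config.mode == "copula_only":
        return ad.matmul(ad.Tensor(np.ones((n, 1))), params.intercept)
    mask = None
    if dropout_rng is not None and config.dropout > 0:
        mask = _dropout_mask(dropout_rng, (n, config.hidden_dim), config.dropout)
    h2 = mm.gcn_forward_graph(X, S, params, dropout_mask=mask)
    return mm.task_head_graph(h2, params)


def train(features, graph: CellGraph, labels: np.ndarray,
          train_index: np.ndarray, config: TrainConfig):
    """Fit model parameters on the observed (training) nodes.

    Returns ``(params, log)`` with one LossBreakdown per epoch.
    """
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    n = X.shape[0]
    obs = np.sort(np.asarray(train_index, dtype=np.int64))
    if obs.size == 0:
        raise ValidationError("no labeled training node")
    y, label_order = encode_labels(labels)
    streams = _streams(config.seed)
    params = mm.init_params(X.shape[1], y.shape[1], streams["init"],
                            hidden_dim=config.hidden_dim,
                            head_dim=config.head_dim,
                            pair_hidden=config.pair_hidden)
    copula_active = config.mode == "copula_only" or (
        config.mode == "full" and config.copula_weight > 0)
    effective_mode = config.mode
    if config.mode == "full" and not copula_active:
        effective_mode = "gcn_only"  # identical objective and parameter set
    opt = ad.Adam(params.trainable(effective_mode), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    S = gcn_normalized_adjacency(graph)
    Xc = ad.Tensor(X)
    log: list[mm.LossBreakdown] = []
    weight = 0.0 if effective_mode == "gcn_only" else (
        1.0 if config.mode == "copula_only" else config.copula_weight)

    for epoch in range(config.epochs):
        opt.zero_grad()
        scores = _forward_scores(Xc, S, params, config, n,
                                 dropout_rng=streams["dropout"]
                                 if effective_mode != "copula_only" else None)
        terms = []
        bce_val = 0.0
        if config.mode != "copula_only":
            bce = mm.bce_loss_graph(scores, y, obs)
            terms.append(bce)
            bce_val = float(bce.value)
        nll_val = 0.0
        if copula_active:
            obs_c = obs
            if obs.size > MAX_FULL_COPULA_NODES:
                obs_c = np.sort(streams["subsample"].choice(
                    obs, size=min(config.copula_subsample, obs.size),
                    replace=False))
            lam = ad.softplus(ad.take_rows(scores, obs_c))
            lam = ad.clip(lam, 1e-8, 1e8)
            z = PoissonPITZ(y[obs_c].astype(np.int64))(lam)
            w = _edge_weights_graph(Xc, graph, params)
            nll = CopulaNLL(graph.edges, n, obs_c,
                            dtype=config.copula_dtype)(w, z)
            nll_val = float(nll.value)
            terms.append(ad.mul(nll, weight))
        loss = terms[0] if len(terms) == 1 else ad.add(terms[0], terms[1])
        breakdown = mm.total_loss(bce_val, nll_val,
                                  weight if copula_active else 0.0)
        if not np.isfinite(loss.value):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        log.append(breakdown)
        loss.backward()
        opt.step()
    return params, log


def _edge_weights_graph(Xc: ad.Tensor, graph: CellGraph,
                        params: mm.ModelParams) -> ad.Tensor:
    """Differentiable per-edge softplus scores, sharing the per-node
    projections of the pairwise regressor across edges."""
    if graph.n_edges == 0:
        return ad.Tensor(np.empty(0))
    ei, ej = graph.edges[:, 0], graph.edges[:, 1]
    U = ad.matmul(Xc, params.pair_W_left)
    V = ad.matmul(Xc, params.pair_W_right)
    def h(a_idx, b_idx):
        pre = ad.add(ad.add(ad.take_rows(U, a_idx), ad.take_rows(V, b_idx)),
                     params.pair_b1)
        return ad.add(ad.matmul(ad.tanh(pre), params.pair_w2), params.pair_b2)
    raw = ad.mul(ad.add(h(ei, ej), h(ej, ei)), 0.5)
    return ad.reshape(ad.softplus(raw), (-1,))


def predict(params: mm.ModelParams, features, graph: CellGraph,
            config: TrainConfig, test_index: np.ndarray,
            obs_index: np.ndarray | None = None,
            labels: np.ndarray | None = None):
    """Marginal outputs for test cells; optionally dependence-adjusted.

    With ``conditional_prediction`` on (and labels/obs provided), the
    training labels act as the observed block of the latent Gaussian and
    the returned ``adjusted`` array holds the conditional P(y=1).
    """
    X = np.asarray(getattr(features, "values", features), dtype=np.float64)
    n = X.shape[0]
    test_index = np.asarray(test_index, dtype=np.int64)
    if obs_index is not None and np.intersect1d(test_index, obs_index).size:
        raise ValidationError("test index overlaps the observed block")
    S = gcn_normalized_adjacency(graph)
    scores = _forward_scores(ad.Tensor(X), S, params, config, n).value
    outputs = mm.outputs_from_scores(scores)
    adjusted = None
    if (config.conditional_prediction and config.mode != "gcn_only"
            and obs_index is not None and labels is not None
            and graph.n_edges > 0):
        obs = np.sort(np.asarray(obs_index, dtype=np.int64))
        y, _ = encode_labels(labels)
        model = build_precision(graph, X, params.regressor())
        pit = poisson_pit(y[obs].astype(np.int64), outputs.rates[obs])
        adjusted = conditional_adjusted_scores(
            pit.u, outputs.rates[test_index], model, obs, test_index)
    return mm.MarginalOutputs(scores=scores[test_index],
                              probs=outputs.probs[test_index],
                              rates=outputs.rates[test_index]), adjusted


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Mann-Whitney ROC-AUC; tied scores contribute 1/2 per pair.

    Returns None when one class is absent. Constant scores give exactly
    0.5 by the ties convention.
    """
    truth = np.asarray(truth, dtype=bool)
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        return None
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(pred_scores: np.ndarray, true_labels: np.ndarray,
             label_order: list[str]) -> dict[str, dict[str, float | None]]:
    """Per-label one-vs-rest accuracy (threshold 0.5), ROC-AUC and PR-AUC.

    ``pred_scores`` holds probability scores in [0,1], one column per
    label in ``label_order``. A label with a single class in the truth
    gets None metrics (excluded from macro averaging upstream).
    """
    truth_str = np.asarray([str(x) for x in true_labels])
    result: dict[str, dict[str, float | None]] = {}
    for c, lab in enumerate(label_order):
        t = truth_str == lab
        s = pred_scores[:, c]
        if t.all() or not t.any():
            warnings.warn(f"label {lab!r} has a single class in this fold; "
                          "metrics recorded as missing")
            result[lab] = {"accuracy": None, "roc_auc": None, "pr_auc": None}
            continue
        result[lab] = {
            "accuracy": float(np.mean((s >= 0.5) == t)),
            "roc_auc": roc_auc(s, t),
            "pr_auc": float(sklearn.metrics.average_precision_score(t, s)),
        }
    return result


def cross_validate(features, graph: CellGraph, labels: np.ndarray,
                   config: TrainConfig):
    """Stratified k-fold CV; returns (MetricsReport, out-of-fold scores).

    The score matrix has one probability per (cell, label), each cell
    scored exactly once by the model trained on the other folds.
    """
    labels = np.asarray(labels)
    _, label_order = encode_labels(labels)
    assignment = stratified_kfold(labels, config.folds, config.seed)
    per_fold = []
    oof = np.full((len(labels), len(label_order)), np.nan)
    for fold in range(config.folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        params, _ = train(features, graph, labels, train_idx, config)
        outputs, adjusted = predict(params, features, graph, config,
                                    test_idx, obs_index=train_idx,
                                    labels=labels)
        scores = adjusted if adjusted is not None else outputs.probs
        oof[test_idx] = scores
        per_fold.append(evaluate(scores, labels[test_idx], label_order))
    metadata = {"seed": config.seed, "mode": config.mode,
                "folds": config.folds, "config_hash": config.hash(),
                "label_order": label_order}
    return MetricsReport.from_folds(per_fold, metadata), oof


def run_cv(features, graph: CellGraph, labels: np.ndarray,
           config: TrainConfig) -> MetricsReport:
    """Stratified k-fold cross-validation of the configured model."""
    report, _ = cross_validate(features, graph, labels, config)
    return report
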