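"""Spectral graph-convolutional classifier with self-attention pooling.

Architecture (defaults reproduce the published configuration):

* two first-order spectral convolutions, H' = ReLU(S H W), taking the node
  features from N (each node's row of the subject's FC matrix) to 25 and
  then to 10 dimensions; S is the shared backbone operator;
* one self-attention graph pooling (SAGPool) layer: each node is scored by a
  one-filter graph convolution z = tanh(S H Theta), the k=10 highest-scoring
  nodes are kept (stable tie-break toward lower node index, returned in
  ascending original order), their features scaled by their scores, and the
  adjacency restricted to the kept nodes;
* the pooled features are flattened (row-major over kept node, feature) and
  projected to length 15; the phenotype encoding is projected to length 2;
  the two are concatenated and read out by a single dense softmax layer.

Training: Adam with learning rate 0.01 on categorical cross-entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor, glorot_uniform
from .data_model import Cohort
from .graphs import BackboneGraph, normalized_adjacency

logger = logging.getLogger(__name__)

__all__ = ["GCNConfig", "GCNModel", "PoolResult", "graph_conv", "sag_pool",
           "gcn_forward", "train_gcn", "predict_gcn"]


@dataclass
class GCNConfig:
    """Hyper-parameters; defaults follow the published architecture."""

    feature_dims: Sequence[int] = (25, 10)
    pool_k: int = 10
    gnn_out_dim: int = 15
    phen_out_dim: int = 2
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    class_weights: bool = False
    seed: int = 0

    def validate(self, n_nodes: int) -> None:
        if self.pool_k > n_nodes:
            raise ValueError(f"pool_k={self.pool_k} exceeds N={n_nodes}")
        if any(d <= 0 for d in self.feature_dims) or self.pool_k <= 0:
            raise ValueError("layer dimensions must be positive")


class GCNModel:
    """Parameter container for the GCN classifier."""

    def __init__(self, n_nodes: int, phen_len: int, n_classes: int,
                 cfg: GCNConfig, rng: np.random.Generator) -> None:
        cfg.validate(n_nodes)
        d1, d2 = cfg.feature_dims
        self.cfg = cfg
        self.n_nodes, self.phen_len, self.n_classes = n_nodes, phen_len, n_classes

        def param(shape, fan_in=None, fan_out=None):
            return Tensor(glorot_uniform(rng, shape, fan_in, fan_out),
                          requires_grad=True)

        self.W1 = param((n_nodes, d1))
        self.W2 = param((d1, d2))
        self.theta = param((d2, 1))
        self.W_gnn = param((cfg.pool_k * d2, cfg.gnn_out_dim))
        self.b_gnn = Tensor(np.zeros(cfg.gnn_out_dim), requires_grad=True)
        self.W_phen = param((phen_len, cfg.phen_out_dim))
        self.b_phen = Tensor(np.zeros(cfg.phen_out_dim), requires_grad=True)
        self.W_out = param((cfg.gnn_out_dim + cfg.phen_out_dim, n_classes))
        self.b_out = Tensor(np.zeros(n_classes), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.W2, self.theta, self.W_gnn, self.b_gnn,
                self.W_phen, self.b_phen, self.W_out, self.b_out]

    def state_dict(self) -> dict[str, np.ndarray]:
        names = ["W1", "W2", "theta", "W_gnn", "b_gnn", "W_phen", "b_phen",
                 "W_out", "b_out"]
        return {n: getattr(self, n).data.copy() for n in names}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, value in state.items():
            getattr(self, name).data = np.array(value, dtype=np.float64)


@dataclass
class PoolResult:
    """Outputs of one SAGPool application (single graph)."""

    scores: np.ndarray          # z, per node
    kept_index: np.ndarray      # idx, ascending original order, |idx| = k
    masked_scores: np.ndarray   # z[idx]
    pooled_features: np.ndarray  # H[idx, :] * z[idx]
    pooled_adjacency: np.ndarray  # A[idx][:, idx]


def graph_conv(H: np.ndarray, S: np.ndarray, W: np.ndarray,
               activation: str = "relu") -> np.ndarray:
    """One first-order spectral convolution: sigma(S H W).

    ``H`` may be (N, d) or batched (B, N, d); ``S`` is the normalised
    self-looped operator of the backbone graph.
    """
    if H.shape[-2] != S.shape[0] or H.shape[-1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: H {H.shape}, S {S.shape}, W {W.shape}")
    out = np.matmul(np.matmul(S, H), W) if H.ndim == 2 else np.matmul(S @ H, W)
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "linear":
        return out
    raise ValueError(f"unknown activation {activation!r}")


def _topk_ascending(z: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, ties to the lower index, returned in
    ascending original-node order."""
    order = np.argsort(-z, kind="stable")  # stable: equal scores keep low index
    return np.sort(order[:k])


def sag_pool(H: np.ndarray, A: np.ndarray, S_pool: np.ndarray,
             theta: np.ndarray, k: int) -> PoolResult:
    """Self-attention graph pooling on a single graph (reference path)."""
    n = H.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes {n}")
    z = np.tanh(S_pool @ H @ theta).ravel()
    idx = _topk_ascending(z, k)
    z_mask = z[idx]
    pooled_h = H[idx, :] * z_mask[:, None]
    pooled_a = A[np.ix_(idx, idx)]
    return PoolResult(scores=z, kept_index=idx, masked_scores=z_mask,
                      pooled_features=pooled_h, pooled_adjacency=pooled_a)


def _forward_graph(model: GCNModel, X: Tensor, S: np.ndarray,
                   phen: Tensor) -> Tensor:
    """Batched forward pass to logits.  X: (B, N, N), phen: (B, p)."""
    S_t = Tensor(S)
    h1 = (S_t @ X @ model.W1).relu()
    h2 = (S_t @ h1 @ model.W2).relu()
    # SAGPool scores via the same normalised operator (A(l-1) = backbone A)
    z = (S_t @ h2 @ model.theta).tanh()            # (B, N, 1)
    z_np = z.data[:, :, 0]
    idx = np.stack([_topk_ascending(z_np[b], model.cfg.pool_k)
                    for b in range(z_np.shape[0])])
    h_kept = h2.gather_rows(idx)                    # (B, k, d2)
    z_kept = z.gather_rows(idx)                     # (B, k, 1)
    pooled = h_kept * z_kept
    flat = pooled.reshape(pooled.shape[0], -1)      # row-major (node, feature)
    g_vec = flat @ model.W_gnn + model.b_gnn        # linear projection to 15
    p_vec = phen @ model.W_phen + model.b_phen      # linear projection to 2
    joint = Tensor.concat([g_vec, p_vec], axis=-1)
    return joint @ model.W_out + model.b_out


def gcn_forward(model: GCNModel, fc_values: np.ndarray, graph: BackboneGraph,
                phen_vector: np.ndarray) -> np.ndarray:
    """Class probabilities for one subject (or a batch).

    ``fc_values``: (N, N) or (B, N, N); ``phen_vector``: (p,) or (B, p).
    """
    single = fc_values.ndim == 2
    X = fc_values[None] if single else fc_values
    phen = phen_vector[None] if phen_vector.ndim == 1 else phen_vector
    if X.shape[-1] != graph.n_nodes:
        raise ValueError(
            f"FC matrix is {X.shape[-2]}x{X.shape[-1]} but graph has "
            f"N={graph.n_nodes}")
    logits = _forward_graph(model, Tensor(X), graph.normalized, Tensor(phen))
    probs = logits.softmax()
    return probs[0] if single else probs


def train_gcn(cohort_train: Cohort, graph: BackboneGraph, cfg: GCNConfig,
              validation: Optional[Cohort] = None,
              site_levels: Optional[Sequence[str]] = None) -> GCNModel:
    """Train the GCN on a cohort with Adam / cross-entropy.

    If a validation cohort is given, the returned parameters are those with
    the best validation accuracy over the epochs; otherwise the final ones.
    Fully deterministic given ``cfg.seed``.
    """
    y = cohort_train.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if site_levels is None:
        site_levels = cohort_train.site_levels
    X = cohort_train.matrices()
    P = cohort_train.phenotype_matrix(site_levels)
    n_classes = len(cohort_train.label_names)

    rng = np.random.default_rng(cfg.seed)
    model = GCNModel(graph.n_nodes, P.shape[1], n_classes, cfg, rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    weights = None
    if cfg.class_weights:
        counts = np.bincount(y, minlength=n_classes).astype(float)
        weights = counts.sum() / (n_classes * np.maximum(counts, 1))

    if validation is not None:
        Xv = validation.matrices()
        Pv = validation.phenotype_matrix(site_levels)
        yv = validation.labels()
    best_acc, best_state = -1.0, None

    n = X.shape[0]
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = perm[start:start + cfg.batch_size]
            logits = _forward_graph(model, Tensor(X[batch]), graph.normalized,
                                    Tensor(P[batch]))
            if weights is not None:
                # weighted CE via per-sample scaling of the fused loss
                loss = _weighted_ce(logits, y[batch], weights[y[batch]])
            else:
                loss = logits.cross_entropy(y[batch])
            opt.zero_grad()
            loss.backward()
            opt.step()
        if validation is not None:
            probs = _forward_graph(model, Tensor(Xv), graph.normalized,
                                   Tensor(Pv)).softmax()
            acc = float(np.mean(probs.argmax(axis=1) == yv))
            if acc > best_acc:
                best_acc, best_state = acc, model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
        logger.info("train_gcn: restored best validation accuracy %.3f", best_acc)
    return model


def _weighted_ce(logits: Tensor, labels: np.ndarray, w: np.ndarray) -> Tensor:
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1))
    picked = z[np.arange(z.shape[0]), labels]
    per = logsumexp - picked
    loss_val = float(np.sum(w * per) / np.sum(w))
    out = Tensor(loss_val, parents=(logits,))
    probs = np.exp(z - logsumexp[:, None])

    def backward(g):
        grad = probs.copy()
        grad[np.arange(grad.shape[0]), labels] -= 1.0
        grad *= (w / np.sum(w))[:, None]
        logits._accumulate(g * grad)

    out._backward = backward
    return out


def predict_gcn(model: GCNModel, cohort: Cohort, graph: BackboneGraph,
                site_levels: Optional[Sequence[str]] = None) -> np.ndarray:
    """Per-subject class probabilities (n_subjects, n_classes)."""
    if site_levels is None:
        site_levels = cohort.site_levels
    return gcn_forward(model, cohort.matrices(), graph,
                       cohort.phenotype_matrix(site_levels))
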