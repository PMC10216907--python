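"""Relationship-strength message-passing model and its training loop.

Architecture: input batch normalization over the feature columns, two
message-passing layers, and a fully connected map to one score per node.
Each message-passing layer computes

    e' = BatchNorm(e @ W1 + L @ e @ W2)

where ``L = D^{-1/2} R D^{-1/2}`` is the normalized relationship-strength
operator; equivalently, per node, messages ``m_{i<-j} = e_j * R_ij /
sqrt(S_i S_j)`` are summed after the W2 map and added to the W1-mapped
self state.  No nonlinearity follows the normalization by default (an
optional ReLU sits behind a flag).

Everything is plain NumPy with hand-written reverse-mode gradients and a
NAdam optimizer, so training is deterministic given the seed and needs no
deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from rsgnn.entropy_features import DEFAULT_WIDTH, build_features
from rsgnn.netio import Network
from rsgnn.relationship import StrengthOperator, strength_matrix
from rsgnn.sir import InfluenceLabels

__all__ = [
    "BatchNorm",
    "LayerParams",
    "RSGNNModel",
    "TrainConfig",
    "message_passing",
    "forward",
    "train",
    "rank",
    "save_model",
    "load_model",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class BatchNorm:
    """1-d batch normalization over columns, with trainable scale/shift.

    Training mode normalizes with batch statistics and updates running
    statistics; eval mode uses the running statistics.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache = None
        self.d_gamma = np.zeros(dim)
        self.d_beta = np.zeros(dim)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} columns, got {x.shape[1]}")
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (x - mu) * inv_std
            m = x.shape[0]
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * unbiased
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + _BN_EPS)
            xhat = (x - self.running_mean) * inv_std
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray, training: bool) -> np.ndarray:
        xhat, inv_std = self._cache
        self.d_gamma = (dout * xhat).sum(axis=0)
        self.d_beta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        if not training:
            return dxhat * inv_std
        m = dout.shape[0]
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params(self):
        return [("gamma", self), ("beta", self)]


class LayerParams:
    """One message-passing layer: self path W1, neighbor path W2, batch norm."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, relu: bool = False):
        bound = 1.0 / np.sqrt(in_dim)
        self.W1 = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.W2 = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.bn = BatchNorm(out_dim)
        self.relu = relu
        self.d_W1 = np.zeros_like(self.W1)
        self.d_W2 = np.zeros_like(self.W2)
        self._cache = None

    def forward(self, e: np.ndarray, L: sp.csr_matrix, training: bool) -> np.ndarray:
        if e.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"state has {e.shape[1]} columns, layer expects {self.W1.shape[0]}"
            )
        Le = L @ e
        h = e @ self.W1 + Le @ self.W2
        out = self.bn.forward(h, training)
        if self.relu:
            mask = out > 0
            out = out * mask
            self._cache = (e, Le, L, mask)
        else:
            self._cache = (e, Le, L, None)
        return out

    def backward(self, dout: np.ndarray, training: bool) -> np.ndarray:
        e, Le, L, mask = self._cache
        if mask is not None:
            dout = dout * mask
        dh = self.bn.backward(dout, training)
        self.d_W1 = e.T @ dh
        self.d_W2 = Le.T @ dh
        # L is symmetric: d e = dh W1^T + L^T (dh W2^T)
        return dh @ self.W1.T + L @ (dh @ self.W2.T)


class RSGNNModel:
    """Input batch norm, two message-passing layers, linear scorer."""

    def __init__(
        self,
        in_dim: int = DEFAULT_WIDTH,
        hidden: Tuple[int, int] = (32, 32),
        seed: int = 0,
        relu: bool = False,
        basic_rule: str = "entropy",
    ):
        rng = np.random.default_rng(seed)
        self.in_dim = in_dim
        self.hidden = tuple(hidden)
        self.basic_rule = basic_rule
        self.input_bn = BatchNorm(in_dim)
        self.layer1 = LayerParams(in_dim, hidden[0], rng, relu=relu)
        self.layer2 = LayerParams(hidden[0], hidden[1], rng, relu=relu)
        bound = 1.0 / np.sqrt(hidden[1])
        self.fc_W = rng.uniform(-bound, bound, size=(hidden[1], 1))
        self.fc_b = rng.uniform(-bound, bound, size=(1,))
        self.d_fc_W = np.zeros_like(self.fc_W)
        self.d_fc_b = np.zeros_like(self.fc_b)
        self.trained = False
        self.loss_history: List[float] = []
        self.best_epoch: int = -1
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, F: np.ndarray, op: StrengthOperator, training: bool = False) -> np.ndarray:
        if F.shape[1] != self.in_dim:
            raise ValueError(f"features have {F.shape[1]} columns, model expects {self.in_dim}")
        if F.shape[0] != op.L.shape[0]:
            raise ValueError("feature matrix and operator disagree on node count")
        x = self.input_bn.forward(F, training)
        h1 = self.layer1.forward(x, op.L, training)
        h2 = self.layer2.forward(h1, op.L, training)
        scores = h2 @ self.fc_W + self.fc_b
        self._cache = h2
        return scores.ravel()

    def backward(self, d_scores: np.ndarray, op: StrengthOperator, training: bool = True) -> None:
        h2 = self._cache
        d = d_scores.reshape(-1, 1)
        self.d_fc_W = h2.T @ d
        self.d_fc_b = d.sum(axis=0)
        dh2 = d @ self.fc_W.T
        dh1 = self.layer2.backward(dh2, training)
        dx = self.layer1.backward(dh1, training)
        self.input_bn.backward(dx, training)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs, in a fixed order."""
        pairs = []
        for bn in (self.input_bn, self.layer1.bn, self.layer2.bn):
            pairs.append((bn.gamma, lambda b=bn: b.d_gamma))
            pairs.append((bn.beta, lambda b=bn: b.d_beta))
        pairs.append((self.layer1.W1, lambda: self.layer1.d_W1))
        pairs.append((self.layer1.W2, lambda: self.layer1.d_W2))
        pairs.append((self.layer2.W1, lambda: self.layer2.d_W1))
        pairs.append((self.layer2.W2, lambda: self.layer2.d_W2))
        pairs.append((self.fc_W, lambda: self.d_fc_W))
        pairs.append((self.fc_b, lambda: self.d_fc_b))
        return pairs


class NAdam:
    """NAdam with decoupled momentum schedule (library-default constants:
    betas (0.9, 0.999), eps 1e-8, momentum decay 0.004)."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8, psi=0.004):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps, self.psi = beta1, beta2, eps, psi
        self.t = 0
        self.mu_prod = 1.0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, grads=None):
        """One update; ``grads`` overrides the params' own gradient getters
        (used when gradients are accumulated over several graphs)."""
        self.t += 1
        t = self.t
        mu_t = self.beta1 * (1.0 - 0.5 * 0.96 ** (t * self.psi))
        mu_next = self.beta1 * (1.0 - 0.5 * 0.96 ** ((t + 1) * self.psi))
        self.mu_prod *= mu_t
        bias2 = 1.0 - self.beta2**t
        for i, ((p, grad_fn), m, v) in enumerate(zip(self.params, self.m, self.v)):
            g = grad_fn() if grads is None else grads[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = mu_next * m / (1.0 - self.mu_prod * mu_next) + (1.0 - mu_t) * g / (
                1.0 - self.mu_prod
            )
            vhat = v / bias2
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    train_networks: Sequence[Tuple[Network, InfluenceLabels]]
    lr: float = 0.001
    epochs: int = 2000
    rng_seed: int = 0
    hidden: Tuple[int, int] = (32, 32)
    width: int = DEFAULT_WIDTH
    relu: bool = False
    basic_rule: str = "entropy"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def message_passing(
    e: np.ndarray, op: StrengthOperator, p: LayerParams, training: bool = False
) -> np.ndarray:
    """Apply one message-passing layer (functional convenience wrapper)."""
    return p.forward(np.asarray(e, dtype=float), op.L, training)


def forward(
    F: np.ndarray, op: StrengthOperator, model: RSGNNModel, training: bool = False
) -> np.ndarray:
    return model.forward(np.asarray(F, dtype=float), op, training)


def train(cfg: TrainConfig) -> RSGNNModel:
    """Fit the model by MSE regression of scores onto SIR influence labels.

    Full-graph batches; one optimizer step per network per epoch,
    alternating over the training networks in their given order.
    """
    if not cfg.train_networks:
        raise ValueError("no training networks given")
    model = RSGNNModel(
        in_dim=cfg.width,
        hidden=cfg.hidden,
        seed=cfg.rng_seed,
        relu=cfg.relu,
        basic_rule=cfg.basic_rule,
    )
    prepared = []
    for g, labels in cfg.train_networks:
        if labels.t.shape[0] != g.n:
            raise ValueError("labels do not cover all nodes")
        bundle = build_features(g, width=cfg.width, basic_rule=cfg.basic_rule)
        # per-network target standardization: the networks' label scales
        # differ with their epidemic thresholds, and regressing the raw
        # scales forces network-specific offsets through the shared batch
        # norm, which does not survive transfer to unseen graphs.  Ranking
        # is invariant to this monotone rescaling.
        t = labels.t.astype(float)
        sd = t.std()
        t = (t - t.mean()) / sd if sd > 0 else t - t.mean()
        prepared.append((bundle.features, strength_matrix(g), t))
    opt = NAdam(model.parameters(), lr=cfg.lr)
    best_loss = np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for F, op, t in prepared:
            scores = model.forward(F, op, training=True)
            resid = scores - t
            loss = float(np.mean(resid**2))
            model.backward(2.0 * resid / resid.size, op, training=True)
            opt.step()
            epoch_loss += loss
        model.loss_history.append(epoch_loss)
        # keep the best-training-loss parameters: constant-lr NAdam can
        # wander off late in the run, and no test data is involved here
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = [(arr, arr.copy()) for _, arr in _named_tensors(model)]
            model.best_epoch = epoch
    for arr, saved in best_state:
        arr[...] = saved
    model.trained = True
    return model


def rank(model: RSGNNModel, g: Network):
    """Score and rank the nodes of ``g`` with a trained model.

    Features and the strength operator are recomputed for ``g`` (entropy
    weights are network-level quantities).  Returns a list of
    ``(original_label, score)`` in descending score order, ties broken by
    internal index.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    scores = score_nodes(model, g)
    order = np.lexsort((np.arange(g.n), -scores))
    return [(g.node_ids[i], float(scores[i])) for i in order]


def score_nodes(model: RSGNNModel, g: Network) -> np.ndarray:
    """Per-node scores in internal-index order (eval mode)."""
    bundle = build_features(g, width=model.in_dim, basic_rule=model.basic_rule)
    op = strength_matrix(g)
    return model.forward(bundle.features, op, training=False)


# -- serialization ----------------------------------------------------------

def save_model(model: RSGNNModel, path) -> None:
    """Versioned JSON archive of all tensors, dims, and config."""
    blob = {
        "format_version": 1,
        "in_dim": model.in_dim,
        "hidden": list(model.hidden),
        "basic_rule": model.basic_rule,
        "relu": model.layer1.relu,
        "trained": model.trained,
        "loss_history": model.loss_history,
        "tensors": {},
    }
    for name, arr in _named_tensors(model):
        blob["tensors"][name] = arr.tolist()
    Path(path).write_text(json.dumps(blob))


def load_model(path) -> RSGNNModel:
    blob = json.loads(Path(path).read_text())
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model archive version")
    model = RSGNNModel(
        in_dim=blob["in_dim"],
        hidden=tuple(blob["hidden"]),
        relu=blob["relu"],
        basic_rule=blob["basic_rule"],
    )
    for name, arr in _named_tensors(model):
        arr[...] = np.asarray(blob["tensors"][name])
    model.trained = blob["trained"]
    model.loss_history = list(blob["loss_history"])
    return model


def _named_tensors(model: RSGNNModel):
    out = []
    for prefix, bn in (
        ("input_bn", model.input_bn),
        ("bn1", model.layer1.bn),
        ("bn2", model.layer2.bn),
    ):
        out += [
            (f"{prefix}.gamma", bn.gamma),
            (f"{prefix}.beta", bn.beta),
            (f"{prefix}.running_mean", bn.running_mean),
            (f"{prefix}.running_var", bn.running_var),
        ]
    out += [
        ("layer1.W1", model.layer1.W1),
        ("layer1.W2", model.layer1.W2),
        ("layer2.W1", model.layer2.W1),
        ("layer2.W2", model.layer2.W2),
        ("fc.W", model.fc_W),
        ("fc.b", model.fc_b),
    ]
    return out
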