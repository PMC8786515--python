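"""Graph convolutional classifier over protein contact graphs.

Each convolution layer propagates node features through the
symmetric-normalized adjacency with self-loops:

    H^{l+1} = sigma( D_hat^{-1/2} (A + I) D_hat^{-1/2} H^l W^{l+1} )

where A is the binary contact adjacency, D_hat the degree matrix after
self-loop addition, and H^0 the M×54 node-feature matrix.  Three such
layers (54→54→108→216) are followed by a symmetric graph-level readout
(mean by default), two fully connected layers with dropout between them,
and a two-class softmax reported as the positive-class probability.

The network and its gradients are implemented directly in numpy: the
model is small (tens of thousands of parameters) and dense per-graph
matrix products are exact and fast at contact-graph sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_build import AdjacencyMatrix, ProteinGraph

DEFAULT_CONV_DIMS: Tuple[Tuple[int, int], ...] = ((54, 54), (54, 108), (108, 216))
DEFAULT_FC_DIMS: Tuple[int, ...] = (216, 64, 2)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_dims`` chain (out of layer l = in of layer l+1) starting at the
    54 node features; ``fc_dims`` runs from the pooled graph vector to the
    2-unit class head.  ``dropout`` acts on the hidden FC activation
    during training only.  ``use_bias=False`` gives the strict
    propagation rule with no affine offsets (used by the oracle tests).
    """

    conv_dims: Tuple[Tuple[int, int], ...] = DEFAULT_CONV_DIMS
    fc_dims: Tuple[int, ...] = DEFAULT_FC_DIMS
    dropout: float = 0.2
    activation: str = "relu"
    pooling: str = "mean"
    classification_threshold: float = 0.5
    use_bias: bool = True

    def __post_init__(self) -> None:
        for (a, b), (c, _) in zip(self.conv_dims, self.conv_dims[1:]):
            if b != c:
                raise ValueError(f"conv dims do not chain: out {b} vs next in {c}")
        if self.fc_dims[0] != self.conv_dims[-1][1]:
            raise ValueError("first FC width must equal last conv output width")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.pooling not in ("mean", "sum", "max"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.activation not in ("relu", "identity", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class ModelParams:
    """Learned weights: per-layer conv and FC matrices with biases."""

    conv_W: List[np.ndarray]
    conv_b: List[np.ndarray]
    fc_W: List[np.ndarray]
    fc_b: List[np.ndarray]
    seed: Optional[int] = None

    def flat(self) -> List[np.ndarray]:
        return self.conv_W + self.conv_b + self.fc_W + self.fc_b

    def copy(self) -> "ModelParams":
        return ModelParams(
            conv_W=[w.copy() for w in self.conv_W],
            conv_b=[b.copy() for b in self.conv_b],
            fc_W=[w.copy() for w in self.fc_W],
            fc_b=[b.copy() for b in self.fc_b],
            seed=self.seed,
        )


def init_params(config: ModelConfig, seed: int) -> ModelParams:
    """Variance-scaled (Glorot) uniform initialization with a recorded seed."""
    rng = np.random.default_rng(seed)

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        bound = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-bound, bound, size=(n_in, n_out))

    conv_W = [glorot(a, b) for a, b in config.conv_dims]
    conv_b = [np.zeros(b) for _, b in config.conv_dims]
    fc_W = [glorot(a, b) for a, b in zip(config.fc_dims, config.fc_dims[1:])]
    fc_b = [np.zeros(b) for b in config.fc_dims[1:]]
    return ModelParams(conv_W=conv_W, conv_b=conv_b, fc_W=fc_W, fc_b=fc_b, seed=seed)


def normalize_adjacency(adjacency: AdjacencyMatrix) -> np.ndarray:
    """Symmetric normalization with self-loops: D_hat^{-1/2}(A+I)D_hat^{-1/2}.

    The added identity guarantees every degree is >= 1, so the inverse
    square root is always defined; the result is symmetric with spectral
    radius <= 1 (an edgeless graph maps to the identity).
    """
    a_hat = adjacency.values.astype(float) + np.eye(adjacency.n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    return z


def _activate_grad(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    return np.ones_like(z)


def gcn_layer_forward(H: np.ndarray, norm_adj: np.ndarray, W: np.ndarray,
                      activation: str = "identity",
                      b: Optional[np.ndarray] = None) -> np.ndarray:
    """One propagation step: activation(norm_adj @ H @ W (+ b))."""
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"feature width {H.shape[1]} does not match W rows {W.shape[0]}")
    z = norm_adj @ H @ W
    if b is not None:
        z = z + b
    return _activate(z, activation)


def pool_graph(H: np.ndarray, pooling: str = "mean") -> np.ndarray:
    """Symmetric graph-level readout: column-wise mean, sum or max over nodes."""
    if pooling == "mean":
        return H.mean(axis=0)
    if pooling == "sum":
        return H.sum(axis=0)
    if pooling == "max":
        return H.max(axis=0)
    raise ValueError(f"unknown pooling {pooling!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _forward_cache(graph: ProteinGraph, params: ModelParams, config: ModelConfig,
                   dropout_mask: Optional[np.ndarray] = None) -> Dict:
    """Full forward pass keeping every intermediate needed for backprop.

    ``dropout_mask`` (pre-scaled, inverted-dropout convention) is applied
    to the hidden FC activation; ``None`` means inference.
    """
    if graph.features.shape[1] != config.conv_dims[0][0]:
        raise ValueError(
            f"graph {graph.id!r}: feature width {graph.features.shape[1]} != "
            f"model input width {config.conv_dims[0][0]}"
        )
    n_adj = normalize_adjacency(graph.adjacency)
    H = graph.features
    conv_in, conv_z = [], []
    for W, b in zip(params.conv_W, params.conv_b):
        conv_in.append(H)
        z = n_adj @ H @ W
        if config.use_bias:
            z = z + b
        conv_z.append(z)
        H = _activate(z, config.activation)
    pooled = pool_graph(H, config.pooling)
    if config.pooling == "max":
        argmax = H.argmax(axis=0)
    else:
        argmax = None

    # FC stack: hidden layers use the conv activation; dropout after the
    # hidden activation; final layer is linear into the softmax.
    fc_in, fc_z = [], []
    h = pooled
    n_fc = len(params.fc_W)
    for i, (W, b) in enumerate(zip(params.fc_W, params.fc_b)):
        fc_in.append(h)
        z = h @ W
        if config.use_bias:
            z = z + b
        fc_z.append(z)
        if i < n_fc - 1:
            h = _activate(z, config.activation)
            if dropout_mask is not None:
                h = h * dropout_mask
        else:
            h = z
    probs = _softmax(h)
    return {
        "n_adj": n_adj,
        "conv_in": conv_in,
        "conv_z": conv_z,
        "H_last": _activate(conv_z[-1], config.activation),
        "pooled": pooled,
        "argmax": argmax,
        "fc_in": fc_in,
        "fc_z": fc_z,
        "dropout_mask": dropout_mask,
        "probs": probs,
        "n_nodes": graph.n_nodes,
    }


def forward(graph: ProteinGraph, params: ModelParams, config: ModelConfig,
            training_mode: bool = False,
            rng: Optional[np.random.Generator] = None) -> float:
    """Positive-class probability for one protein graph.

    In training mode with a supplied ``rng``, inverted dropout is applied
    to the hidden FC activation; inference is deterministic.
    """
    mask = None
    if training_mode and config.dropout > 0:
        if rng is None:
            raise ValueError("training_mode with dropout requires an rng")
        keep = 1.0 - config.dropout
        width = config.fc_dims[1]
        mask = (rng.random(width) < keep).astype(float) / keep
    cache = _forward_cache(graph, params, config, dropout_mask=mask)
    return float(cache["probs"][1])


def predict(probability: float, threshold: float = 0.5) -> int:
    """Decision rule: positive iff probability >= threshold."""
    return int(probability >= threshold)


def backward(cache: Dict, label: int, params: ModelParams,
             config: ModelConfig) -> Tuple[float, ModelParams]:
    """Cross-entropy loss and its gradient for one cached forward pass.

    Returns ``(loss, grads)`` with ``grads`` shaped exactly like
    ``params`` so optimizer updates can zip over the flat lists.
    """
    probs = cache["probs"]
    loss = -float(np.log(max(probs[label], 1e-300)))

    g_conv_W = [np.zeros_like(w) for w in params.conv_W]
    g_conv_b = [np.zeros_like(b) for b in params.conv_b]
    g_fc_W = [np.zeros_like(w) for w in params.fc_W]
    g_fc_b = [np.zeros_like(b) for b in params.fc_b]

    dz = probs.copy()
    dz[label] -= 1.0  # softmax + CE gradient

    n_fc = len(params.fc_W)
    for i in range(n_fc - 1, -1, -1):
        h_in = cache["fc_in"][i]
        g_fc_W[i] = np.outer(h_in, dz)
        g_fc_b[i] = dz
        dh = params.fc_W[i] @ dz
        if i > 0:
            if cache["dropout_mask"] is not None:
                dh = dh * cache["dropout_mask"]
            dz = dh * _activate_grad(cache["fc_z"][i - 1], config.activation)
    d_pooled = dh  # gradient w.r.t. the pooled graph vector

    H_last = cache["H_last"]
    m = cache["n_nodes"]
    if config.pooling == "mean":
        dH = np.tile(d_pooled / m, (m, 1))
    elif config.pooling == "sum":
        dH = np.tile(d_pooled, (m, 1))
    else:  # max: route each channel's gradient to its argmax node
        dH = np.zeros_like(H_last)
        dH[cache["argmax"], np.arange(H_last.shape[1])] = d_pooled

    n_adj = cache["n_adj"]
    for l in range(len(params.conv_W) - 1, -1, -1):
        dZ = dH * _activate_grad(cache["conv_z"][l], config.activation)
        prop = n_adj @ cache["conv_in"][l]  # n_adj is symmetric
        g_conv_W[l] = prop.T @ dZ
        g_conv_b[l] = dZ.sum(axis=0)
        if l > 0:
            dH = n_adj @ (dZ @ params.conv_W[l].T)

    grads = ModelParams(conv_W=g_conv_W, conv_b=g_conv_b, fc_W=g_fc_W, fc_b=g_fc_b)
    return loss, grads


def save_checkpoint(path, params: ModelParams, config: ModelConfig) -> None:
    """Single-file archive: config JSON + every weight array + init seed."""
    arrays = {}
    for i, (w, b) in enumerate(zip(params.conv_W, params.conv_b)):
        arrays[f"conv_W{i}"] = w
        arrays[f"conv_b{i}"] = b
    for i, (w, b) in enumerate(zip(params.fc_W, params.fc_b)):
        arrays[f"fc_W{i}"] = w
        arrays[f"fc_b{i}"] = b
    cfg = {
        "conv_dims": [list(d) for d in config.conv_dims],
        "fc_dims": list(config.fc_dims),
        "dropout": config.dropout,
        "activation": config.activation,
        "pooling": config.pooling,
        "classification_threshold": config.classification_threshold,
        "use_bias": config.use_bias,
        "seed": params.seed,
    }
    np.savez(path, __config__=np.array(json.dumps(cfg)), **arrays)


def load_checkpoint(path) -> Tuple[ModelParams, ModelConfig]:
    with np.load(path) as data:
        cfg = json.loads(str(data["__config__"]))
        config = ModelConfig(
            conv_dims=tuple(tuple(d) for d in cfg["conv_dims"]),
            fc_dims=tuple(cfg["fc_dims"]),
            dropout=cfg["dropout"],
            activation=cfg["activation"],
            pooling=cfg["pooling"],
            classification_threshold=cfg["classification_threshold"],
            use_bias=cfg["use_bias"],
        )
        n_conv = len(config.conv_dims)
        n_fc = len(config.fc_dims) - 1
        params = ModelParams(
            conv_W=[data[f"conv_W{i}"] for i in range(n_conv)],
            conv_b=[data[f"conv_b{i}"] for i in range(n_conv)],
            fc_W=[data[f"fc_W{i}"] for i in range(n_fc)],
            fc_b=[data[f"fc_b{i}"] for i in range(n_fc)],
            seed=cfg["seed"],
        )
    return params, config
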