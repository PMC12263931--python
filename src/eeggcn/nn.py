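"""Numpy implementation of the dual-graph multi-band GCN.

Architecture, per frequency band b (J bands in a fixed order):

    H1_b = ReLU(A1_b  X_b  W0_b)     # functional graph propagation, M -> K
    H2_b = ReLU(A2    H1_b W1_b)     # structural graph propagation, K -> L

the J band outputs are flattened to N*L each and concatenated (band-major) to
a N*L*J vector, which feeds a three-layer perceptron N*L*J -> S -> F -> Z with
ReLU hidden activations and a softmax head trained with cross-entropy.

The network is small (tens of thousands of parameters), so a hand-written
forward/backward with Adam is both fast and exactly reproducible: given a seed
the whole training trajectory is deterministic, with no threading or GPU
nondeterminism to document away.

GCN layers carry no bias by default (propagation is a pure re-weighted
aggregation); fully connected layers carry biases. Weights are Glorot-uniform
initialised from a seeded Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_params",
    "forward",
    "loss_and_grads",
    "gcn_layer",
    "count_parameters",
    "AdamState",
]


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gcn_layer(x: np.ndarray, a_norm: np.ndarray, w: np.ndarray,
              activation=relu) -> np.ndarray:
    """One graph-convolution layer: activation(A_norm @ X @ W).

    Reference (single-graph) form used by the oracles and by small examples;
    the batched training path uses the einsum equivalents in :func:`forward`.
    """
    x, a_norm, w = (np.asarray(v, dtype=float) for v in (x, a_norm, w))
    if a_norm.shape[0] != a_norm.shape[1] or a_norm.shape[1] != x.shape[0]:
        raise ValueError("adjacency/feature shape mismatch")
    if x.shape[1] != w.shape[0]:
        raise ValueError("feature/weight shape mismatch")
    return activation(a_norm @ x @ w)


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(arch, rng: np.random.Generator) -> dict:
    """Initialise all learnable arrays for an :class:`ArchitectureConfig`."""
    j_w = 1 if arch.weight_sharing == "shared" else arch.n_bands
    p = {
        "W0": _glorot(rng, (j_w, arch.m_features, arch.gcn_hidden)),
        "W1": _glorot(rng, (j_w, arch.gcn_hidden, arch.gcn_out)),
        "U1": _glorot(rng, (arch.flatten_size, arch.fc_hidden)),
        "b1": np.zeros(arch.fc_hidden),
        "U2": _glorot(rng, (arch.fc_hidden, arch.fc_hidden2)),
        "b2": np.zeros(arch.fc_hidden2),
        "U3": _glorot(rng, (arch.fc_hidden2, arch.n_classes)),
        "b3": np.zeros(arch.n_classes),
    }
    if arch.gcn_bias:
        p["B0"] = np.zeros((j_w, arch.gcn_hidden))
        p["B1"] = np.zeros((j_w, arch.gcn_out))
    return p


def count_parameters(params: dict) -> int:
    """Total scalar parameter count."""
    return int(sum(v.size for v in params.values()))


def _band_weights(w: np.ndarray, n_bands: int) -> np.ndarray:
    """Broadcast shared weights (1, ., .) to per-band view (J, ., .)."""
    return np.broadcast_to(w, (n_bands,) + w.shape[1:])


def forward(params: dict, x: np.ndarray, a1: np.ndarray, a2: np.ndarray,
            return_cache: bool = False):
    """Batched forward pass.

    Parameters
    ----------
    x : (B, J, N, M) normalised node features.
    a1 : (B, J, N, N) normalised functional adjacencies.
    a2 : (N, N) normalised structural adjacency.

    Returns
    -------
    logits (B, Z) and probabilities (B, Z); with ``return_cache`` also the
    intermediate activations needed for backprop.
    """
    b, j = x.shape[0], x.shape[1]
    w0 = _band_weights(params["W0"], j)
    w1 = _band_weights(params["W1"], j)

    s1 = np.matmul(a1, x)                                # (B,J,N,M)
    z1 = np.einsum("bjnm,jmk->bjnk", s1, w0)
    if "B0" in params:
        z1 = z1 + _band_weights(params["B0"], j)[None, :, None, :]
    h1 = relu(z1)
    s2 = np.matmul(a2, h1)                               # (B,J,N,K)
    z2 = np.einsum("bjnk,jkl->bjnl", s2, w1)
    if "B1" in params:
        z2 = z2 + _band_weights(params["B1"], j)[None, :, None, :]
    h2 = relu(z2)
    flat = h2.reshape(b, -1)                             # band-major N*L blocks

    zf1 = flat @ params["U1"] + params["b1"]
    hf1 = relu(zf1)
    zf2 = hf1 @ params["U2"] + params["b2"]
    hf2 = relu(zf2)
    logits = hf2 @ params["U3"] + params["b3"]
    probs = softmax(logits)
    if not return_cache:
        return logits, probs
    cache = dict(s1=s1, z1=z1, h1=h1, s2=s2, z2=z2, h2=h2, flat=flat,
                 zf1=zf1, hf1=hf1, zf2=zf2, hf2=hf2, probs=probs, j=j)
    return logits, probs, cache


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def loss_and_grads(params: dict, x: np.ndarray, a1: np.ndarray, a2: np.ndarray,
                   y: np.ndarray) -> tuple[float, dict]:
    """Cross-entropy loss and gradients for one minibatch."""
    _, probs, c = forward(params, x, a1, a2, return_cache=True)
    b = x.shape[0]
    j = c["j"]
    loss = cross_entropy(probs, y)

    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits /= b

    grads = {
        "U3": c["hf2"].T @ dlogits,
        "b3": dlogits.sum(axis=0),
    }
    dhf2 = dlogits @ params["U3"].T
    dzf2 = dhf2 * (c["zf2"] > 0)
    grads["U2"] = c["hf1"].T @ dzf2
    grads["b2"] = dzf2.sum(axis=0)
    dhf1 = dzf2 @ params["U2"].T
    dzf1 = dhf1 * (c["zf1"] > 0)
    grads["U1"] = c["flat"].T @ dzf1
    grads["b1"] = dzf1.sum(axis=0)

    dflat = dzf1 @ params["U1"].T
    dh2 = dflat.reshape(c["h2"].shape)
    dz2 = dh2 * (c["z2"] > 0)
    w1 = _band_weights(params["W1"], j)
    gw1 = np.einsum("bjnk,bjnl->jkl", c["s2"], dz2)
    ds2 = np.einsum("bjnl,jkl->bjnk", dz2, w1)
    dh1 = np.matmul(a2.T, ds2)
    dz1 = dh1 * (c["z1"] > 0)
    gw0 = np.einsum("bjnm,bjnk->jmk", c["s1"], dz1)

    if params["W0"].shape[0] == 1:  # shared weights: sum band gradients
        gw0 = gw0.sum(axis=0, keepdims=True)
        gw1 = gw1.sum(axis=0, keepdims=True)
    grads["W0"] = gw0
    grads["W1"] = gw1
    if "B0" in params:
        gb0 = dz1.sum(axis=(0, 2))
        gb1 = dz2.sum(axis=(0, 2))
        if params["B0"].shape[0] == 1:
            gb0 = gb0.sum(axis=0, keepdims=True)
            gb1 = gb1.sum(axis=0, keepdims=True)
        grads["B0"] = gb0
        grads["B1"] = gb1
    return loss, grads


class AdamState:
    """Adam optimiser with default moment decay (0.9, 0.999)."""

    def __init__(self, params: dict, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )
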