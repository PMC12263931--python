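"""Brute-force oracles shared by the model tests: per-node loops, no matmul
shortcuts, kept deliberately independent of the library's vectorised path."""

import numpy as np


def loop_gcn(x, a, w):
    """Per-node aggregation: sum over neighbours, then weights, then ReLU."""
    n = x.shape[0]
    agg = np.zeros_like(x)
    for i in range(n):
        for j in range(n):
            agg[i] += a[i, j] * x[j]
    return np.maximum(agg @ w, 0.0)


def loop_forward(params, x, a1, a2):
    """Two GCN layers per band, flatten+concat, three FC layers; one instance.

    x: (J, N, M); a1: (J, N, N); a2: (N, N). Returns the logits.
    """
    flats = []
    for j in range(x.shape[0]):
        h1 = loop_gcn(x[j], a1[j], params["W0"][j])
        h2 = loop_gcn(h1, a2, params["W1"][j])
        flats.append(h2.reshape(-1))
    flat = np.concatenate(flats)
    hf1 = np.maximum(flat @ params["U1"] + params["b1"], 0.0)
    hf2 = np.maximum(hf1 @ params["U2"] + params["b2"], 0.0)
    return hf2 @ params["U3"] + params["b3"]


def random_instance(arch, batch, rng):
    """Random normalised-feature/adjacency batch for a small architecture."""
    from eeggcn.connectivity import normalize_adjacency

    x = rng.standard_normal((batch, arch.n_bands, arch.n_nodes, arch.m_features))
    a1 = np.empty((batch, arch.n_bands, arch.n_nodes, arch.n_nodes))
    for b in range(batch):
        for j in range(arch.n_bands):
            m = np.abs(rng.standard_normal((arch.n_nodes, arch.n_nodes)))
            a1[b, j] = normalize_adjacency((m + m.T) / 2)
    m = np.abs(rng.standard_normal((arch.n_nodes, arch.n_nodes)))
    a2 = normalize_adjacency((m + m.T) / 2)
    return x, a1, a2
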