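"""Functional and structural electrode graphs and their GCN normalisation.

Two complementary adjacency matrices drive the two GCN layers:

* **Functional** — per segment and per band, the absolute Pearson correlation
  between the DE feature vectors of every channel pair. The absolute value is
  taken because symmetric degree normalisation requires non-negative edge
  weights; |rho| preserves coupling magnitude while discarding sign, the usual
  convention in EEG functional-connectivity graph learning.
* **Structural** — the binary same-anatomical-region relation of the montage
  (see :mod:`eeggcn.montage`); one constant matrix shared by all segments.

Normalisation is the standard renormalisation trick: with self-loops added,
A_hat = A + I and D_hat its degree matrix,

    A_norm = D_hat^{-1/2} A_hat D_hat^{-1/2},

whose spectral radius is at most 1, keeping repeated propagation stable.
"""

from __future__ import annotations

import numpy as np

from .features import DEFeatureTensor

__all__ = [
    "functional_adjacency",
    "functional_adjacency_tensor",
    "normalize_adjacency",
]

#: Below this feature-vector standard deviation a node's correlations are
#: numerically undefined.
_STD_TOL = 1e-12


def functional_adjacency(band_features: np.ndarray, channel_names=None) -> np.ndarray:
    """|Pearson| adjacency of one band's N x M node-feature matrix.

    Entry (m, n) is the absolute Pearson correlation between the M-dimensional
    feature vectors of channels m and n; the diagonal is exactly 1. Invariant
    to any affine rescaling of a node's feature vector.

    Raises
    ------
    ValueError
        If M < 2 or a node's feature vector is constant (its correlation with
        anything is undefined); the error names the channel.
    """
    x = np.asarray(band_features, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need an N x M feature matrix with M >= 2")
    stds = x.std(axis=1)
    if np.any(stds < _STD_TOL):
        idx = int(np.argmin(stds))
        name = channel_names[idx] if channel_names is not None else f"#{idx}"
        raise ValueError(f"constant feature vector for channel {name}")
    rho = np.corrcoef(x)
    a = np.abs(rho)
    a = (a + a.T) / 2.0  # BLAS products are not bitwise symmetric
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def functional_adjacency_tensor(feat: DEFeatureTensor) -> np.ndarray:
    """Per-band functional adjacencies of one segment: (J, N, N)."""
    n_bands = feat.values.shape[2]
    return np.stack(
        [
            functional_adjacency(feat.values[:, :, j], feat.channel_names)
            for j in range(n_bands)
        ]
    )


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Symmetric degree normalisation with self-loops.

    Returns D_hat^{-1/2} (A + I) D_hat^{-1/2}. The self-loop also floors
    isolated-node degrees at 1, so the inverse square root is always defined.

    Raises
    ------
    ValueError
        If A is not square, not symmetric, or has negative entries (signed
        weights must be transformed, e.g. by absolute value, first).
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency entries must be non-negative")
    a_hat = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    return d_inv_sqrt[:, None] * a_hat * d_inv_sqrt[None, :]
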