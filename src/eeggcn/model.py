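"""Model/Results interface for the dual-graph multi-band GCN classifier.

Usage follows the fit-then-results convention of statistical modelling
packages::

    model = EEGGraphClassifier(train_ds, test_ds)
    res = model.fit(TrainConfig(epochs=200, seed=0))
    print(res.summary())
    report = res.evaluate(test_ds)

The model owns the data and the architecture; ``fit`` z-scores the features
with statistics estimated on the training rows only, runs minibatch Adam on
the cross-entropy, and returns an :class:`EEGGraphResults` holding the trained
parameters, the per-epoch loss curves and evaluation helpers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .dataset import SegmentDataset
from .features import NormalizationStats

__all__ = ["ArchitectureConfig", "TrainConfig", "EEGGraphClassifier", "EEGGraphResults"]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Network dimensions.

    Defaults: N=19 electrodes, M=32 DE features per node, K=16 GCN hidden
    units, L=2 GCN output units, J=5 bands, FC hidden sizes S=128 and F=32,
    Z=2 classes. The flatten size is N*L*J. GCN weights are per-band by
    default and carry no bias; FC layers carry biases.
    """

    n_nodes: int = 19
    m_features: int = 32
    gcn_hidden: int = 16
    gcn_out: int = 2
    n_bands: int = 5
    fc_hidden: int = 128
    fc_hidden2: int = 32
    n_classes: int = 2
    weight_sharing: str = "per_band"
    gcn_bias: bool = False

    def __post_init__(self) -> None:
        dims = (self.n_nodes, self.m_features, self.gcn_hidden, self.gcn_out,
                self.n_bands, self.fc_hidden, self.fc_hidden2, self.n_classes)
        if any(d < 1 for d in dims):
            raise ValueError("all architecture dimensions must be >= 1")
        if self.weight_sharing not in ("per_band", "shared"):
            raise ValueError("weight_sharing must be 'per_band' or 'shared'")

    @property
    def flatten_size(self) -> int:
        return self.n_nodes * self.gcn_out * self.n_bands

    @classmethod
    def from_dataset(cls, ds: SegmentDataset, **overrides) -> "ArchitectureConfig":
        kwargs = dict(
            n_nodes=len(ds.channel_names),
            m_features=ds.x.shape[3],
            n_bands=len(ds.band_names),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: Adam on softmax cross-entropy."""

    learning_rate: float = 1e-3
    batch_size: int = 10
    epochs: int = 200
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


class EEGGraphClassifier:
    """Dual-connectivity multi-band GCN built from a segment dataset.

    Parameters
    ----------
    train_data : SegmentDataset
        Training rows; normalisation statistics are fitted on these only.
    test_data : SegmentDataset, optional
        Held-out rows used for the per-epoch test loss curve.
    arch : ArchitectureConfig, optional
        Defaults are inferred from the training dataset.
    """

    def __init__(self, train_data: SegmentDataset, test_data: SegmentDataset | None = None,
                 arch: ArchitectureConfig | None = None):
        if train_data.n_segments == 0:
            raise ValueError("empty training split")
        if len(np.unique(train_data.y)) < 2:
            raise ValueError("training split contains a single class")
        if not train_data.adjacency_normalized:
            raise ValueError("dataset adjacencies are not normalised")
        self.train_data = train_data
        self.test_data = test_data
        self.arch = arch or ArchitectureConfig.from_dataset(train_data)
        if self.arch.n_nodes != len(train_data.channel_names):
            raise ValueError("architecture n_nodes does not match the dataset")
        if self.arch.n_bands != len(train_data.band_names):
            raise ValueError("architecture n_bands does not match the dataset")

    # -- normalisation ----------------------------------------------------
    def _fit_norm(self) -> NormalizationStats:
        x = self.train_data.x  # (n, J, N, M)
        mean = x.mean(axis=0)
        std = np.maximum(x.std(axis=0), NormalizationStats.STD_FLOOR)
        return NormalizationStats(mean=mean, std=std,
                                  band_names=self.train_data.band_names)

    def fit(self, train_config: TrainConfig | None = None) -> "EEGGraphResults":
        tc = train_config or TrainConfig()
        norm = self._fit_norm()
        xtr = (self.train_data.x - norm.mean) / norm.std
        ytr = self.train_data.y
        a1tr, a2 = self.train_data.a1, self.train_data.a2

        rng = np.random.default_rng(tc.seed)
        params = nn.init_params(self.arch, rng)
        opt = nn.AdamState(params, tc.learning_rate)

        has_test = self.test_data is not None and self.test_data.n_segments > 0
        if has_test:
            xte = (self.test_data.x - norm.mean) / norm.std
            yte, a1te = self.test_data.y, self.test_data.a1

        n = xtr.shape[0]
        train_losses, test_losses = [], []
        for _epoch in range(tc.epochs):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for s0 in range(0, n, tc.batch_size):
                idx = order[s0 : s0 + tc.batch_size]
                loss, grads = nn.loss_and_grads(
                    params, xtr[idx], a1tr[idx], a2, ytr[idx]
                )
                opt.step(params, grads)
                epoch_loss += loss * len(idx)
                seen += len(idx)
            train_losses.append(epoch_loss / seen)
            if has_test:
                _, probs = nn.forward(params, xte, a1te, a2)
                test_losses.append(nn.cross_entropy(probs, yte))

        curves = pd.DataFrame({"epoch": np.arange(1, tc.epochs + 1),
                               "train_loss": train_losses})
        if has_test:
            curves["test_loss"] = test_losses
        return EEGGraphResults(model=self, params=params, norm=norm,
                               train_config=tc, loss_curves=curves)


@dataclass
class EEGGraphResults:
    """Trained parameters plus diagnostics for one fit."""

    model: EEGGraphClassifier
    params: dict = field(repr=False)
    norm: NormalizationStats = field(repr=False)
    train_config: TrainConfig = None
    loss_curves: pd.DataFrame = field(default=None, repr=False)

    # -- prediction -------------------------------------------------------
    def _check(self, ds: SegmentDataset) -> None:
        if ds.band_names != self.model.train_data.band_names:
            raise ValueError("band order mismatch with the fitted model")
        if ds.channel_names != self.model.train_data.channel_names:
            raise ValueError("channel set mismatch with the fitted model")
        if not ds.adjacency_normalized:
            raise ValueError("dataset adjacencies are not normalised")

    def predict_proba(self, ds: SegmentDataset) -> np.ndarray:
        """Class probabilities, shape (n, Z); column 1 is the AD probability."""
        self._check(ds)
        x = (ds.x - self.norm.mean) / self.norm.std
        _, probs = nn.forward(self.params, x, ds.a1, ds.a2)
        return probs

    def predict(self, ds: SegmentDataset, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(ds)[:, 1] >= threshold).astype(int)

    def evaluate(self, ds: SegmentDataset, threshold: float = 0.5):
        """Full metric suite on a dataset (accuracy/precision/recall/F1/AUC)."""
        from .evaluation import compute_metrics

        probs = self.predict_proba(ds)[:, 1]
        return compute_metrics(ds.y, probs, threshold=threshold,
                               provenance=f"n={ds.n_segments} segments, "
                                          f"{len(ds.subjects)} subjects")

    @property
    def n_parameters(self) -> int:
        return nn.count_parameters(self.params)

    def plot_loss(self, ax=None):
        """Training/test loss curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_curves["epoch"], self.loss_curves["train_loss"],
                label="train")
        if "test_loss" in self.loss_curves:
            ax.plot(self.loss_curves["epoch"], self.loss_curves["test_loss"],
                    label="test")
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary."""
        a, tc = self.model.arch, self.train_config
        buf = io.StringIO()
        w = buf.write
        w("Dual-connectivity multi-band GCN classifier\n")
        w("=" * 46 + "\n")
        w(f"bands (J)            : {len(self.model.train_data.band_names)} "
          f"{list(self.model.train_data.band_names)}\n")
        w(f"nodes (N)            : {a.n_nodes}\n")
        w(f"node features (M)    : {a.m_features}\n")
        w(f"GCN units (K -> L)   : {a.gcn_hidden} -> {a.gcn_out}\n")
        w(f"FC sizes (S, F, Z)   : {a.fc_hidden}, {a.fc_hidden2}, {a.n_classes}\n")
        w(f"weight sharing       : {a.weight_sharing}, gcn_bias={a.gcn_bias}\n")
        w(f"parameters           : {self.n_parameters:,}\n")
        w(f"training             : {tc.epochs} epochs, batch {tc.batch_size}, "
          f"lr {tc.learning_rate}, {tc.optimizer}, seed {tc.seed}\n")
        w(f"train segments       : {self.model.train_data.n_segments} "
          f"({len(self.model.train_data.subjects)} subjects)\n")
        w(f"final train loss     : {self.loss_curves['train_loss'].iloc[-1]:.4f}\n")
        if "test_loss" in self.loss_curves:
            w(f"final test loss      : {self.loss_curves['test_loss'].iloc[-1]:.4f}\n")
        return buf.getvalue()
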