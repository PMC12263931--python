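"""Segment-level dataset: DE feature tensors plus their dual adjacencies.

One ``SegmentDataset`` row is one augmented window of one subject. It carries

* ``x`` — raw (unnormalised) DE features, shape (n, J, N, M);
* ``a1`` — per-band normalised functional adjacency, shape (n, J, N, N),
  computed from the raw DE features of that segment (no fitted statistics, so
  no train/test leakage);
* ``a2`` — the one normalised structural adjacency shared by all rows, (N, N);
* ``y`` — integer labels with AD = 1 (the positive class);
* ``subject_ids`` — for participant-level splitting: all windows of a subject
  must land on the same side of any split.

Feature normalisation is *not* baked in here; the model z-scores ``x`` with
statistics fitted on its training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import functional_adjacency_tensor, normalize_adjacency
from .features import node_features
from .montage import structural_adjacency
from .preprocessing import (
    DEFAULT_BANDS,
    bandpass_decompose,
    segment_windows,
    select_fixed_duration,
)

__all__ = ["SegmentDataset", "build_dataset"]

LABEL_TO_INT = {"HC": 0, "AD": 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass
class SegmentDataset:
    x: np.ndarray = field(repr=False)          # (n, J, N, M) raw DE features
    a1: np.ndarray = field(repr=False)         # (n, J, N, N) normalised functional
    a2: np.ndarray = field(repr=False)         # (N, N) normalised structural
    y: np.ndarray = field(repr=False)          # (n,) int, AD = 1
    subject_ids: np.ndarray = field(repr=False)
    band_names: tuple = ()
    channel_names: tuple = ()
    adjacency_normalized: bool = True          # provenance guard for the model

    def __post_init__(self) -> None:
        n = self.x.shape[0]
        if not (self.a1.shape[0] == self.y.shape[0] == len(self.subject_ids) == n):
            raise ValueError("inconsistent row counts across dataset arrays")
        if self.x.shape[1] != len(self.band_names):
            raise ValueError("band axis does not match band_names")
        if self.x.shape[2] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")

    # -- basic shape info -------------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.x.shape[0]

    def __len__(self) -> int:
        return self.n_segments

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids, in first-appearance order."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    def subject_labels(self) -> dict:
        """Mapping subject_id -> string label."""
        out = {}
        for sid, yi in zip(self.subject_ids, self.y):
            out.setdefault(sid, INT_TO_LABEL[int(yi)])
        return out

    # -- views ------------------------------------------------------------
    def select(self, index) -> "SegmentDataset":
        """Row subset (windows), e.g. one side of a subject-level split."""
        index = np.asarray(index)
        return replace(
            self,
            x=self.x[index],
            a1=self.a1[index],
            y=self.y[index],
            subject_ids=self.subject_ids[index],
        )

    def select_subjects(self, subject_ids) -> "SegmentDataset":
        mask = np.isin(self.subject_ids, list(subject_ids))
        return self.select(np.flatnonzero(mask))

    def subset_bands(self, names) -> "SegmentDataset":
        """Keep only the named bands (order taken from the current dataset)."""
        names = list(names)
        unknown = set(names) - set(self.band_names)
        if unknown:
            raise ValueError(f"unknown band name(s): {sorted(unknown)}")
        idx = [i for i, b in enumerate(self.band_names) if b in names]
        return replace(
            self,
            x=self.x[:, idx],
            a1=self.a1[:, idx],
            band_names=tuple(self.band_names[i] for i in idx),
        )

    def drop_channel(self, channel: str) -> "SegmentDataset":
        """Remove one electrode from features and both adjacencies (N -> N-1).

        The reduced structural adjacency is re-normalised from the montage so
        degrees reflect the smaller graph. The functional adjacencies are
        re-normalised from their unnormalised counterparts implicitly: we
        cannot recover them from the normalised form, so ablation datasets are
        rebuilt from the stored raw features instead.
        """
        if channel not in self.channel_names:
            raise ValueError(f"channel {channel!r} not in montage")
        keep = [i for i, ch in enumerate(self.channel_names) if ch != channel]
        names = tuple(self.channel_names[i] for i in keep)
        x = self.x[:, :, keep, :]
        # rebuild functional adjacencies on the reduced feature set
        n, j = x.shape[0], x.shape[1]
        a1 = np.empty((n, j, len(keep), len(keep)))
        for s in range(n):
            for b in range(j):
                a1[s, b] = normalize_adjacency(
                    _abs_corr(x[s, b], names)
                )
        a2 = normalize_adjacency(structural_adjacency(names))
        return replace(self, x=x, a1=a1, a2=a2, channel_names=names)


def _abs_corr(feat: np.ndarray, channel_names) -> np.ndarray:
    from .connectivity import functional_adjacency

    return functional_adjacency(feat, channel_names)


def build_dataset(
    recordings,
    bands=DEFAULT_BANDS,
    analysis_duration: float | None = None,
    window_length: float = 10.0,
    overlap: float = 0.9,
    mode: str = "tenfold",
    m_features: int = 32,
    sub_length: float = 1.0,
) -> SegmentDataset:
    """Run the full feature pipeline over an iterable of recordings.

    Per subject: optional fixed-duration selection, band decomposition,
    sliding-window segmentation, DE feature extraction, per-segment functional
    adjacency, and symmetric normalisation of every graph. Accepts a generator
    so long cohorts never need to be held in memory as raw signal.
    """
    xs, a1s, ys, sids = [], [], [], []
    band_names = channel_names = None
    for rec in recordings:
        if analysis_duration is not None:
            rec = select_fixed_duration(rec, analysis_duration)
        bs = bandpass_decompose(rec, bands)
        segs = segment_windows(bs, window_length, overlap, mode)
        for seg in segs.segments:
            feat = node_features(
                seg, segs.channel_names, segs.sampling_rate, m_features, sub_length
            )
            a1 = functional_adjacency_tensor(feat)
            a1s.append(np.stack([normalize_adjacency(a1[j]) for j in range(a1.shape[0])]))
            xs.append(np.transpose(feat.values, (2, 0, 1)))  # (J, N, M)
            ys.append(LABEL_TO_INT[seg.label])
            sids.append(seg.subject_id)
            if band_names is None:
                band_names = feat.band_names
                channel_names = feat.channel_names
    if not xs:
        raise ValueError("no recordings supplied")
    a2 = normalize_adjacency(structural_adjacency(channel_names))
    return SegmentDataset(
        x=np.stack(xs),
        a1=np.stack(a1s),
        a2=a2,
        y=np.asarray(ys, dtype=int),
        subject_ids=np.asarray(sids, dtype=object),
        band_names=band_names,
        channel_names=channel_names,
    )
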