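"""Differential-entropy node features.

Differential entropy (DE) of a Gaussian signal with variance sigma^2 has the
closed form

    DE = 1/2 * log2(2 * pi * e * sigma^2)   [bits],

and band-limited EEG is well approximated as Gaussian, so the per-band DE of a
short window is estimated by plugging the unbiased sample variance into the
closed form. DE grows monotonically with signal power on a log scale, which
makes it a stable per-band complexity feature.

Each T-second segment is summarised, per channel and band, by M overlapping
sub-windows: sub-window m starts at m * (T - w) / (M - 1) for m = 0..M-1 and
has length w (defaults M = 32, w = 1 s). The resulting M-vector per channel is
both the GCN node feature vector and the input to the Pearson functional
connectivity (which needs >= 2 feature points per node).

Feature normalisation is a z-score per (channel, feature, band) coordinate,
fitted on the training split only so no test statistics leak into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import Segment, SegmentSet

__all__ = [
    "differential_entropy",
    "subwindow_grid",
    "node_features",
    "DEFeatureTensor",
    "NormalizationStats",
    "fit_normalization",
    "apply_normalization",
]

#: Sample variances below this are treated as degenerate (DE -> -inf).
VARIANCE_FLOOR = 1e-12

_HALF_LOG2_2PIE = 0.5 * np.log2(2.0 * np.pi * np.e)


def differential_entropy(window: np.ndarray, variance_floor: float = VARIANCE_FLOOR) -> float:
    """DE in bits of a 1-D window under the Gaussian closed form.

    Uses the unbiased (n-1) sample variance. Doubling the amplitude of the
    window adds exactly 1 bit.

    Raises
    ------
    ValueError
        If the window has fewer than 2 samples or is (near-)constant, where
        the differential entropy diverges to -inf.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    var = window.var(ddof=1)
    if var < variance_floor:
        raise ValueError(
            f"degenerate window: sample variance {var:.3e} below floor "
            f"{variance_floor:.1e}"
        )
    return float(_HALF_LOG2_2PIE + 0.5 * np.log2(var))


def subwindow_grid(
    window_samples: int, m: int, sub_samples: int
) -> list[tuple[int, int]]:
    """(start, length) sample pairs of M evenly spaced sub-windows.

    Starts are m * (window - sub) / (M - 1) rounded to the nearest sample; the
    first sub-window begins at 0 and the last ends at the window edge.
    """
    if m < 2:
        raise ValueError("need at least 2 sub-windows (M >= 2)")
    if sub_samples < 2:
        raise ValueError("sub-window must contain at least 2 samples")
    if sub_samples > window_samples:
        raise ValueError("sub-window longer than the segment window")
    span = window_samples - sub_samples
    return [(int(round(k * span / (m - 1))), sub_samples) for k in range(m)]


@dataclass
class DEFeatureTensor:
    """Per-segment node features: channels (N) x features (M) x bands (J).

    ``feature_grid`` records the (start, length) sample pairs of the M
    sub-windows so the mapping from signal to feature is reconstructible.
    """

    subject_id: str
    label: str
    channel_names: tuple
    band_names: tuple
    values: np.ndarray = field(repr=False)
    feature_grid: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be channels x features x bands")
        if self.values.shape[0] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.values.shape[2] != len(self.band_names):
            raise ValueError("band axis does not match band_names")
        if self.values.shape[1] < 2:
            raise ValueError("need M >= 2 features per node")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def node_features(
    seg: Segment,
    channel_names: tuple,
    sampling_rate: float,
    m: int = 32,
    sub_length: float = 1.0,
) -> DEFeatureTensor:
    """DE feature tensor of one segment.

    ``values[ch, k, band]`` is the DE of sub-window k of channel ch in that
    band. Degenerate windows raise with (channel, band, sub-window) context.
    """
    band_names = tuple(seg.bands.keys())
    window_samples = next(iter(seg.bands.values())).shape[1]
    sub_samples = int(round(sub_length * sampling_rate))
    grid = subwindow_grid(window_samples, m, sub_samples)

    n_ch = len(channel_names)
    values = np.empty((n_ch, m, len(band_names)))
    # vectorised over channels: one variance reduction per (band, sub-window)
    for j, bname in enumerate(band_names):
        arr = seg.bands[bname]
        for k, (s0, ln) in enumerate(grid):
            var = arr[:, s0 : s0 + ln].var(axis=1, ddof=1)
            if np.any(var < VARIANCE_FLOOR):
                c = int(np.argmin(var))
                raise ValueError(
                    f"channel {channel_names[c]}, band {bname}, sub-window {k}: "
                    f"degenerate window (variance {var[c]:.3e})"
                )
            values[:, k, j] = _HALF_LOG2_2PIE + 0.5 * np.log2(var)
    return DEFeatureTensor(
        subject_id=seg.subject_id,
        label=seg.label,
        channel_names=tuple(channel_names),
        band_names=band_names,
        values=values,
        feature_grid=tuple(grid),
    )


def segment_set_features(
    segs: SegmentSet, m: int = 32, sub_length: float = 1.0
) -> list[DEFeatureTensor]:
    """DE tensors for every window of one subject."""
    return [
        node_features(seg, segs.channel_names, segs.sampling_rate, m, sub_length)
        for seg in segs.segments
    ]


@dataclass
class NormalizationStats:
    """Per-(channel, feature, band) z-score statistics, fitted on training data.

    Standard deviations are floored so constant coordinates map to zero rather
    than dividing by zero.
    """

    mean: np.ndarray
    std: np.ndarray
    band_names: tuple

    STD_FLOOR = 1e-8


def fit_normalization(train_features: list[DEFeatureTensor]) -> NormalizationStats:
    """Estimate z-score statistics from training-split tensors only."""
    if not train_features:
        raise ValueError("cannot fit normalization on an empty training list")
    band_names = train_features[0].band_names
    for t in train_features:
        if t.band_names != band_names:
            raise ValueError("inconsistent band order across training tensors")
    stack = np.stack([t.values for t in train_features])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    std = np.maximum(std, NormalizationStats.STD_FLOOR)
    return NormalizationStats(mean=mean, std=std, band_names=band_names)


def apply_normalization(
    stats: NormalizationStats, feat: DEFeatureTensor
) -> DEFeatureTensor:
    """Apply fitted z-score statistics to one tensor."""
    if feat.band_names != stats.band_names:
        raise ValueError("band order mismatch between stats and features")
    values = (feat.values - stats.mean) / stats.std
    return DEFeatureTensor(
        subject_id=feat.subject_id,
        label=feat.label,
        channel_names=feat.channel_names,
        band_names=feat.band_names,
        values=values,
        feature_grid=feat.feature_grid,
    )
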