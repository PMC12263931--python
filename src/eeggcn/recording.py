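"""Raw multi-channel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CHANNELS_1020, region_of

#: Class labels: AD (Alzheimer's disease) is the positive class everywhere.
LABELS = ("HC", "AD")


@dataclass
class RawRecording:
    """One subject's multi-channel EEG time series.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    label : str
        ``"AD"`` or ``"HC"``.
    channel_names : tuple of str
        Ordered montage labels; must all belong to the 19-channel 10-20 set.
    sampling_rate : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    label: str
    channel_names: tuple
    sampling_rate: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.data = np.asarray(self.data, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        for ch in self.channel_names:
            region_of(ch)  # raises on unknown channels
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite samples in recording {self.subject_id!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate
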