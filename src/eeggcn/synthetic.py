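"""Synthetic EEG cohorts with class-dependent band power and connectivity.

The generator emulates the two statistical contrasts that separate Alzheimer's
disease (AD) patients from healthy controls (HC) in resting-state EEG:

* **Band-power shift** — AD shows elevated slow-wave (delta/theta) power and
  suppressed alpha power. Each subject's signal is a sum over the five bands of
  bandpass-filtered white Gaussian noise, with the per-band variance set by a
  class profile (plus a per-subject log-normal jitter standing in for
  inter-subject variability).
* **Connectivity weakening** — AD shows weaker inter-regional coupling. Each
  band component of channel c is a mixture sqrt(w)*shared + sqrt(1-w)*private
  of a cohort of unit-variance sources, so the inter-channel correlation of the
  raw signal equals the mixing weight w (``connectivity_strength``), which is
  lower for AD.

Both knobs are analytically controllable, which is what makes the generator a
usable oracle: the expected differential entropy of band b is
0.5*log2(2*pi*e*sigma_b^2) with sigma_b^2 the configured band variance.

Everything is a pure function of (spec, label, subject_index): per-subject
random streams are derived from the root seed with ``numpy.random.SeedSequence``
spawn keys, so cohorts are reproducible under any generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CHANNELS_1020
from .preprocessing import DEFAULT_BANDS, BAND_NAMES, bandpass_filter
from .recording import LABELS, RawRecording

__all__ = [
    "CohortSpec",
    "DEFAULT_AD_PROFILE",
    "DEFAULT_HC_PROFILE",
    "DEFAULT_CONNECTIVITY",
    "generate_subject",
    "generate_cohort",
]

#: Per-band variance multipliers for AD: elevated delta/theta, suppressed
#: alpha, mildly suppressed beta/gamma — the classical "slowing" pattern.
DEFAULT_AD_PROFILE: dict = {
    "delta": 1.5, "theta": 1.5, "alpha": 0.45, "beta": 0.85, "gamma": 0.85,
}
#: HC is the reference class.
DEFAULT_HC_PROFILE: dict = {name: 1.0 for name in BAND_NAMES}

#: Shared-source mixing weight per class; HC couples more strongly than AD.
DEFAULT_CONNECTIVITY: dict = {"HC": 0.60, "AD": 0.35}

#: Baseline per-band signal variance in microvolts squared (10 uV rms/band).
BASE_BAND_VARIANCE = 100.0

_LABEL_CODE = {"HC": 0, "AD": 1}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_ad, n_hc : int
        Subjects per class (defaults 36 / 29).
    n_channels : int
        Montage size; channels are the first ``n_channels`` of the 10-20 set.
    sampling_rate : float
        Hz. Default 500.
    duration : float
        Seconds per recording. Default 300 (a 5-min resting segment).
    band_variance_profile : dict
        label -> {band name -> positive variance multiplier}.
    connectivity_strength : dict
        label -> shared-source mixing weight in [0, 1].
    subject_variability : float
        Standard deviation, in log2 units, of the per-subject per-band
        variance jitter. 0 disables inter-subject heterogeneity.
    channel_variance_profile : dict or None
        Optional label -> {channel -> {band -> multiplier}} for planting
        channel-localised class effects (used by ablation studies).
    seed : int
        Root seed; the whole cohort is a pure function of this spec.
    """

    n_ad: int = 36
    n_hc: int = 29
    n_channels: int = 19
    sampling_rate: float = 500.0
    duration: float = 300.0
    band_variance_profile: dict = field(
        default_factory=lambda: {
            "AD": dict(DEFAULT_AD_PROFILE),
            "HC": dict(DEFAULT_HC_PROFILE),
        }
    )
    connectivity_strength: dict = field(
        default_factory=lambda: dict(DEFAULT_CONNECTIVITY)
    )
    subject_variability: float = 0.35
    channel_variance_profile: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 1 or self.n_hc < 1:
            raise ValueError("need at least one subject per class")
        if not 1 <= self.n_channels <= len(CHANNELS_1020):
            raise ValueError(f"n_channels must be in [1, {len(CHANNELS_1020)}]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer")
        for label in LABELS:
            prof = self.band_variance_profile[label]
            for name in BAND_NAMES:
                if prof[name] <= 0:
                    raise ValueError(f"variance multiplier {label}/{name} must be > 0")
            w = self.connectivity_strength[label]
            if not 0 <= w <= 1:
                raise ValueError("connectivity_strength must lie in [0, 1]")
        if self.subject_variability < 0:
            raise ValueError("subject_variability must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def channel_names(self) -> tuple:
        return CHANNELS_1020[: self.n_channels]


def _subject_rng(spec: CohortSpec, label: str, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(_LABEL_CODE[label], subject_index)
    )
    return np.random.default_rng(ss)


def generate_subject(
    spec: CohortSpec, label: str, subject_index: int
) -> RawRecording:
    """Generate one subject's recording; deterministic in (seed, label, index)."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = _subject_rng(spec, label, subject_index)
    n = spec.n_samples
    n_ch = spec.n_channels
    channels = spec.channel_names
    w = spec.connectivity_strength[label]
    profile = spec.band_variance_profile[label]
    ch_profile = (spec.channel_variance_profile or {}).get(label, {})

    x = np.zeros((n_ch, n))
    for band in DEFAULT_BANDS:
        shared = bandpass_filter(rng.standard_normal(n), band, spec.sampling_rate)
        shared /= shared.std()
        private = bandpass_filter(
            rng.standard_normal((n_ch, n)), band, spec.sampling_rate
        )
        private /= private.std(axis=1, keepdims=True)
        jitter = 2.0 ** (spec.subject_variability * rng.standard_normal())
        mixed = np.sqrt(w) * shared + np.sqrt(1.0 - w) * private
        var = BASE_BAND_VARIANCE * profile[band.name] * jitter
        scale = np.full(n_ch, np.sqrt(var))
        for i, ch in enumerate(channels):
            mult = ch_profile.get(ch, {}).get(band.name)
            if mult is not None:
                scale[i] *= np.sqrt(mult)
        x += scale[:, None] * mixed

    return RawRecording(
        subject_id=f"sub-{label}{subject_index:03d}",
        label=label,
        channel_names=channels,
        sampling_rate=spec.sampling_rate,
        data=x,
    )


def generate_cohort(spec: CohortSpec) -> list:
    """Generate the full labelled cohort (AD subjects first, then HC)."""
    cohort = [generate_subject(spec, "AD", i) for i in range(spec.n_ad)]
    cohort += [generate_subject(spec, "HC", i) for i in range(spec.n_hc)]
    return cohort


def iter_cohort(spec: CohortSpec):
    """Yield recordings one at a time (memory-friendly for long recordings)."""
    for i in range(spec.n_ad):
        yield generate_subject(spec, "AD", i)
    for i in range(spec.n_hc):
        yield generate_subject(spec, "HC", i)
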