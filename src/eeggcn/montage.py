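"""International 10-20 montage: the 19-channel layout and its anatomical regions.

The structural ("spatial") connectivity graph used by the second GCN layer is a
binary same-region relation: two electrodes are connected iff they sit in the
same anatomical lobe. With the standard 19-channel montage the region sizes are
Frontal 7, Central 3, Parietal 3, Temporal 4, Occipital 2, so the adjacency has
7^2 + 3^2 + 3^2 + 4^2 + 2^2 = 87 unit entries (19 on the diagonal).
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order used throughout the package (left-right, front-back).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Anatomical region of each electrode. Fp1/Fp2 are grouped with the frontal
#: lobe for graph construction (some importance tables display them as
#: "Prefrontal"; that is a display label, not a separate graph region).
REGION_MAP: dict[str, str] = {
    "Fp1": "Frontal", "Fp2": "Frontal", "F7": "Frontal", "F3": "Frontal",
    "Fz": "Frontal", "F4": "Frontal", "F8": "Frontal",
    "C3": "Central", "Cz": "Central", "C4": "Central",
    "P3": "Parietal", "Pz": "Parietal", "P4": "Parietal",
    "T3": "Temporal", "T4": "Temporal", "T5": "Temporal", "T6": "Temporal",
    "O1": "Occipital", "O2": "Occipital",
}

REGIONS: tuple[str, ...] = ("Frontal", "Central", "Parietal", "Temporal", "Occipital")


def region_of(channel: str) -> str:
    """Anatomical region of a 10-20 channel name.

    Raises
    ------
    KeyError
        If the channel is not part of the 19-channel montage.
    """
    try:
        return REGION_MAP[channel]
    except KeyError:
        raise KeyError(
            f"unknown channel {channel!r}: not in the 19-channel 10-20 montage"
        ) from None


def structural_adjacency(channel_names=CHANNELS_1020) -> np.ndarray:
    """Binary same-region adjacency matrix for the given channels.

    Entry (m, n) is 1 iff channels m and n lie in the same anatomical region
    (the diagonal is therefore 1). The matrix is a fixed constant of the
    montage: it does not depend on the data.
    """
    regions = [region_of(ch) for ch in channel_names]
    n = len(regions)
    a = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            a[i, j] = 1.0 if regions[i] == regions[j] else 0.0
    return a
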