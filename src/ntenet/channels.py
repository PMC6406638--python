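"""Canonical 14-channel montage of the consumer EEG headset and its groupings.

The montage covers frontal (AF3/AF4, F3/F4, F7/F8, FC5/FC6), temporal
(T7/T8) and parieto-occipital (P7/P8, O1/O2) sites of the 10-20 system.
All matrices and feature vectors in this package index channels in
``CHANNELS`` order.
"""

from __future__ import annotations

# Canonical channel order; every NTE matrix row/column follows it.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

N_CHANNELS = len(CHANNELS)

CHANNEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(CHANNELS)}

# 10-20 parity convention: odd-numbered electrodes over the left hemisphere,
# even-numbered over the right.
LEFT_HEMISPHERE: tuple[str, ...] = ("AF3", "F7", "F3", "FC5", "T7", "P7", "O1")
RIGHT_HEMISPHERE: tuple[str, ...] = ("AF4", "F8", "F4", "FC6", "T8", "P8", "O2")

# Region nodes for lobe-wise information flow. AF3/AF4 belong to no region.
REGIONS: dict[str, tuple[str, ...]] = {
    "F": ("F7", "F3", "F4", "F8"),       # frontal
    "C": ("FC5", "T7", "T8", "FC6"),     # central / temporal
    "P": ("P7", "O1", "O2", "P8"),       # parietal / occipital
}


def indices(names) -> list[int]:
    """Map channel names to their canonical indices."""
    return [CHANNEL_INDEX[n] for n in names]
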