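"""64-channel 10-20/10-10 montage used throughout the package.

The electrode layout follows the standard BioSemi 64-cap naming (a superset
of the classic 10-20 labels). Channel order is fixed and shared by the
simulator, the epoching code and the feature extractor, so a feature vector
always concatenates channels in this order.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Standard BioSemi 64-channel cap, left hemisphere first, then midline/right.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: Frontal channels where ocular/muscle artifacts concentrate.
FRONTAL_CHANNELS: tuple[str, ...] = ("Fpz", "Fp1", "Fp2", "AF7", "AF8")


def channel_index(name: str, channels: tuple[str, ...] = CHANNELS_64) -> int:
    """Index of an electrode label, raising a helpful error when unknown."""
    try:
        return channels.index(name)
    except ValueError:
        raise KeyError(
            f"unknown channel {name!r}; montage has {len(channels)} channels"
        ) from None


@lru_cache(maxsize=1)
def channel_positions() -> dict[str, np.ndarray]:
    """3-D head-frame electrode positions (meters) from the standard montage."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    return {ch: np.asarray(pos[ch], dtype=float) for ch in CHANNELS_64}


def scalp_gain_map(center: str = "Pz", sigma_m: float = 0.07) -> np.ndarray:
    """Smooth per-channel gain in [0, 1], maximal (=1) at ``center``.

    A Gaussian falloff with scalp-distance scale ``sigma_m`` (meters) over the
    electrode positions; used by the simulator as the ERP scalp topography,
    putting the largest response over central/posterior sites.
    """
    pos = channel_positions()
    c = pos[center]
    gains = np.array(
        [np.exp(-np.sum((pos[ch] - c) ** 2) / (2.0 * sigma_m**2)) for ch in CHANNELS_64]
    )
    gains[channel_index(center)] = 1.0
    return gains
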