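"""Classifier features: block-decimated, per-channel-normalized epoch data.

For the full 0-1100 ms window at 256 Hz, the first 280 of the 282
post-onset samples per electrode are reduced to 28 values by averaging each
consecutive block of 10 samples; each electrode's 28-value vector is then
normalized so its maximum absolute value is 1, and channels are concatenated
in montage order — 28 x 64 = 1792 features for the full montage. Channel
subsets (6 and 19 central/posterior electrodes) and 500 ms sliding windows
reuse the same block scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .montage import CHANNELS_64, channel_index
from .preprocess import EpochSet

BLOCK_LEN = 10

#: Central/posterior six-electrode set.
CHANNELS_6 = ("Fz", "Cz", "Pz", "PO7", "PO8", "Oz")

#: The 6-set plus 13 additional channels. The printed label "PO2" is not a
#: standard 10-20 electrode; it is kept here as an alias of POz (documented,
#: not silently guessed).
CHANNELS_19 = CHANNELS_6 + (
    "FCz", "CPz", "PO2", "C3", "C4", "P3", "P4", "P7", "P8", "PO3", "PO4", "O1", "O2",
)

CHANNEL_ALIASES = {"PO2": "POz"}


@dataclass(frozen=True)
class ChannelSet:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        resolved = [CHANNEL_ALIASES.get(ch, ch) for ch in self.labels]
        if len(set(resolved)) != len(resolved):
            raise ValueError("channel set contains duplicates")
        for ch in resolved:
            channel_index(ch)  # raises on labels outside the montage

    @property
    def resolved_labels(self) -> tuple[str, ...]:
        return tuple(CHANNEL_ALIASES.get(ch, ch) for ch in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def channel_subset(name: str) -> ChannelSet:
    """Named channel sets: "6", "19" or "64" (full montage)."""
    sets = {
        "6": CHANNELS_6,
        "19": CHANNELS_19,
        "64": CHANNELS_64,
    }
    if name not in sets:
        raise ValueError(f"unknown channel set {name!r}; options are {sorted(sets)}")
    return ChannelSet(name=name, labels=sets[name])


def temporal_windows(
    extent_ms: float = 500.0,
    starts_ms: tuple[float, ...] = (0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
) -> list[tuple[float, float]]:
    """Sliding analysis windows of equal extent (default seven 500 ms windows)."""
    return [(s, s + extent_ms) for s in starts_ms]

FULL_WINDOW = (0.0, 1100.0)


class ErpFeatureExtractor(BaseEstimator, TransformerMixin):
    """Block-average + per-channel max-abs normalization over epochs.

    Parameters
    ----------
    channel_set : str or ChannelSet
        "64" (default), "19", "6", or an explicit :class:`ChannelSet`.
    window_ms : (float, float)
        Post-stimulus analysis window; only its first ``10 * floor(n/10)``
        samples form blocks (280 of 282 samples for 0-1100 ms at 256 Hz;
        120 of 128 for the 500 ms windows).

    Normalization is per trial and per channel, on the block-averaged
    values — it needs no training-set statistics, so ``fit`` is a no-op.
    An identically-zero channel is left at zero rather than divided.
    """

    def __init__(self, channel_set="64", window_ms: tuple[float, float] = FULL_WINDOW):
        self.channel_set = channel_set
        self.window_ms = window_ms

    def _channels(self) -> ChannelSet:
        if isinstance(self.channel_set, ChannelSet):
            return self.channel_set
        return channel_subset(str(self.channel_set))

    def fit(self, X=None, y=None) -> "ErpFeatureExtractor":
        self.channel_set_ = self._channels()
        self.n_features_out_ = None  # known after first transform
        return self

    def transform(self, epochs: EpochSet) -> np.ndarray:
        """Feature matrix (n_trials, n_blocks * n_channels) for all trials."""
        cs = self._channels()
        fs = epochs.sampling_rate
        onset = epochs.onset_index()
        lo, hi = self.window_ms
        if not (0.0 <= lo < hi <= epochs.window_ms[1]):
            raise ValueError(f"analysis window {self.window_ms} outside the epoch")
        i0 = onset + int(round(lo / 1000.0 * fs))
        i1 = onset + int(round(hi / 1000.0 * fs))
        n_win = i1 - i0
        n_blocks = n_win // BLOCK_LEN
        if n_blocks < 1:
            raise ValueError(
                f"window {self.window_ms} has {n_win} samples, "
                f"too short for one {BLOCK_LEN}-sample block"
            )
        idx = [channel_index(ch, epochs.channel_names) for ch in cs.resolved_labels]
        data = epochs.epochs[:, idx, i0 : i0 + n_blocks * BLOCK_LEN]
        blocks = data.reshape(data.shape[0], data.shape[1], n_blocks, BLOCK_LEN).mean(
            axis=3
        )
        scale = np.abs(blocks).max(axis=2, keepdims=True)
        scale[scale == 0.0] = 1.0  # all-zero channel: leave features at 0
        blocks = blocks / scale
        self.n_features_out_ = n_blocks * len(idx)
        return blocks.reshape(blocks.shape[0], -1)


def extract_features(
    epochs: EpochSet,
    channel_set="64",
    window_ms: tuple[float, float] = FULL_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Features and labels (kept trials only) for a channel set and window."""
    kept = epochs.kept()
    X = ErpFeatureExtractor(channel_set, window_ms).fit().transform(kept)
    return X, kept.labels.copy()
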