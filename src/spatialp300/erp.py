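"""Averaged event-related potentials and their statistics.

Grand averages over target / non-target trials, positive-peak latency and
amplitude, per-sample Mann-Whitney significance masks comparing target
against non-target amplitude distributions, and per-direction peak tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montage import channel_index
from .preprocess import EpochSet


@dataclass
class ErpWaveform:
    values: np.ndarray  # (n_channels, n_samples), uV
    time_ms: np.ndarray
    condition: str
    n_trials: int
    channel_names: tuple[str, ...]
    direction: int | None = None

    def channel(self, name: str) -> np.ndarray:
        return self.values[channel_index(name, self.channel_names)]


@dataclass
class PeakStats:
    latency_ms: float
    amplitude_uv: float
    channel: str
    search_window_ms: tuple[float, float]


@dataclass
class SignificanceMask:
    p_values: np.ndarray
    mask: np.ndarray  # True where p < alpha
    alpha: float
    time_ms: np.ndarray
    channel: str


def _condition_label(condition) -> int:
    if condition in (1, "target"):
        return 1
    if condition in (-1, "nontarget", "non-target"):
        return -1
    raise ValueError(f"unknown condition {condition!r}")


def grand_average(
    epochs: EpochSet, condition, direction: int | None = None
) -> ErpWaveform:
    """Element-wise mean over kept trials matching the condition/direction."""
    label = _condition_label(condition)
    sel = epochs.kept_mask & (epochs.labels == label)
    if direction is not None:
        sel &= epochs.directions == direction
    n = int(sel.sum())
    if n == 0:
        raise ValueError(
            f"no kept trials for condition={condition!r}, direction={direction!r}"
        )
    return ErpWaveform(
        values=epochs.epochs[sel].mean(axis=0),
        time_ms=epochs.time_ms,
        condition="target" if label == 1 else "nontarget",
        n_trials=n,
        channel_names=epochs.channel_names,
        direction=direction,
    )


def positive_peak(
    erp: ErpWaveform,
    channel: str = "Pz",
    search_window_ms: tuple[float, float] = (0.0, 1100.0),
) -> PeakStats:
    """Latency/amplitude of the maximum on a channel within a window.

    Ties in the argmax are broken toward the earliest latency (np.argmax
    returns the first maximum).
    """
    wave = erp.channel(channel)
    lo, hi = search_window_ms
    in_win = (erp.time_ms >= lo) & (erp.time_ms <= hi)
    if not in_win.any():
        raise ValueError(f"search window {search_window_ms} contains no samples")
    idx = np.flatnonzero(in_win)
    best = idx[np.argmax(wave[idx])]
    return PeakStats(
        latency_ms=float(erp.time_ms[best]),
        amplitude_uv=float(wave[best]),
        channel=channel,
        search_window_ms=search_window_ms,
    )


def mann_whitney_mask(
    target_epochs: EpochSet,
    nontarget_epochs: EpochSet,
    channel: str = "Pz",
    alpha: float = 0.01,
) -> SignificanceMask:
    """Per-sample two-sided Mann-Whitney U comparison of the two conditions.

    At each time sample, per-trial amplitudes on ``channel`` are compared
    across the two trial groups (rank-sum with tie correction; exact null
    distribution for group sizes up to 20 without ties, normal approximation
    otherwise). No multiple-testing correction is applied: the mask mirrors
    the per-time-point p < alpha display convention.
    """
    ci_t = channel_index(channel, target_epochs.channel_names)
    ci_n = channel_index(channel, nontarget_epochs.channel_names)
    a = target_epochs.epochs[target_epochs.kept_mask, ci_t, :]
    b = nontarget_epochs.epochs[nontarget_epochs.kept_mask, ci_n, :]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 kept trials per group")
    small = max(a.shape[0], b.shape[0]) <= 20
    method = "exact" if small and not _has_ties(a, b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue)
    return SignificanceMask(
        p_values=p,
        mask=p < alpha,
        alpha=alpha,
        time_ms=target_epochs.time_ms,
        channel=channel,
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    stacked = np.concatenate([a, b], axis=0)
    return any(
        len(np.unique(stacked[:, j])) < stacked.shape[0] for j in range(stacked.shape[1])
    )


def direction_table(
    epochs: EpochSet,
    channel: str = "Pz",
    search_window_ms: tuple[float, float] = (0.0, 1100.0),
) -> pd.DataFrame:
    """Per-(direction, condition) positive-peak table at one channel.

    Empty cells (no kept trials for a combination) are flagged with NaN
    statistics rather than raising.
    """
    rows = []
    for direction in np.unique(epochs.directions):
        for label, cond in ((1, "target"), (-1, "nontarget")):
            try:
                avg = grand_average(epochs, label, int(direction))
                pk = positive_peak(avg, channel, search_window_ms)
                rows.append(
                    (int(direction), cond, pk.latency_ms, pk.amplitude_uv, avg.n_trials)
                )
            except ValueError:
                rows.append((int(direction), cond, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["direction_deg", "condition", "latency_ms", "amplitude_uv", "n_trials"]
    )
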