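"""Synthetic EEG and behavior generator for the spatial-auditory oddball task.

The generator emulates the study conditions the analysis pipeline assumes:
a six-direction auditory oddball (directions 30, 90, 150, -150, -90, -30
degrees azimuth), 150 trials per session, each trial a 100 ms stimulus
followed by a 1000 ms inter-stimulus interval, ~20% of stimuli from the
attended (target) direction, 64-channel EEG at 256 Hz.

Target trials carry a P300-like positive deflection (default peak 384 ms,
5.2 uV at Pz) preceded by a smaller N2-like negativity; non-target trials
carry an earlier, smaller positivity (default 217 ms, 3.3 uV). Both ride on
1/f background noise, and occasional high-amplitude frontal artifacts mimic
eye blinks. ERP components are Gaussian bumps: the functional form is a
modeling choice that makes peak latency and amplitude exactly controllable.

Every stochastic operation takes an explicit seed; there is no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .montage import CHANNELS_64, FRONTAL_CHANNELS, channel_index, scalp_gain_map

DIRECTIONS_6 = (30, 90, 150, -150, -90, -30)


class Event(NamedTuple):
    onset_sample: int
    direction: int
    is_target: bool


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and layout of the oddball protocol."""

    sampling_rate: float = 256.0
    trials_per_session: int = 150
    sessions: int = 12
    stimulus_ms: float = 100.0
    isi_ms: float = 1000.0
    directions: tuple[int, ...] = DIRECTIONS_6
    target_fraction: float = 0.2
    n_channels: int = 64
    channel_names: tuple[str, ...] = CHANNELS_64
    #: "stochastic": each trial is a target with prob target_fraction;
    #: "exact": exactly round(fraction * trials) targets per session.
    target_count_mode: Literal["stochastic", "exact"] = "stochastic"

    def __post_init__(self) -> None:
        if self.trials_per_session <= 0:
            raise ValueError("trials_per_session must be positive")
        if not 0.0 <= self.target_fraction < 1.0:
            raise ValueError("target_fraction must lie in [0, 1)")
        if len(set(self.directions)) != len(self.directions):
            raise ValueError("directions must be distinct")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def trial_period_ms(self) -> float:
        return self.stimulus_ms + self.isi_ms

    @property
    def trial_period_samples(self) -> int:
        # 1100 ms at 256 Hz is 281.6 samples; onsets are pinned to the
        # integer grid, so the spacing rounds to 282 samples.
        return int(round(self.trial_period_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class ErpComponent:
    """One condition's ERP template parameters (Gaussian positive + negative bump)."""

    peak_latency_ms: float
    peak_amplitude_uv: float
    peak_width_ms: float
    n2_latency_ms: float
    n2_amplitude_uv: float  # negative by convention
    n2_width_ms: float


@dataclass(frozen=True)
class ErpModel:
    """Condition-, channel- and direction-dependent ERP templates.

    ``topography`` is a per-channel gain in [0, 1] with 1 at Pz (largest
    response over central/posterior scalp); ``direction_gain`` multiplies the
    template per stimulus direction, with attenuation toward rear directions
    for targets.
    """

    target: ErpComponent = ErpComponent(384.0, 5.2, 60.0, 250.0, -2.0, 30.0)
    nontarget: ErpComponent = ErpComponent(217.0, 3.3, 55.0, 140.0, -1.2, 20.0)
    topography: np.ndarray = field(default_factory=lambda: scalp_gain_map("Pz"))
    direction_gain: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            "target": {30: 1.0, 90: 0.95, 150: 0.8, -150: 0.8, -90: 0.95, -30: 1.0},
            "nontarget": {d: 1.0 for d in DIRECTIONS_6},
        }
    )
    channel_names: tuple[str, ...] = CHANNELS_64

    def component(self, condition: str) -> ErpComponent:
        if condition == "target":
            return self.target
        if condition == "nontarget":
            return self.nontarget
        raise ValueError(f"condition must be 'target' or 'nontarget', got {condition!r}")

    def scaled(self, amplitude_factor: float) -> "ErpModel":
        """Copy with both conditions' amplitudes multiplied by a factor."""

        def scale(c: ErpComponent) -> ErpComponent:
            return replace(
                c,
                peak_amplitude_uv=c.peak_amplitude_uv * amplitude_factor,
                n2_amplitude_uv=c.n2_amplitude_uv * amplitude_factor,
            )

        return replace(self, target=scale(self.target), nontarget=scale(self.nontarget))


@dataclass(frozen=True)
class NoiseModel:
    """Background 1/f noise plus occasional high-amplitude frontal artifacts.

    The background field is spatially correlated across electrodes with a
    Gaussian kernel of scale ``spatial_scale_m`` over scalp positions —
    real background EEG is strongly coherent between neighboring electrodes,
    and an independent-per-channel field would let a multichannel classifier
    average noise away unrealistically fast. ``spatial_scale_m = 0`` gives
    independent channels.
    """

    background_sd: float = 11.0  # uV, per channel, broadband before filtering
    spectral_slope: float = 1.0  # beta in 1/f^beta power
    spatial_scale_m: float = 0.12  # correlation length over the scalp
    artifact_rate: float = 0.03  # probability per trial
    artifact_amplitude: float = 200.0  # uV, exceeds the 60 uV screen after filtering
    artifact_width_ms: float = 200.0
    artifact_channels: tuple[str, ...] = FRONTAL_CHANNELS

    def __post_init__(self) -> None:
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


@dataclass
class SessionRecording:
    """Continuous 64-channel recording with stimulus events."""

    samples: np.ndarray  # (n_channels, n_times), uV
    sampling_rate: float
    events: list[Event]
    target_direction: int
    channel_names: tuple[str, ...] = CHANNELS_64
    metadata: dict = field(default_factory=dict)

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    def to_mne_raw(self):
        """Bridge to an :class:`mne.io.RawArray` (volts, EEG channel types)."""
        import mne

        info = mne.create_info(
            list(self.channel_names), self.sampling_rate, ch_types="eeg"
        )
        return mne.io.RawArray(self.samples * 1e-6, info, verbose="error")

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": [e.onset_sample for e in self.events],
                "direction_deg": [e.direction for e in self.events],
                "is_target": [int(e.is_target) for e in self.events],
            }
        )


@dataclass
class BehaviorTable:
    """Localization-test responses and per-session target-count reports."""

    localization: pd.DataFrame  # administration, presented_deg, reported_deg
    counting: pd.DataFrame  # session, true_count, reported_count

    def localization_correct_rate(self) -> float:
        """Percent of responses where the reported direction was correct."""
        ok = self.localization["reported_deg"] == self.localization["presented_deg"]
        return 100.0 * float(ok.mean())

    def counting_error_pct(self) -> float:
        """Mean |reported - true| / true across sessions, in percent."""
        c = self.counting
        with np.errstate(invalid="ignore"):
            err = np.abs(c["reported_count"] - c["true_count"]) / c["true_count"]
        return 100.0 * float(np.nanmean(err))


def erp_waveform(
    erp: ErpModel,
    condition: str,
    direction: int,
    channel: str,
    time_grid_ms: np.ndarray,
) -> np.ndarray:
    """Deterministic ERP template on an arbitrary time grid (ms), in uV.

    The positive component is rescaled so that the template's value at
    ``peak_latency_ms`` equals ``peak_amplitude_uv`` exactly (after direction
    and topography gains), compensating for the tail of the negative bump.
    """
    comp = erp.component(condition)
    gain = erp.direction_gain[condition][direction]
    topo = erp.topography[channel_index(channel, erp.channel_names)]
    t = np.asarray(time_grid_ms, dtype=float)

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-((t - center) ** 2) / (2.0 * width**2))

    n2_at_peak = comp.n2_amplitude_uv * np.exp(
        -((comp.peak_latency_ms - comp.n2_latency_ms) ** 2) / (2.0 * comp.n2_width_ms**2)
    )
    pos_amp = comp.peak_amplitude_uv - n2_at_peak
    wave = pos_amp * bump(comp.peak_latency_ms, comp.peak_width_ms)
    wave += comp.n2_amplitude_uv * bump(comp.n2_latency_ms, comp.n2_width_ms)
    return gain * topo * wave


def _erp_template_all_channels(
    erp: ErpModel, condition: str, direction: int, time_grid_ms: np.ndarray
) -> np.ndarray:
    """(n_channels, n_times) template; channel loop factored through the gain map."""
    pz = erp_waveform(erp, condition, direction, "Pz", time_grid_ms)
    # erp_waveform is linear in the topography gain and topography[Pz] == 1.
    return erp.topography[:, None] * pz[None, :]


@lru_cache(maxsize=4)
def _spatial_mixing(channel_names: tuple[str, ...], scale_m: float) -> np.ndarray | None:
    """Cholesky factor of a Gaussian spatial correlation kernel over electrodes."""
    if scale_m <= 0.0:
        return None
    from .montage import channel_positions

    pos = channel_positions()
    xyz = np.stack([pos[ch] for ch in channel_names])
    d2 = np.sum((xyz[:, None, :] - xyz[None, :, :]) ** 2, axis=2)
    corr = np.exp(-d2 / (2.0 * scale_m**2))
    corr[np.diag_indices_from(corr)] += 1e-9
    return np.linalg.cholesky(corr)


def _one_over_f_noise(
    rng: np.random.Generator,
    channel_names: tuple[str, ...],
    n_times: int,
    sd: float,
    beta: float,
    spatial_scale_m: float = 0.0,
) -> np.ndarray:
    n_channels = len(channel_names)
    if sd == 0.0:
        return np.zeros((n_channels, n_times))
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_times)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC component
    noise = np.fft.irfft(spec * shaping[None, :], n=n_times, axis=1)
    mixing = _spatial_mixing(channel_names, spatial_scale_m)
    if mixing is not None:
        noise = mixing @ noise
    noise *= sd / noise.std(axis=1, keepdims=True)
    return noise


def simulate_session(
    protocol: ProtocolConfig,
    erp: ErpModel,
    noise: NoiseModel,
    target_direction: int,
    seed: int,
) -> SessionRecording:
    """Simulate one continuous oddball session with a fixed target direction.

    Per trial, the stimulus direction is the target direction with
    probability ``target_fraction`` and otherwise uniform over the remaining
    directions ("stochastic" mode), or exactly ``round(fraction * trials)``
    targets are placed at shuffled positions ("exact" mode). Each event adds
    the condition- and direction-specific ERP template on top of background
    noise. Identical seeds give bit-identical recordings.
    """
    if target_direction not in protocol.directions:
        raise ValueError(
            f"target_direction {target_direction} not in protocol directions "
            f"{protocol.directions}"
        )
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate
    n_trials = protocol.trials_per_session
    spacing = protocol.trial_period_samples
    lead = int(round(fs))  # 1 s of padding at both ends
    n_times = lead + n_trials * spacing + lead

    others = [d for d in protocol.directions if d != target_direction]
    if protocol.target_count_mode == "exact":
        n_targets = int(round(protocol.target_fraction * n_trials))
        is_target = np.zeros(n_trials, dtype=bool)
        is_target[rng.choice(n_trials, size=n_targets, replace=False)] = True
    else:
        is_target = rng.random(n_trials) < protocol.target_fraction
    directions = np.where(
        is_target, target_direction, rng.choice(others, size=n_trials)
    )

    data = _one_over_f_noise(
        rng,
        protocol.channel_names,
        n_times,
        noise.background_sd,
        noise.spectral_slope,
        noise.spatial_scale_m,
    )

    # ERP templates over one trial window (0 .. trial period), cached per condition
    win = np.arange(spacing) / fs * 1000.0
    templates = {
        (cond, d): _erp_template_all_channels(erp, cond, d, win)
        for cond in ("target", "nontarget")
        for d in protocol.directions
    }

    art_idx = (
        [channel_index(c, protocol.channel_names) for c in noise.artifact_channels]
        if noise.artifact_rate > 0
        else []
    )
    art_width = noise.artifact_width_ms / 1000.0 * fs
    t_rel = np.arange(spacing)

    events: list[Event] = []
    for i in range(n_trials):
        onset = lead + i * spacing
        cond = "target" if is_target[i] else "nontarget"
        data[:, onset : onset + spacing] += templates[(cond, int(directions[i]))]
        if rng.random() < noise.artifact_rate:
            center = rng.uniform(0.2 * spacing, 0.8 * spacing)
            bump = noise.artifact_amplitude * np.exp(
                -((t_rel - center) ** 2) / (2.0 * art_width**2)
            )
            data[art_idx, onset : onset + spacing] += bump[None, :]
        events.append(Event(onset, int(directions[i]), bool(is_target[i])))

    return SessionRecording(
        samples=data,
        sampling_rate=fs,
        events=events,
        target_direction=target_direction,
        channel_names=protocol.channel_names,
        metadata={"seed": seed},
    )


def default_confusion(
    directions: Sequence[int] = DIRECTIONS_6,
    correct: float = 0.92,
    neighbor: float = 0.05,
    front_back: float = 0.03,
) -> np.ndarray:
    """Row-stochastic confusion matrix over directions.

    Errors go to the two angular neighbors (split evenly) and, for the
    front/rear directions, to the same-side direction 120 degrees away
    (front-back confusion: 30<->150 and -30<->-150). The lateral directions
    (+/-90) lie on the interaural axis and have no distinct front-back
    partner, so that mass folds back into the correct response.
    """
    dirs = list(directions)
    n = len(dirs)
    fb_partner = {30: 150, 150: 30, -30: -150, -150: -30}
    mat = np.zeros((n, n))
    for i, d in enumerate(dirs):
        mat[i, i] = correct
        mat[i, (i - 1) % n] += neighbor / 2.0
        mat[i, (i + 1) % n] += neighbor / 2.0
        partner = fb_partner.get(d)
        if partner is not None and partner in dirs:
            mat[i, dirs.index(partner)] += front_back
        else:
            mat[i, i] += front_back
    return mat


def simulate_behavior(
    protocol: ProtocolConfig,
    confusion: np.ndarray | None = None,
    counting_error_rate: float = 0.05,
    seed: int = 0,
) -> BehaviorTable:
    """Simulate the localization test and the target-counting reports.

    The localization test presents each direction 10 times per
    administration, with administrations before and after the main
    experiment: 2 x 6 x 10 = 120 responses in total. Counting reports miss
    each true target independently with probability ``counting_error_rate``.
    """
    rng = np.random.default_rng(seed)
    dirs = list(protocol.directions)
    conf = default_confusion(dirs) if confusion is None else np.asarray(confusion, float)
    if conf.shape != (len(dirs), len(dirs)):
        raise ValueError("confusion matrix shape must be (n_directions, n_directions)")
    row_sums = conf.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-9):
        raise ValueError("confusion rows must each sum to 1 (tolerance 1e-9)")

    rows = []
    for administration in ("before", "after"):
        for i, presented in enumerate(dirs):
            reported = rng.choice(dirs, size=10, p=conf[i])
            for r in reported:
                rows.append((administration, presented, int(r)))
    localization = pd.DataFrame(
        rows, columns=["administration", "presented_deg", "reported_deg"]
    )

    counting_rows = []
    for s in range(protocol.sessions):
        if protocol.target_count_mode == "exact":
            true = int(round(protocol.target_fraction * protocol.trials_per_session))
        else:
            true = int(
                rng.binomial(protocol.trials_per_session, protocol.target_fraction)
            )
        reported = int(rng.binomial(true, 1.0 - counting_error_rate)) if true else 0
        counting_rows.append((s, true, reported))
    counting = pd.DataFrame(
        counting_rows, columns=["session", "true_count", "reported_count"]
    )
    return BehaviorTable(localization=localization, counting=counting)


def simulate_subject(
    protocol: ProtocolConfig,
    erp: ErpModel,
    noise: NoiseModel,
    seed: int,
) -> list[SessionRecording]:
    """Simulate a subject's sessions, cycling the target direction.

    With the default 12 sessions and 6 directions, each direction is the
    target in exactly two sessions, as in the protocol this emulates.
    """
    dirs = protocol.directions
    rng = np.random.default_rng(seed)
    session_seeds = rng.integers(0, 2**31 - 1, size=protocol.sessions)
    return [
        simulate_session(protocol, erp, noise, dirs[s % len(dirs)], int(session_seeds[s]))
        for s in range(protocol.sessions)
    ]
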