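"""Virtual directional auditory stimuli.

A stimulus is band-limited white noise (default 100 Hz - 15 kHz, 100 ms)
convolved with a per-direction stereo impulse-response pair, which places the
sound at a virtual azimuth when played over earphones. Measured per-subject
transfer functions are the gold standard for this; the module accepts
user-supplied impulse responses from 2-channel WAV files and ships a
spherical-head surrogate (Woodworth interaural time delay plus a head-shadow
level difference) so the rendering path is exercisable without measurement
hardware.

The nominal 65 dB SPL presentation level is metadata only: digital full
scale carries no physical calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclass(frozen=True)
class StimulusSpec:
    """Band-limited noise-burst parameters."""

    duration_ms: float = 100.0
    band_hz: tuple[float, float] = (100.0, 15000.0)
    level_dbspl: float = 65.0  # nominal calibration tag, not applied digitally
    sampling_rate: float = 44100.0

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if not 0.0 < low < high < self.sampling_rate / 2.0:
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high < Nyquist "
                f"({self.sampling_rate / 2.0} Hz)"
            )
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class ImpulseResponsePair:
    """Stereo impulse response for one direction."""

    left: np.ndarray
    right: np.ndarray
    sampling_rate: float
    direction_deg: float

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left/right impulse responses must have equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("impulse responses must be finite")


def bandlimited_noise(spec: StimulusSpec, seed: int) -> np.ndarray:
    """Gaussian white noise band-passed to ``spec.band_hz``, unit peak scale.

    A 4th-order Butterworth band-pass (zero-phase) shapes the spectrum; the
    output is normalized to 0.5 peak amplitude to leave headroom for the
    subsequent impulse-response convolution.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(spec.n_samples)
    sos = signal.butter(
        4, spec.band_hz, btype="bandpass", fs=spec.sampling_rate, output="sos"
    )
    y = signal.sosfiltfilt(sos, x)
    return 0.5 * y / np.max(np.abs(y))


def render_direction(noise: np.ndarray, ir: ImpulseResponsePair) -> np.ndarray:
    """Linear convolution of the mono noise with each ear's impulse response.

    Returns a (2, n + m - 1) stereo array, left ear first.
    """
    left = np.convolve(noise, ir.left, mode="full")
    right = np.convolve(noise, ir.right, mode="full")
    return np.stack([left, right])


def woodworth_itd(direction_deg: float, head_radius_m: float, sound_speed: float) -> float:
    """Interaural time difference (seconds) of the Woodworth spherical model.

    ITD(theta) = (a / c) * (sin|theta| + |theta|_rad) for azimuth folded into
    the frontal quadrant; positive values mean the right ear leads for
    positive (rightward) azimuths. Rear azimuths mirror their frontal
    counterparts (the sphere is front-back symmetric).
    """
    theta = np.deg2rad(direction_deg)
    # fold rear hemifield onto the front: ITD is symmetric about +/-90 deg
    folded = np.arcsin(np.sin(theta))
    return head_radius_m / sound_speed * (np.sin(abs(folded)) + abs(folded)) * np.sign(
        folded
    )


def spherical_head_ir(
    direction_deg: float,
    sampling_rate: float = 44100.0,
    head_radius_m: float = 0.0875,
    sound_speed: float = 343.0,
    shadow_db_at_90: float = 6.0,
    n_taps: int = 64,
) -> ImpulseResponsePair:
    """Surrogate stereo impulse response for a spherical head.

    The ipsilateral ear receives a unit impulse; the contralateral ear is
    delayed by the Woodworth ITD (implemented at fractional-sample precision
    with a truncated-sinc kernel) and attenuated by a level difference that
    grows to ``shadow_db_at_90`` dB at +/-90 degrees. A bare sphere is
    front-back ambiguous, so rear directions (|azimuth| > 90) additionally
    receive a mild high-frequency roll-off on both ears, standing in for the
    pinna shadowing that disambiguates rear sources. Direction 0 gives
    identical ears; IR(-theta) equals IR(theta) with ears swapped.
    """
    if not -180.0 < direction_deg <= 180.0:
        raise ValueError("direction must lie in (-180, 180] degrees")
    itd = woodworth_itd(direction_deg, head_radius_m, sound_speed)
    delay = abs(itd) * sampling_rate
    theta = np.deg2rad(direction_deg)
    shadow = 10.0 ** (-shadow_db_at_90 * abs(np.sin(theta)) / 20.0)

    n = np.arange(n_taps, dtype=float)
    lead = np.zeros(n_taps)
    lead[0] = 1.0
    # fractional-delay truncated sinc centered at `delay` (delay << n_taps,
    # so truncation ripple is negligible for rendering purposes)
    lag = shadow * np.sinc(n - delay)

    if direction_deg >= 0:  # source on the right: right ear leads
        left, right = lag, lead
    else:
        left, right = lead, lag
    if direction_deg in (0.0, 180.0):
        left = right = lead.copy()
    if abs(direction_deg) > 90.0:  # rear source: pinna-style spectral tilt
        smooth = np.array([0.7, 0.3])
        left = np.convolve(left, smooth)[:n_taps]
        right = np.convolve(right, smooth)[:n_taps]
    return ImpulseResponsePair(
        left=left, right=right, sampling_rate=sampling_rate, direction_deg=direction_deg
    )


def write_wav(path, data: np.ndarray, sampling_rate: float) -> None:
    """Write mono (n,) or stereo (2, n) float32 PCM WAV."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr.T  # scipy expects (n_samples, n_channels)
    wavfile.write(path, int(sampling_rate), arr)


def read_ir_wav(path, direction_deg: float) -> ImpulseResponsePair:
    """Load a 2-channel WAV file as an impulse-response pair."""
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path} is not a 2-channel WAV file")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return ImpulseResponsePair(
        left=np.asarray(data[:, 0], float),
        right=np.asarray(data[:, 1], float),
        sampling_rate=float(rate),
        direction_deg=direction_deg,
    )
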