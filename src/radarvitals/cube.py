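"""Radar data cube construction: per-channel range FFT over fast time."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .errors import ConfigurationError
from .simulate import ADCFrameCube, RadarConfig, Recording

__all__ = [
    "RadarDataCube",
    "SlowTimeCube",
    "range_fft",
    "range_resolution",
    "virtual_array_size",
    "slow_time_cube",
]


def range_resolution(config: RadarConfig) -> float:
    """Range resolution c / (2B) [m]."""
    return config.c / (2.0 * config.bandwidth)


def virtual_array_size(config: RadarConfig) -> int:
    """Virtual channel count: n_tx * n_rx."""
    return config.n_tx * config.n_rx


def _bin_spacing(config: RadarConfig, n_samples: int, fft_size: int) -> float:
    # ADC spans the full chirp, so beat-bin spacing fs/fft_size maps to
    # c/(2B) * n_samples / fft_size metres.
    return range_resolution(config) * n_samples / fft_size


@dataclass(frozen=True)
class RadarDataCube:
    """One frame after the range FFT: (chirp, range bin, virtual channel)."""

    values: np.ndarray
    bin_spacing: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ConfigurationError(
                "RadarDataCube expects (chirps, range bins, channels)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def ranges(self) -> np.ndarray:
        """Range [m] of each bin centre (bin 0 = zero range)."""
        if self.bin_spacing is None:
            raise ConfigurationError("bin spacing unknown; pass config to range_fft")
        return np.arange(self.values.shape[1]) * self.bin_spacing


def range_fft(
    frame: ADCFrameCube | np.ndarray,
    fft_size: int | None = None,
    *,
    window: str | None = "hann",
    config: RadarConfig | None = None,
) -> RadarDataCube:
    """FFT along fast time, per chirp and channel.

    ``window`` is a fast-time taper name understood by
    :func:`scipy.signal.get_window` (``None`` or ``"boxcar"`` for
    rectangular).  ``fft_size`` defaults to the sample count and must not be
    smaller than it.
    """
    samples = frame.samples if isinstance(frame, ADCFrameCube) else np.asarray(frame)
    t0 = frame.t0 if isinstance(frame, ADCFrameCube) else 0.0
    if samples.ndim != 3:
        raise ConfigurationError("expected (chirps, samples, channels) input")
    n = samples.shape[1]
    if fft_size is None:
        fft_size = n
    if fft_size < n:
        raise ConfigurationError("fft_size must be >= number of samples")
    if window is not None and window != "boxcar":
        samples = samples * get_window(window, n)[None, :, None]
    values = np.fft.fft(samples, n=fft_size, axis=1)
    spacing = None if config is None else _bin_spacing(config, n, fft_size)
    return RadarDataCube(values=values, bin_spacing=spacing, t0=t0)


@dataclass(frozen=True)
class SlowTimeCube:
    """Chirp-averaged range profiles over frames: (frame, range bin, channel).

    One complex value per frame, range bin and virtual channel; the chirps
    of each frame are averaged coherently after the range FFT, so the slow
    axis is sampled at the frame rate.
    """

    values: np.ndarray
    frame_rate: float
    bin_spacing: float | None = None
    config: RadarConfig | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ConfigurationError(
                "SlowTimeCube expects (frames, range bins, channels)"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def channel(self, index: int) -> np.ndarray:
        """Slow-time slice (frames, range bins) of one virtual channel."""
        return self.values[:, :, index]

    def checksum(self) -> str:
        """SHA-256 of the cube bytes (for concurrent-comparison audits)."""
        return hashlib.sha256(np.ascontiguousarray(self.values).tobytes()).hexdigest()


def slow_time_cube(
    recording: Recording,
    fft_size: int | None = None,
    *,
    window: str | None = "hann",
) -> SlowTimeCube:
    """Stream a recording through the range FFT and chirp averaging.

    Frames are processed one at a time so the raw ADC cube never needs to be
    held in memory.
    """
    config = recording.config
    rows = []
    spacing = None
    for frame in recording:
        cube = range_fft(frame, fft_size, window=window, config=config)
        spacing = cube.bin_spacing
        rows.append(cube.values.mean(axis=0))
    if not rows:
        raise ConfigurationError("recording contains no frames")
    return SlowTimeCube(
        values=np.stack(rows),
        frame_rate=config.frame_rate,
        bin_spacing=spacing,
        config=config,
    )
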