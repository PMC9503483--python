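"""FMCW IF-signal synthesis for a MIMO virtual uniform linear array.

The transmit waveform is a linear chirp of bandwidth ``B`` over duration
``T`` starting at carrier ``fc``.  Mixing the echo of a reflector at delay
``dt`` with the transmit copy yields the IF sample phase

    2*pi * ( fc*dt + (B/T)*dt*t - (B/(2T))*dt**2 )

at fast time ``t``.  A far-field reflector at azimuth ``theta`` additionally
carries the geometric inter-channel phase ``2*pi*d*(n-1)*sin(theta)/lambda``
on virtual channel ``n`` (``pi*(n-1)*sin(theta)`` at half-wavelength
spacing).  TDM-MIMO orthogonality is idealised: the ``n_tx * n_rx`` virtual
channels are synthesised directly as a half-wavelength ULA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .scene import Scene, chest_displacement

__all__ = [
    "C_LIGHT",
    "RadarConfig",
    "ADCFrameCube",
    "Recording",
    "round_trip_delay",
    "if_signal",
    "simulate_recording",
]

#: Propagation speed used throughout [m/s].
C_LIGHT = 3.0e8


@dataclass(frozen=True)
class RadarConfig:
    """Waveform and array constants of the simulated radar.

    Defaults follow the 60 GHz off-the-shelf device profile: 3.89 GHz chirp
    bandwidth, 50 chirps per frame, 20 frames/s, 2 TX x 4 RX giving an
    8-element half-wavelength virtual ULA.  The ADC rate and samples per
    chirp are not published for that device; the defaults (256 complex
    samples spanning the full 50 us chirp, i.e. 5.12 MHz) give a ~9.9 m
    unambiguous range at the native c/(2B) bin spacing.
    """

    fc: float = 60.0e9
    bandwidth: float = 3.89e9
    chirp_duration: float = 50.0e-6
    chirps_per_frame: int = 50
    frame_rate: float = 20.0
    n_samples: int = 256
    n_tx: int = 2
    n_rx: int = 4
    spacing: float | None = None
    c: float = C_LIGHT

    def __post_init__(self) -> None:
        for name in ("fc", "bandwidth", "chirp_duration", "frame_rate", "c"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.chirps_per_frame < 1:
            raise ConfigurationError("chirps_per_frame must be >= 1")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_tx < 1 or self.n_rx < 1:
            raise ConfigurationError("antenna counts must be >= 1")
        if self.spacing is not None and self.spacing <= 0:
            raise ConfigurationError("element spacing must be > 0")
        if self.chirps_per_frame * self.chirp_duration > 1.0 / self.frame_rate:
            raise ConfigurationError("chirps do not fit within one frame")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / fc [m]."""
        return self.c / self.fc

    @property
    def d(self) -> float:
        """Virtual element spacing [m]; lambda/2 unless overridden."""
        return self.wavelength / 2 if self.spacing is None else self.spacing

    @property
    def n_virtual(self) -> int:
        """Number of virtual receive channels, n_tx * n_rx."""
        return self.n_tx * self.n_rx

    @property
    def slope(self) -> float:
        """Chirp slope B / T [Hz/s]."""
        return self.bandwidth / self.chirp_duration

    @property
    def fs(self) -> float:
        """Complex ADC sampling rate [Hz]; the ADC spans the full chirp."""
        return self.n_samples / self.chirp_duration

    @property
    def frame_period(self) -> float:
        return 1.0 / self.frame_rate

    def fast_time(self) -> np.ndarray:
        """Fast-time sample grid for one chirp [s]."""
        return np.arange(self.n_samples) / self.fs

    def channel_phases(self, theta_deg: float) -> np.ndarray:
        """Geometric phase per virtual channel for arrival angle ``theta_deg``."""
        n = np.arange(self.n_virtual)
        return (
            2 * np.pi * self.d * n * np.sin(np.deg2rad(theta_deg))
            / self.wavelength
        )


@dataclass(frozen=True)
class ADCFrameCube:
    """Raw complex ADC samples of one frame: (chirp, fast-time, channel)."""

    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.samples.ndim != 3:
            raise ConfigurationError(
                "ADCFrameCube expects (chirps, samples, channels)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.samples.shape


def round_trip_delay(r, v_r: float = 0.0, t: float = 0.0, c: float = C_LIGHT):
    """Round-trip delay 2*(R + v_r*t)/c [s] of a reflector at range ``r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("range must be > 0")
    out = 2.0 * (r + v_r * t) / c
    return out if out.ndim else float(out)


def if_signal(
    config: RadarConfig,
    r,
    n_chan: int,
    theta_deg: float,
    t_fast: np.ndarray | None = None,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Complex IF samples of one chirp for one virtual channel.

    ``r`` is the reflector range at the chirp start (stop-and-hop: motion is
    frozen within a chirp).  ``n_chan`` is 1-based; channel 1 carries no
    geometric phase.
    """
    if not 1 <= n_chan <= config.n_virtual:
        raise ConfigurationError(
            f"channel {n_chan} outside 1..{config.n_virtual}"
        )
    if t_fast is None:
        t_fast = config.fast_time()
    dt = round_trip_delay(r, c=config.c)
    phase = 2 * np.pi * (
        config.fc * dt
        + config.slope * dt * t_fast
        - 0.5 * config.slope * dt**2
    )
    geo = config.channel_phases(theta_deg)[n_chan - 1]
    return amplitude * np.exp(1j * (phase + geo))


def _frame_samples(
    config: RadarConfig, scene: Scene, t0: float, rng: np.random.Generator | None
) -> np.ndarray:
    """Synthesise one frame cube (chirps, samples, channels)."""
    m = config.chirps_per_frame
    t_chirp = t0 + np.arange(m) * config.chirp_duration
    t_fast = config.fast_time()[None, :, None]
    out = np.zeros((m, config.n_samples, config.n_virtual), dtype=complex)

    def add_reflector(r, amplitude, theta_deg):
        # r: scalar (static) or (m,) per-chirp ranges
        dt = 2.0 * np.asarray(r, dtype=float) / config.c
        dt = dt.reshape(-1, 1, 1)
        phase = 2 * np.pi * (
            config.fc * dt
            + config.slope * dt * t_fast
            - 0.5 * config.slope * dt**2
        )
        geo = config.channel_phases(theta_deg)[None, None, :]
        out[:] += amplitude * np.exp(1j * (phase + geo))

    r_target = scene.r0 + chest_displacement(t_chirp, scene.motion)
    add_reflector(r_target, scene.sigma * scene.gain(scene.theta) ** 2, scene.theta)
    for c in scene.clutter:
        add_reflector(
            c.range_m, c.amplitude * scene.gain(c.angle_deg) ** 2, c.angle_deg
        )
    if scene.noise_std > 0:
        if rng is None:
            raise ConfigurationError("noisy scene requires a random generator")
        noise = rng.standard_normal(out.shape) + 1j * rng.standard_normal(out.shape)
        out += (scene.noise_std / math.sqrt(2.0)) * noise
    return out


@dataclass(frozen=True)
class Recording:
    """A lazily synthesised sequence of ADC frames.

    Iteration restarts the noise generator from ``seed``, so iterating twice
    yields bit-identical frames.
    """

    config: RadarConfig
    scene: Scene
    duration: float
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration * self.config.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.config.frame_period

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        rng = np.random.default_rng(self.seed)
        for t0 in self.frame_times:
            yield ADCFrameCube(
                _frame_samples(self.config, self.scene, float(t0), rng),
                t0=float(t0),
            )


def simulate_recording(
    config: RadarConfig, scene: Scene, duration: float, seed: int = 0
) -> Recording:
    """Build a :class:`Recording` of ``floor(duration * frame_rate)`` frames.

    Raises
    ------
    DomainError
        If the duration is shorter than one frame.
    """
    if duration <= 0 or duration * config.frame_rate < 1:
        raise DomainError("duration must cover at least one frame")
    return Recording(config=config, scene=scene, duration=float(duration), seed=int(seed))
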