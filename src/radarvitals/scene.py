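"""Synthetic scenes: chest micro-motion, antenna gain taper, reflector layout.

A :class:`Scene` stands in for a seated human subject: a point reflector at a
nominal range and azimuth whose radial position is modulated by a breathing
and a heartbeat sinusoid, optionally accompanied by static clutter reflectors
and additive receiver noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "ChestMotion",
    "Reflector",
    "Scene",
    "chest_displacement",
    "antenna_gain",
    "make_scene",
    "DEFAULT_TAPER_EXPONENT",
]

#: Cosine-power exponent for the one-way amplitude taper.  Chosen so that the
#: two-way power gain at 40 degrees is ~6 dB below boresight
#: (40 * k * log10(cos 40deg) = -6 dB  =>  k ~= 1.3).
DEFAULT_TAPER_EXPONENT = 1.3

_F_BR_RANGE = (0.05, 1.0)
_F_HR_RANGE = (0.6, 3.0)


@dataclass(frozen=True)
class ChestMotion:
    """Parameters of the two-sinusoid chest displacement model.

    The displacement amplitudes are stand-ins — resting-adult chest-surface
    motion is of order millimetres for breathing and sub-millimetre for the
    heartbeat, with the heartbeat an order of magnitude weaker.

    Parameters
    ----------
    f_br, f_hr : float
        Breathing and heart fundamental frequencies [Hz].
    a_br, a_hr : float
        Radial displacement amplitudes [m]; ``a_hr`` must be below ``a_br``.
    phi_br, phi_hr : float
        Phase offsets [rad].
    harmonics : tuple of (freq, amplitude, phase)
        Optional extra sinusoids [Hz, m, rad] for stress tests.
    """

    f_br: float = 0.25
    a_br: float = 2.0e-3
    f_hr: float = 1.25
    a_hr: float = 0.3e-3
    phi_br: float = 0.0
    phi_hr: float = 0.0
    harmonics: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (_F_BR_RANGE[0] < self.f_br < _F_BR_RANGE[1]):
            raise ConfigurationError(
                f"f_br={self.f_br} outside {_F_BR_RANGE} Hz"
            )
        if not (_F_HR_RANGE[0] < self.f_hr < _F_HR_RANGE[1]):
            raise ConfigurationError(
                f"f_hr={self.f_hr} outside {_F_HR_RANGE} Hz"
            )
        if self.a_br <= 0 or self.a_hr < 0:
            raise ConfigurationError("displacement amplitudes must be positive")
        if self.a_hr >= self.a_br:
            raise ConfigurationError("a_hr must be smaller than a_br")
        for h in self.harmonics:
            if len(h) != 3:
                raise ConfigurationError(
                    "harmonics must be (freq, amplitude, phase) triples"
                )

    @property
    def br_bpm(self) -> float:
        """Ground-truth breathing rate in breaths per minute."""
        return 60.0 * self.f_br

    @property
    def hr_bpm(self) -> float:
        """Ground-truth heart rate in beats per minute."""
        return 60.0 * self.f_hr


@dataclass(frozen=True)
class Reflector:
    """A static point reflector (clutter)."""

    range_m: float
    amplitude: float
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.range_m <= 0:
            raise ConfigurationError("clutter range must be > 0")
        if self.amplitude < 0:
            raise ConfigurationError("clutter amplitude must be >= 0")
        if abs(self.angle_deg) > 90:
            raise ConfigurationError("clutter angle must be within +/-90 deg")


def chest_displacement(t, motion: ChestMotion):
    """Radial chest displacement [m] at time(s) ``t`` [s].

    Pure function: sum of the breathing and heartbeat sinusoids (plus any
    extra harmonics), bounded in magnitude by the sum of the amplitudes.
    """
    t = np.asarray(t, dtype=float)
    x = motion.a_br * np.sin(2 * np.pi * motion.f_br * t + motion.phi_br)
    x = x + motion.a_hr * np.sin(2 * np.pi * motion.f_hr * t + motion.phi_hr)
    for f, a, p in motion.harmonics:
        x = x + a * np.sin(2 * np.pi * f * t + p)
    return x


def antenna_gain(theta_deg, exponent: float = DEFAULT_TAPER_EXPONENT):
    """Relative one-way amplitude gain of the antenna at azimuth ``theta_deg``.

    Parametric cosine-power taper: ``cos(theta)**exponent``.  Normalised to 1
    at boresight, even in the angle, and non-increasing away from boresight.

    Raises
    ------
    DomainError
        If any angle lies outside [-90, 90] degrees.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(np.abs(theta) > 90):
        raise DomainError("antenna_gain defined only for |theta| <= 90 deg")
    if exponent < 0:
        raise ConfigurationError("taper exponent must be >= 0")
    gain = np.cos(np.deg2rad(theta)) ** exponent
    return gain if gain.ndim else float(gain)


@dataclass(frozen=True)
class Scene:
    """A complete synthetic measurement scene.

    Attributes
    ----------
    r0 : float
        Nominal target range [m].
    theta : float
        Target azimuth [deg], positive toward increasing virtual-channel
        index.
    sigma : float
        Relative target reflection amplitude (dimensionless).
    motion : ChestMotion
        Chest micro-motion parameters (the ground truth).
    clutter : tuple of Reflector
        Static reflectors added to every chirp.
    noise_std : float
        Standard deviation of the circularly symmetric complex Gaussian
        noise added per ADC sample (total, i.e. both quadratures combined).
    taper_exponent : float or None
        Cosine-power exponent of the antenna amplitude taper; ``None``
        disables the taper (unit gain at every angle).
    seed : int
        Seed recorded at construction; used by :func:`make_scene` to draw
        randomised motion phases.
    """

    r0: float
    theta: float
    sigma: float = 1.0
    motion: ChestMotion = field(default_factory=ChestMotion)
    clutter: tuple[Reflector, ...] = ()
    noise_std: float = 0.0
    taper_exponent: float | None = DEFAULT_TAPER_EXPONENT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ConfigurationError("target range r0 must be > 0")
        if abs(self.theta) > 90:
            raise ConfigurationError("target azimuth must be within +/-90 deg")
        if self.sigma < 0:
            raise ConfigurationError("target amplitude must be >= 0")
        if self.noise_std < 0:
            raise ConfigurationError("noise_std must be >= 0")

    def gain(self, theta_deg: float) -> float:
        """One-way amplitude gain at ``theta_deg`` under this scene's taper."""
        if self.taper_exponent is None:
            return 1.0
        return float(antenna_gain(theta_deg, self.taper_exponent))


def make_scene(
    distance: float,
    angle: float,
    motion: ChestMotion | None = None,
    clutter=(),
    noise_std: float = 0.0,
    seed: int = 0,
    *,
    sigma: float = 1.0,
    taper_exponent: float | None = DEFAULT_TAPER_EXPONENT,
) -> Scene:
    """Assemble a :class:`Scene`, deterministically for a given seed.

    If ``motion`` is ``None`` a default :class:`ChestMotion` is used with
    phase offsets drawn uniformly from [0, 2*pi) using ``seed``, so repeated
    calls with identical arguments yield identical scenes while different
    seeds decorrelate the motion phase.
    """
    if motion is None:
        rng = np.random.default_rng(seed)
        phi_br, phi_hr = rng.uniform(0.0, 2 * np.pi, size=2)
        motion = ChestMotion(phi_br=float(phi_br), phi_hr=float(phi_hr))
    clutter = tuple(
        c if isinstance(c, Reflector) else Reflector(*c) for c in clutter
    )
    return Scene(
        r0=float(distance),
        theta=float(angle),
        sigma=float(sigma),
        motion=motion,
        clutter=clutter,
        noise_std=float(noise_std),
        taper_exponent=taper_exponent,
        seed=int(seed),
    )
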