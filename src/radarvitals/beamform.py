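"""Delay-and-sum receiver beamforming on the radar data cube.

Steering weights ``w_n = exp(-j * pi * (n-1) * sin(theta))`` (half-wavelength
spacing) conjugate the geometric inter-channel phase of an arrival from
``theta`` so the channel sum is coherent at the matched angle.  Scanning the
steering angle produces a range-angle map whose peak localises the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube import RadarDataCube, SlowTimeCube
from .errors import ConfigurationError, EstimationError

__all__ = [
    "SteeringWeights",
    "RangeAngleMap",
    "steering_delay",
    "steering_weights",
    "apply_beamforming",
    "beam_scan",
    "estimate_aoa",
    "phase_alignment_check",
    "DEFAULT_SCAN_GRID",
]

#: -90..+90 degrees in 2-degree steps.
DEFAULT_SCAN_GRID = np.arange(-90.0, 91.0, 2.0)


def steering_delay(
    theta_deg: float,
    n_chan: int,
    d: float | None = None,
    wavelength: float | None = None,
) -> float:
    """Steering phase [rad] for (1-based) channel ``n_chan`` at ``theta_deg``.

    General form ``(n-1) * 2*pi*d*sin(theta)/lambda``; with ``d`` and
    ``wavelength`` omitted the half-wavelength simplification
    ``pi*(n-1)*sin(theta)`` is used.
    """
    if n_chan < 1:
        raise ConfigurationError("channel index is 1-based; must be >= 1")
    ratio = 0.5 if d is None or wavelength is None else d / wavelength
    return float((n_chan - 1) * 2 * np.pi * ratio * np.sin(np.deg2rad(theta_deg)))


@dataclass(frozen=True)
class SteeringWeights:
    """Unit-modulus delay-and-sum weights for one steering angle."""

    weights: np.ndarray
    theta_deg: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 1 or w.size < 1:
            raise ConfigurationError("weights must be a non-empty vector")
        if not np.allclose(np.abs(w), 1.0):
            raise ConfigurationError("steering weights must be unit modulus")

    def __len__(self) -> int:
        return self.weights.size


def steering_weights(
    theta_deg: float,
    n_virtual: int,
    *,
    d: float | None = None,
    wavelength: float | None = None,
) -> SteeringWeights:
    """Weight vector ``exp(-j * delay_n)`` over ``n_virtual`` channels."""
    if n_virtual < 1:
        raise ConfigurationError("n_virtual must be >= 1")
    delays = np.array(
        [steering_delay(theta_deg, n, d, wavelength) for n in range(1, n_virtual + 1)]
    )
    return SteeringWeights(weights=np.exp(-1j * delays), theta_deg=float(theta_deg))


def _channel_values(x) -> np.ndarray:
    if isinstance(x, (RadarDataCube, SlowTimeCube)):
        return x.values
    return np.asarray(x)


def apply_beamforming(x, w: SteeringWeights) -> np.ndarray:
    """Weighted channel sum (the beamformed slice, channel axis removed).

    Accepts a :class:`RadarDataCube`, :class:`SlowTimeCube` or any complex
    array with channels on the last axis.
    """
    values = _channel_values(x)
    if values.shape[-1] != len(w):
        raise ConfigurationError(
            f"channel mismatch: data has {values.shape[-1]}, weights {len(w)}"
        )
    return values @ w.weights


def beam_scan(x, angles=None) -> "RangeAngleMap":
    """Scan steering angles into a range-angle magnitude map.

    For each grid angle the beamformed slice is reduced to a per-bin
    root-mean-square magnitude over the slow (chirp/frame) axis.
    """
    values = _channel_values(x)
    if angles is None:
        angles = DEFAULT_SCAN_GRID
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ConfigurationError("scan grid must be non-empty")
    n_virtual = values.shape[-1]
    flat = values.reshape(-1, values.shape[-2], n_virtual)
    cols = []
    for theta in angles:
        bf = apply_beamforming(flat, steering_weights(theta, n_virtual))
        cols.append(np.sqrt(np.mean(np.abs(bf) ** 2, axis=0)))
    spacing = getattr(x, "bin_spacing", None)
    return RangeAngleMap(
        values=np.stack(cols, axis=1), angles_deg=angles, bin_spacing=spacing
    )


@dataclass(frozen=True)
class RangeAngleMap:
    """Non-negative magnitudes indexed (range bin, scan angle)."""

    values: np.ndarray
    angles_deg: np.ndarray
    bin_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.angles_deg):
            raise ConfigurationError("map shape must be (range bins, angles)")
        if np.any(self.values < 0):
            raise ConfigurationError("map magnitudes must be non-negative")

    def argmax(self) -> tuple[int, float]:
        """(range bin, angle) of the map maximum."""
        b, a = np.unravel_index(np.argmax(self.values), self.values.shape)
        return int(b), float(self.angles_deg[a])


def estimate_aoa(ram: RangeAngleMap, threshold: float = 0.5) -> float:
    """Magnitude-weighted mean scan angle of cells above ``threshold * max``.

    Raises
    ------
    EstimationError
        If the map has no positive maximum.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must lie in (0, 1]")
    peak = ram.values.max()
    if peak <= 0:
        raise EstimationError("range-angle map has no positive maximum")
    mask = ram.values >= threshold * peak
    weights = np.where(mask, ram.values, 0.0)
    return float(
        (weights * ram.angles_deg[None, :]).sum() / weights.sum()
    )


def phase_alignment_check(x, w: SteeringWeights, target_bin: int) -> float:
    """Circular standard deviation [rad] of weighted per-channel phases.

    The slow axis is first summed coherently per channel at ``target_bin``;
    a matched steering vector on a noiseless scene collapses the spread to
    ~0, while a mismatched one leaves the residual geometric phases.
    """
    values = _channel_values(x)
    if not 0 <= target_bin < values.shape[-2]:
        raise ConfigurationError("target bin outside the cube")
    per_channel = values[..., target_bin, :].reshape(-1, values.shape[-1]).mean(axis=0)
    phases = np.angle(per_channel * w.weights)
    resultant = np.abs(np.mean(np.exp(1j * phases)))
    resultant = min(resultant, 1.0)
    if resultant < 1e-300:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(resultant)))
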