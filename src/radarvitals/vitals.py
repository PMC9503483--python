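"""Stepwise phase-based vital-sign extraction.

Chain (after optional beamforming): recursive clutter suppression, target
range-bin selection, slow-time phase accumulation and unwrapping, dual
band-pass filtering, windowed spectral-peak rate estimation, and moving-mean
smoothing.  Chest displacement ``x(t)`` maps to echo phase ``4*pi*x/lambda``
(two-way path), so sub-wavelength motion is read directly off the phase of
the target bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, get_window, lfilter, sosfiltfilt

from .beamform import apply_beamforming, beam_scan, estimate_aoa, steering_weights
from .cube import SlowTimeCube
from .errors import ConfigurationError, DetectionError, DomainError

__all__ = [
    "PhaseSeries",
    "VitalsResult",
    "clutter_filter",
    "select_target_bin",
    "extract_phase",
    "bandpass_rates",
    "extract_vitals",
    "BR_BAND",
    "HR_BAND",
]

#: Default band edges [Hz]: 6-36 breaths/min and 48-132 beats/min.
BR_BAND = (0.1, 0.6)
HR_BAND = (0.8, 2.2)


def clutter_filter(x, alpha: float = 0.95, axis: int = 0):
    """Recursive background subtraction along ``axis``.

    Background estimate ``b_k = alpha*b_{k-1} + (1-alpha)*x_k`` is
    subtracted from the input — the IIR high-pass
    ``alpha*(1 - z^-1) / (1 - alpha*z^-1)``.  The background is seeded with
    the first sample (``b_0 = x_0``), so a purely static input is cancelled
    from the start instead of leaking a long settling transient; any later
    deviation from the background decays geometrically at rate ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie strictly in (0, 1)")
    x = np.asarray(x)
    if x.shape[axis] == 0:
        return x.copy()
    x0 = np.take(x, [0], axis=axis)
    zi = alpha * x0  # seeds b_0 = x_0
    background, _ = lfilter([1.0 - alpha], [1.0, -alpha], x, axis=axis, zi=zi)
    return x - background


def select_target_bin(series, alpha: float = 0.95) -> int:
    """Range bin with maximal clutter-filtered slow-time magnitude variance.

    ``series`` is a complex (frames, range bins) slice (beamformed or single
    channel).  Ties break toward the smaller bin.

    Raises
    ------
    DetectionError
        If every bin has the same variance (degenerate input).
    """
    series = np.asarray(series)
    if series.ndim != 2 or series.shape[0] < 2:
        raise DetectionError("need a (frames, bins) slice with >= 2 frames")
    filtered = clutter_filter(series, alpha, axis=0)
    variance = np.var(np.abs(filtered), axis=0)
    spread = variance.max() - variance.min()
    if spread <= 1e-15 * max(variance.max(), 1.0):
        raise DetectionError("no bin stands out: all variances equal")
    return int(np.argmax(variance))


@dataclass(frozen=True)
class PhaseSeries:
    """Unwrapped slow-time phase [rad] sampled at the frame rate."""

    values: np.ndarray
    frame_rate: float
    source_bin: int
    beamformed: bool = False

    def __post_init__(self) -> None:
        if np.asarray(self.values).ndim != 1:
            raise ConfigurationError("phase series must be one-dimensional")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("phase series must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate

    def __len__(self) -> int:
        return len(self.values)


def extract_phase(
    series,
    target_bin: int,
    frame_rate: float,
    *,
    beamformed: bool = False,
) -> PhaseSeries:
    """Per-frame phase at ``target_bin``, unwrapped over slow time.

    ``series`` is a complex (frames, range bins) slice.  Zero-magnitude
    frames raise a low-SNR warning and hold the previous frame's complex
    value so the unwrap stays well defined.
    """
    series = np.asarray(series)
    if series.ndim != 2:
        raise ConfigurationError("expected a (frames, bins) slice")
    if not 0 <= target_bin < series.shape[1]:
        raise ConfigurationError("target bin outside the slice")
    z = series[:, target_bin].astype(complex).copy()
    dead = np.abs(z) == 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} zero-magnitude frames at bin {target_bin}; "
            "holding previous phase",
            stacklevel=2,
        )
        for i in np.flatnonzero(dead):
            z[i] = z[i - 1] if i > 0 else 1.0
    phase = np.unwrap(np.angle(z))
    return PhaseSeries(
        values=phase,
        frame_rate=float(frame_rate),
        source_bin=int(target_bin),
        beamformed=beamformed,
    )


#: An in-band peak falling inside a notch interval is kept anyway when it is
#: this many times stronger than the best peak outside the notches — a true
#: heartbeat coinciding with a breathing harmonic dwarfs the harmonic floor.
_NOTCH_OVERRIDE_RATIO = 2.0


def _spectral_peak(segment, fs, band, nfft, notch):
    spectrum = np.abs(np.fft.rfft(segment, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        return math.nan
    idx = np.flatnonzero(in_band)
    best = idx[np.argmax(spectrum[idx])]
    if spectrum[best] < 1e-12:
        return math.nan
    notched = np.zeros_like(in_band)
    for f0, halfwidth in notch:
        notched |= np.abs(freqs - f0) <= halfwidth
    if not notched[best]:
        return 60.0 * freqs[best]
    outside = in_band & ~notched
    if not np.any(outside):
        return 60.0 * freqs[best]
    idx_out = np.flatnonzero(outside)
    best_out = idx_out[np.argmax(spectrum[idx_out])]
    if spectrum[best] >= _NOTCH_OVERRIDE_RATIO * spectrum[best_out]:
        return 60.0 * freqs[best]
    if spectrum[best_out] < 1e-12:
        return math.nan
    return 60.0 * freqs[best_out]


def bandpass_rates(
    phase: PhaseSeries,
    band: tuple[float, float] = BR_BAND,
    window: float = 30.0,
    stride: float = 1.0,
    *,
    resolution_bpm: float = 0.25,
    smooth: int = 5,
    order: int = 4,
    notch: tuple[tuple[float, float], ...] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed spectral-peak rate estimates [per minute] of a phase series.

    The series is band-pass filtered once with a zero-phase forward-backward
    Butterworth filter, then split into overlapping windows; each window is
    Hann-tapered and zero-padded so the spectral grid is finer than
    ``resolution_bpm``, and the in-band peak frequency (excluding any
    ``notch`` intervals ``(centre_hz, halfwidth_hz)``) is scaled to a
    per-minute rate.  Estimates are smoothed with a centred moving mean over
    ``smooth`` windows; windows with no in-band energy yield NaN (an
    estimation-failure flag) and stay NaN after smoothing.

    Returns ``(window_centre_times [s], rates [per min])``.
    """
    fs = phase.frame_rate
    if not 0 < band[0] < band[1] < fs / 2:
        raise ConfigurationError(f"band {band} invalid for frame rate {fs}")
    if window < 2.0 / band[0]:
        raise DomainError("window must cover >= 2 cycles of the band low edge")
    x = np.asarray(phase.values, dtype=float)
    win_n = int(round(window * fs))
    if win_n > x.size:
        raise DomainError("window longer than the recording")
    stride_n = max(1, int(round(stride * fs)))

    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    y = sosfiltfilt(sos, x - x.mean())

    nfft = max(win_n, int(math.ceil(fs * 60.0 / resolution_bpm)))
    taper = get_window("hann", win_n)
    starts = np.arange(0, x.size - win_n + 1, stride_n)
    rates = np.array(
        [
            _spectral_peak(y[s : s + win_n] * taper, fs, band, nfft, notch)
            for s in starts
        ]
    )
    times = (starts + win_n / 2.0) / fs
    if smooth > 1:
        smoothed = (
            pd.Series(rates)
            .rolling(smooth, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        smoothed[np.isnan(rates)] = math.nan
        rates = smoothed
    return times, rates


@dataclass(frozen=True)
class VitalsResult:
    """Per-window breathing and heart-rate estimates for one recording."""

    times: np.ndarray
    br: np.ndarray
    hr: np.ndarray
    beamformed: bool
    target_bin: int
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.br) == len(self.hr)):
            raise ConfigurationError("times/br/hr must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "br_bpm": self.br,
                "hr_bpm": self.hr,
                "mode": "beamformed" if self.beamformed else "single-channel",
            }
        )


def extract_vitals(
    slow: SlowTimeCube,
    *,
    beamform: bool = True,
    angle: float | None = None,
    channel: int = 0,
    br_band: tuple[float, float] = BR_BAND,
    hr_band: tuple[float, float] = HR_BAND,
    alpha: float = 0.95,
    window: float = 30.0,
    stride: float = 1.0,
    smooth: int = 5,
    notch_harmonics: tuple[int, ...] = (2, 3, 4),
    notch_halfwidth: float = 0.05,
) -> VitalsResult:
    """Run the full extraction chain on a slow-time cube.

    With ``beamform=True`` the channels are combined with delay-and-sum
    weights for ``angle`` (estimated from a beam scan when ``angle`` is
    ``None``); otherwise only virtual channel ``channel`` is used and the
    rest of the data is discarded.  The heart-band peak search notches the
    listed harmonics of the median breathing estimate to keep breathing
    harmonics from masquerading as the heartbeat.
    """
    if beamform:
        if angle is None:
            angle = estimate_aoa(beam_scan(slow))
        weights = steering_weights(angle, slow.n_channels)
        slice2d = apply_beamforming(slow, weights)
    else:
        slice2d = slow.channel(channel)
    # first filtered frame is identically zero by the background seeding
    filtered = clutter_filter(slice2d, alpha, axis=0)[1:]
    target_bin = select_target_bin(slice2d, alpha)
    phase = extract_phase(
        filtered, target_bin, slow.frame_rate, beamformed=beamform
    )
    times, br = bandpass_rates(
        phase, br_band, window, stride, smooth=smooth
    )
    notch = ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        br_hz = float(np.nanmedian(br)) / 60.0 if np.any(np.isfinite(br)) else math.nan
    if math.isfinite(br_hz):
        notch = tuple(
            (k * br_hz, notch_halfwidth)
            for k in notch_harmonics
            if hr_band[0] - notch_halfwidth < k * br_hz < hr_band[1] + notch_halfwidth
        )
    _, hr = bandpass_rates(
        phase, hr_band, window, stride, smooth=smooth, notch=notch
    )
    return VitalsResult(
        times=times,
        br=br,
        hr=hr,
        beamformed=beamform,
        target_bin=target_bin,
        angle_deg=None if not beamform else float(angle),
    )
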