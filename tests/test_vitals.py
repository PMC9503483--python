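import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarvitals import (
    BR_BAND,
    HR_BAND,
    ChestMotion,
    ConfigurationError,
    DetectionError,
    DomainError,
    PhaseSeries,
    bandpass_rates,
    clutter_filter,
    extract_phase,
    extract_vitals,
    make_scene,
    select_target_bin,
    simulate_recording,
    slow_time_cube,
)
from radarvitals.evaluate import _finite_mae, default_motion_ensemble


def unrolled_clutter_oracle(x, alpha):
    """Literal recursion: b_k = a*b_{k-1} + (1-a)*x_k, y_k = x_k - b_k,
    with the background seeded by the first sample (b_0 = x_0)."""
    x = np.asarray(x)
    b = x[0]
    out = np.empty_like(x)
    out[0] = 0.0
    for k in range(1, len(x)):
        b = alpha * b + (1 - alpha) * x[k]
        out[k] = x[k] - b
    return out


def unwrap_oracle(raw):
    """Literal unwrap: add +/-2*pi until successive jumps are <= pi."""
    out = [raw[0]]
    for v in raw[1:]:
        prev = out[-1]
        while v - prev > np.pi:
            v -= 2 * np.pi
        while v - prev < -np.pi:
            v += 2 * np.pi
        out.append(v)
    return np.array(out)


class TestClutterFilter:
    def test_matches_unrolled_recursion(self, rng):
        x = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        got = clutter_filter(x, alpha=0.9)
        np.testing.assert_allclose(got, unrolled_clutter_oracle(x, 0.9), atol=1e-10)

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_any_alpha(self, alpha):
        x = np.linspace(-1, 1, 50) + 0.5j
        np.testing.assert_allclose(
            clutter_filter(x, alpha), unrolled_clutter_oracle(x, alpha), atol=1e-10
        )

    def test_static_input_cancelled_exactly(self):
        c = 3.0 - 1.0j
        y = clutter_filter(np.full(60, c), 0.8)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_step_decays_geometrically(self):
        # a step from the seeded background decays at rate alpha:
        # |y_k| <= alpha**k * |c - b_0| with b_0 = x_0 = 0
        c = 3.0 - 1.0j
        alpha = 0.8
        x = np.full(60, c)
        x[0] = 0.0
        y = clutter_filter(x, alpha)
        k = np.arange(60)
        assert np.all(np.abs(y) <= alpha**k * np.abs(c) + 1e-12)
        assert np.abs(y[-1]) < 1e-5

    def test_zero_input(self):
        assert np.all(clutter_filter(np.zeros(10), 0.95) == 0)

    def test_sinusoid_attenuation_matches_transfer_function(self):
        # |H(w)| of alpha*(1-z^-1)/(1-alpha*z^-1) at 0.25 Hz, 20 Hz rate
        alpha, fs, f0 = 0.95, 20.0, 0.25
        n = np.arange(40000)
        x = np.exp(2j * np.pi * f0 * n / fs)
        y = clutter_filter(x, alpha)
        steady = np.abs(y[-1000:]).mean()
        z = np.exp(-2j * np.pi * f0 / fs)
        expected = np.abs(alpha * (1 - z) / (1 - alpha * z))
        assert steady == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ConfigurationError):
            clutter_filter(np.zeros(4), alpha)


class TestSelectTargetBin:
    def test_breathing_target_beats_static_clutter(self, small_config):
        scene = make_scene(1.2, 0.0, clutter=[(0.5, 2.0)])
        slow = slow_time_cube(simulate_recording(small_config, scene, 10.0, 0))
        series = slow.channel(0)
        chosen = select_target_bin(series)
        # exhaustive variance-scan oracle
        filtered = clutter_filter(series, 0.95, axis=0)
        oracle = int(np.var(np.abs(filtered), axis=0).argmax())
        assert chosen == oracle == 31

    def test_single_oscillating_bin(self):
        series = np.zeros((50, 8), dtype=complex)
        series[:, 5] = np.exp(1j * np.linspace(0, 3, 50))
        assert select_target_bin(series) == 5

    def test_tie_breaks_to_smaller_bin(self):
        series = np.zeros((50, 25), dtype=complex)
        wave = np.exp(1j * np.linspace(0, 3, 50))
        series[:, 10] = wave
        series[:, 20] = wave
        assert select_target_bin(series) == 10

    def test_degenerate_input_rejected(self):
        with pytest.raises(DetectionError):
            select_target_bin(np.ones((30, 6), dtype=complex))


class TestExtractPhase:
    def test_wrapping_ramp_unwraps_monotone(self):
        true_phase = np.linspace(0, 20, 200)
        series = np.exp(1j * true_phase)[:, None]
        ps = extract_phase(series, 0, 20.0)
        assert np.all(np.diff(ps.values) > 0)
        np.testing.assert_allclose(ps.values, true_phase, atol=1e-9)

    def test_matches_unwrap_oracle(self, rng):
        raw = rng.uniform(-np.pi, np.pi, 100)
        series = np.exp(1j * raw)[:, None]
        ps = extract_phase(series, 0, 10.0)
        np.testing.assert_allclose(ps.values, unwrap_oracle(raw), atol=1e-10)

    def test_static_target_constant_phase(self, small_config):
        scene = make_scene(1.2, 0.0, sigma=0.0, clutter=[(1.2, 1.0)])
        slow = slow_time_cube(simulate_recording(small_config, scene, 1.0, 0))
        ps = extract_phase(slow.channel(0), 31, slow.frame_rate)
        assert np.ptp(ps.values) < 1e-10

    def test_peak_to_peak_phase_matches_displacement(self, small_config):
        # phi = 4*pi*x/lambda -> ptp = 8*pi*a_br/lambda ~ 10.05 rad
        motion = ChestMotion(f_br=0.25, a_br=2e-3, a_hr=0.0)
        scene = make_scene(1.2, 0.0, motion=motion)
        slow = slow_time_cube(simulate_recording(small_config, scene, 8.0, 0))
        ps = extract_phase(slow.channel(0), 31, slow.frame_rate)
        expected = 8 * np.pi * motion.a_br / small_config.wavelength
        assert expected == pytest.approx(10.053, abs=1e-2)
        # the fast-time window references the bin phase to the window
        # centre, adding a small displacement-proportional group-delay
        # term on top of 4*pi*x/lambda; allow a few percent for it
        assert np.ptp(ps.values) == pytest.approx(expected, rel=0.04)

    def test_zero_magnitude_holds_previous(self):
        series = np.exp(1j * np.linspace(0, 1, 10))[:, None].astype(complex)
        series[4, 0] = 0.0
        with pytest.warns(UserWarning, match="zero-magnitude"):
            ps = extract_phase(series, 0, 10.0)
        assert ps.values[4] == ps.values[3]

    def test_bad_bin_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_phase(np.ones((5, 3), dtype=complex), 3, 10.0)


class TestBandpassRates:
    def make_phase(self, freq, fs=20.0, duration=60.0, amp=1.0):
        t = np.arange(int(duration * fs)) / fs
        return PhaseSeries(
            values=amp * np.sin(2 * np.pi * freq * t),
            frame_rate=fs,
            source_bin=0,
        )

    def test_pure_breathing_tone(self):
        times, rates = bandpass_rates(self.make_phase(0.25), BR_BAND)
        assert np.all(np.isfinite(rates))
        np.testing.assert_allclose(rates, 15.0, atol=0.25)

    def test_pure_heart_tone(self):
        _, rates = bandpass_rates(self.make_phase(1.25), HR_BAND)
        np.testing.assert_allclose(rates, 75.0, atol=0.25)

    def test_silence_flags_failure(self):
        phase = PhaseSeries(np.zeros(1200), 20.0, 0)
        _, rates = bandpass_rates(phase, HR_BAND)
        assert np.all(np.isnan(rates))

    def test_window_longer_than_recording_rejected(self):
        phase = PhaseSeries(np.zeros(100), 20.0, 0)
        with pytest.raises(DomainError):
            bandpass_rates(phase, BR_BAND, window=30.0)

    def test_window_must_cover_two_cycles(self):
        with pytest.raises(DomainError):
            bandpass_rates(self.make_phase(0.25), BR_BAND, window=10.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass_rates(self.make_phase(0.25), (0.5, 0.1))

    def test_notch_excludes_harmonic(self):
        # tone at 1.0 Hz vanishes when notched, leaving the 1.5 Hz tone
        fs = 20.0
        t = np.arange(1200) / fs
        phase = PhaseSeries(
            0.2 * np.sin(2 * np.pi * 1.0 * t) + 1.5 * np.sin(2 * np.pi * 1.5 * t),
            fs,
            0,
        )
        _, rates = bandpass_rates(phase, HR_BAND, notch=((1.0, 0.05),))
        np.testing.assert_allclose(rates, 90.0, atol=0.25)

    def test_strong_peak_overrides_notch(self):
        # a dominant tone inside the notch is kept (true heartbeat on a
        # breathing harmonic)
        _, rates = bandpass_rates(
            self.make_phase(1.0, amp=2.0), HR_BAND, notch=((1.0, 0.05),)
        )
        np.testing.assert_allclose(rates, 60.0, atol=0.25)

    def test_moving_mean_keeps_constant_series(self):
        _, r5 = bandpass_rates(self.make_phase(1.25), HR_BAND, smooth=5)
        _, r1 = bandpass_rates(self.make_phase(1.25), HR_BAND, smooth=1)
        np.testing.assert_allclose(r5, r1, atol=0.25)


class TestEndToEnd:
    @pytest.mark.parametrize("br", [12.0, 15.0, 18.0])
    @pytest.mark.parametrize("hr", [60.0, 75.0, 90.0])
    def test_parameter_recovery_noiseless(self, small_config, br, hr):
        motion = ChestMotion(f_br=br / 60, f_hr=hr / 60, phi_br=0.4, phi_hr=1.1)
        scene = make_scene(1.2, 20.0, motion=motion)
        slow = slow_time_cube(simulate_recording(small_config, scene, 60.0, 0))
        for beamform in (True, False):
            res = extract_vitals(
                slow, beamform=beamform, angle=20.0 if beamform else None
            )
            br_mae, n_br = _finite_mae(res.br, br)
            hr_mae, n_hr = _finite_mae(res.hr, hr)
            assert n_br == len(res.br) and n_hr == len(res.hr)
            assert br_mae <= 1.0
            assert hr_mae <= 2.0

    def test_noiseless_arms_identical(self, small_config):
        # matched-angle beamforming only rotates/scales the noiseless
        # signal, so both arms recover the identical rate series
        scene = make_scene(1.5, 40.0, seed=3)
        slow = slow_time_cube(simulate_recording(small_config, scene, 45.0, 3))
        with_bf = extract_vitals(slow, beamform=True, angle=40.0)
        without = extract_vitals(slow, beamform=False)
        np.testing.assert_allclose(with_bf.br, without.br, atol=1e-9)
        np.testing.assert_allclose(with_bf.hr, without.hr, atol=1e-9)

    def test_clutter_does_not_break_recovery(self, small_config):
        scene = make_scene(1.2, 0.0, clutter=[(0.5, 2.0), (1.9, 1.0)])
        slow = slow_time_cube(simulate_recording(small_config, scene, 60.0, 0))
        res = extract_vitals(slow, beamform=True, angle=0.0)
        assert res.target_bin == 31
        assert _finite_mae(res.br, scene.motion.br_bpm)[0] <= 1.0
        assert _finite_mae(res.hr, scene.motion.hr_bpm)[0] <= 2.0


@pytest.mark.slow
class TestNoiseProperties:
    def test_monotone_degradation(self, small_config):
        # median single-channel HR error over 30 seeds is non-decreasing in
        # noise (up to one spectral grid step of slack) on a 5-point ladder;
        # the ladder stays below the saturation regime where estimates are
        # uniform in-band guesses and medians wander
        ladder = [0.0, 2.0, 4.0, 6.0, 9.0]
        motions = default_motion_ensemble(30)
        medians = []
        for noise in ladder:
            errors = []
            for seed in range(30):
                motion = motions[seed]
                scene = make_scene(1.2, 40.0, motion=motion,
                                   noise_std=noise, seed=seed)
                slow = slow_time_cube(
                    simulate_recording(small_config, scene, 40.0, seed)
                )
                res = extract_vitals(slow, beamform=False)
                errors.append(_finite_mae(res.hr, motion.hr_bpm)[0])
            medians.append(float(np.nanmedian(errors)))
        assert np.all(np.diff(medians) >= -0.25), medians
        assert medians[-1] > medians[0]

    def test_beamforming_benefit_at_side_angles(self, small_config):
        # reduced-size analogue of the acceptance property
        noise = 12.0
        motions = default_motion_ensemble(12)
        med = {}
        for angle in (20.0, 40.0):
            errs = {"with": [], "without": []}
            for seed in range(12):
                motion = motions[seed]
                scene = make_scene(1.2, angle, motion=motion,
                                   noise_std=noise, seed=seed)
                slow = slow_time_cube(
                    simulate_recording(small_config, scene, 40.0, seed)
                )
                for arm, bf in (("with", True), ("without", False)):
                    res = extract_vitals(
                        slow, beamform=bf, angle=angle if bf else None
                    )
                    errs[arm].append(_finite_mae(res.hr, motion.hr_bpm)[0])
            med[angle] = {k: float(np.nanmedian(v)) for k, v in errs.items()}
        for angle in (20.0, 40.0):
            assert med[angle]["with"] < med[angle]["without"], med
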