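import numpy as np
import pytest
from scipy import signal as sps

from stimgait.preprocessing import (
    EnvelopeSpec,
    ParameterError,
    StimulationSpec,
    bandpass,
    comb_response,
    design_harmonic_comb,
    envelope,
    median_smooth,
    notch,
    preprocess,
    remove_stim_artifact,
)
from stimgait.simulate import generate_recording

from conftest import FS, quiet_config, single_channel_recording, tian


def mid_amplitude(rec):
    """Peak amplitude of the middle 50% (away from filtfilt edge effects)."""
    x = rec.signal[0]
    n = x.size
    return np.abs(x[n // 4 : 3 * n // 4]).max()


def butter_bandpass_gain(f, low, high, order=2):
    """Analog Butterworth band-pass magnitude, squared for zero-phase."""
    w = (f**2 - low * high) / (f * (high - low))
    return (1.0 / np.sqrt(1.0 + w ** (2 * order))) ** 2


class TestBandpass:
    def test_passband_center_preserved(self, sine_recording):
        # 100 Hz = geometric center of 20-500: analog gain exactly 1
        out = bandpass(sine_recording(100.0))
        assert mid_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self, sine_recording):
        # closed form: |H(5)|^2 (zero-phase) = 0.0033 << 0.1
        out = bandpass(sine_recording(5.0))
        assert mid_amplitude(out) < 0.1
        assert mid_amplitude(out) == pytest.approx(
            butter_bandpass_gain(5.0, 20.0, 500.0), rel=0.5
        )

    def test_zero_signal(self):
        out = bandpass(single_channel_recording(np.zeros(4096)))
        assert np.all(out.signal == 0.0)

    def test_bad_edges_raise(self, sine_recording):
        rec = sine_recording(100.0)
        with pytest.raises(ParameterError):
            bandpass(rec, 500.0, 20.0)
        with pytest.raises(ParameterError):
            bandpass(rec, 20.0, 2000.0)


class TestNotch:
    def test_line_frequency_removed(self, sine_recording):
        rec = sine_recording(50.0)
        out = notch(rec, 50.0)
        n = rec.n_samples
        sl = slice(n // 4, 3 * n // 4)
        ratio = np.sqrt(np.mean(out.signal[0, sl] ** 2)) / np.sqrt(
            np.mean(rec.signal[0, sl] ** 2)
        )
        assert ratio <= 0.01

    def test_neighboring_frequency_preserved(self, sine_recording):
        out = notch(sine_recording(100.0), 50.0)
        assert mid_amplitude(out) == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        out = notch(single_channel_recording(np.zeros(4096)))
        assert np.all(out.signal == 0.0)

    def test_out_of_range_raises(self, sine_recording):
        with pytest.raises(ParameterError):
            notch(sine_recording(50.0), 2000.0)


class TestCombDesign:
    def test_zeros_exactly_at_harmonics(self):
        sos = design_harmonic_comb(StimulationSpec(), FS)
        h = comb_response(sos, [30.0, 60.0, 90.0, 300.0], FS)
        assert np.all(h < 1e-10)

    def test_interharmonic_gain_with_spec_radius(self):
        # mid-harmonic gain stays near 1 even at the much wider r = 0.985
        sos = design_harmonic_comb(StimulationSpec(pole_radius=0.985), FS)
        assert comb_response(sos, [45.0], FS)[0] >= 0.95

    def test_midpoint_normalization(self):
        sos = design_harmonic_comb(StimulationSpec(), FS)
        mids = 30.0 * (np.arange(1, 34) + 0.5)
        h = comb_response(sos, mids, FS)
        assert np.all(np.abs(h - 1.0) <= 0.05)

    def test_stability_pole_radius(self):
        spec = StimulationSpec()
        sos = design_harmonic_comb(spec, FS)
        _, poles, _ = sps.sos2zpk(sos)
        assert np.abs(poles).max() == pytest.approx(spec.pole_radius, abs=1e-9)

    def test_design_error_when_no_harmonic_fits(self):
        with pytest.raises(ParameterError):
            design_harmonic_comb(StimulationSpec(stim_freq_hz=600.0), 1000.0)


@pytest.fixture(scope="module")
def pulse_only():
    # ON block contains only the biphasic pulse train
    cfg = quiet_config(
        duration_s=60.0,
        muscles=[tian(amplitude=0.0)],
        stim_amplitude=4.0,
        blocks=("OFF-PRE", "ON", "OFF-POST"),
        rng_seed=1,
    )
    rec, _ = generate_recording(cfg)
    return notch(bandpass(rec), 50.0)


class TestRemoveStimArtifact:

    def test_harmonic_bands_attenuated_30db(self, pulse_only):
        after = remove_stim_artifact(pulse_only, StimulationSpec())
        b = pulse_only.block("ON")
        trim = int(4 * FS)  # keep clear of filtfilt edge transients
        sl = slice(b.start + trim, b.end - trim)
        for f0 in (30.0, 60.0, 90.0):
            f, P0 = sps.periodogram(pulse_only.signal[0, sl], FS)
            _, P1 = sps.periodogram(after.signal[0, sl], FS)
            band = (f >= f0 - 0.5) & (f <= f0 + 0.5)
            assert 10 * np.log10(P0[band].sum() / P1[band].sum()) >= 30.0

    def test_off_blocks_untouched(self, pulse_only):
        after = remove_stim_artifact(pulse_only, StimulationSpec())
        for label in ("OFF-PRE", "OFF-POST"):
            b = pulse_only.block(label)
            np.testing.assert_array_equal(
                after.signal[:, b.start : b.end], pulse_only.signal[:, b.start : b.end]
            )

    def test_burst_envelope_preserved(self):
        # artifact-free channel: comb must not distort the burst envelope
        cfg = quiet_config(duration_s=60.0, background_noise_sd=0.05, rng_seed=3)
        rec, _ = generate_recording(cfg)
        filtered = notch(bandpass(rec), 50.0)
        spec = StimulationSpec(apply_to=frozenset({"OFF-PRE", "ON", "OFF-POST"}))
        after = remove_stim_artifact(filtered, spec)
        e0 = envelope(filtered).signal[0]
        e1 = envelope(after).signal[0]
        assert np.corrcoef(e0, e1)[0, 1] >= 0.99

    def test_interharmonic_power_preserved(self):
        cfg = quiet_config(duration_s=60.0, background_noise_sd=0.1, rng_seed=4)
        rec, _ = generate_recording(cfg)
        filtered = notch(bandpass(rec), 50.0)
        spec = StimulationSpec(apply_to=frozenset({"OFF-PRE", "ON", "OFF-POST"}))
        after = remove_stim_artifact(filtered, spec)
        f, P0 = sps.periodogram(filtered.signal[0], FS)
        _, P1 = sps.periodogram(after.signal[0], FS)
        sel = (
            (f >= 35) & (f <= 55)
            & ~((f >= 49) & (f <= 51))
            & ~((f >= 44.5) & (f <= 45.5))  # notch + comb-zero neighborhoods
        )
        loss = 1.0 - P1[sel].sum() / P0[sel].sum()
        assert loss <= 0.10


class TestMedianSmooth:
    def test_constant_signal_unchanged(self):
        out = median_smooth(single_channel_recording(np.full(2048, 3.7)))
        np.testing.assert_allclose(out.signal[0], 3.7)

    def test_isolated_spike_removed(self):
        x = np.zeros(2048)
        x[1000] = 100.0
        out = median_smooth(single_channel_recording(x))
        assert np.all(out.signal == 0.0)

    def test_monotone_ramp_matches_brute_force(self):
        x = np.linspace(0.0, 1.0, 300)
        rec = single_channel_recording(x, fs=300.0)
        out = median_smooth(rec, window_s=7 / 300.0)
        w = 7
        brute = np.array(
            [
                np.median(x[max(0, i - w // 2) : i + w // 2 + 1])
                if w // 2 <= i < x.size - w // 2
                else x[i]
                for i in range(x.size)
            ]
        )
        # interior equals the brute-force running median (== the ramp itself)
        np.testing.assert_allclose(out.signal[0][3:-3], brute[3:-3])

    def test_window_too_short_raises(self):
        with pytest.raises(ParameterError):
            median_smooth(single_channel_recording(np.zeros(100), fs=10.0), window_s=0.05)


class TestEnvelope:
    def test_constant_passes_dc(self):
        out = envelope(single_channel_recording(np.full(int(20 * FS), 2.0)))
        mid = out.signal[0][out.n_samples // 4 : 3 * out.n_samples // 4]
        np.testing.assert_allclose(mid, 2.0, rtol=0.01)

    def test_sinusoid_rectified_mean(self, sine_recording):
        # mean of |A sin| = 2A/pi; the 1 Hz low-pass keeps just that DC level
        out = envelope(sine_recording(80.0, amplitude=1.5, duration_s=20.0))
        mid = out.signal[0][out.n_samples // 4 : 3 * out.n_samples // 4]
        assert np.median(mid) == pytest.approx(2 * 1.5 / np.pi, rel=0.05)

    def test_zero_signal(self):
        out = envelope(single_channel_recording(np.zeros(4096)))
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_cadence_adjustment_rule(self):
        spec = EnvelopeSpec(cutoff_hz=1.0, cadence_hz=0.22)
        assert spec.effective_cutoff() == 1.0
        spec = EnvelopeSpec(cutoff_hz=1.0, cadence_hz=2.0)
        assert spec.effective_cutoff() == 2.0

    def test_bad_cutoff_raises(self):
        rec = single_channel_recording(np.zeros(1000), fs=100.0)
        with pytest.raises(ParameterError):
            envelope(rec, EnvelopeSpec(cutoff_hz=80.0))


class TestChainProperties:
    def test_linear_stages_scale_with_input(self, sine_recording):
        rec = sine_recording(35.0)
        scaled = single_channel_recording(2.5 * rec.signal[0])
        for stage in (
            lambda r: bandpass(r),
            lambda r: notch(r),
            lambda r: remove_stim_artifact(r, StimulationSpec(apply_to=frozenset({"OFF-PRE"}))),
        ):
            np.testing.assert_allclose(
                stage(scaled).signal, 2.5 * stage(rec).signal, atol=1e-9
            )
        # median and rectification are positively homogeneous
        np.testing.assert_allclose(
            median_smooth(scaled).signal, 2.5 * median_smooth(rec).signal, atol=1e-9
        )
        np.testing.assert_allclose(
            envelope(scaled).signal, 2.5 * envelope(rec).signal, atol=1e-9
        )

    def test_zero_phase_no_lag(self):
        # a burst must not shift through any linear stage
        rng = np.random.default_rng(0)
        n = int(8 * FS)
        x = rng.standard_normal(n)
        sos = sps.butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        x = sps.sosfiltfilt(sos, x)
        burst = np.zeros(n)
        c = n // 2
        burst[c - 1024 : c + 1024] = np.hanning(2048)
        rec = single_channel_recording(x * burst)
        for stage in (bandpass, notch):
            out = stage(rec)
            xc = sps.correlate(np.abs(out.signal[0]), np.abs(rec.signal[0]), mode="full")
            lag = np.argmax(
                sps.correlate(out.signal[0], rec.signal[0], mode="full")
            ) - (n - 1)
            assert abs(lag) == 0, f"{stage.__name__} lags by {lag} samples ({xc.argmax()})"

    def test_processing_log_order(self):
        cfg = quiet_config(duration_s=20.0, background_noise_sd=0.05, rng_seed=9)
        rec, _ = generate_recording(cfg)
        res = preprocess(rec, stim=StimulationSpec())
        stages = [s.split("(")[0] for s in res.envelopes.processing_log]
        assert stages == ["simulated", "bandpass", "notch", "comb", "median", "envelope"]

    def test_rerun_reproduces_bit_identically(self):
        cfg = quiet_config(duration_s=20.0, background_noise_sd=0.05, rng_seed=10)
        rec, _ = generate_recording(cfg)
        a = preprocess(rec, stim=StimulationSpec())
        b = preprocess(rec, stim=StimulationSpec())
        np.testing.assert_array_equal(a.filtered.signal, b.filtered.signal)
        np.testing.assert_array_equal(a.envelopes.signal, b.envelopes.signal)
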