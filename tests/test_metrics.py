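"""Stream analysis: demux, filtering, spike sorting, SNR, noise, linearity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from muxrec import (
    FrontEndConfig,
    MuxTiming,
    SampleStream,
    SortedEvents,
    adc_histogram_linearity,
    adc_quantize,
    bandpass,
    demultiplex,
    detect_and_sort,
    input_referred_noise,
    nef,
    noise_floor,
    simulate_acquisition,
    snr_waveforms,
    thd_fft,
)
from muxrec.scene import SceneConfig, SpikeTemplate, generate_scene

from conftest import dc_scene


def make_stream(codes, M=2, config=None):
    config = config or FrontEndConfig()
    timing = MuxTiming(M=M, fch=30e3)
    return SampleStream(
        codes=np.asarray(codes, np.uint16), timing=timing,
        channel_map=np.arange(M), config=config,
        metadata={"passband_gain": 1000.0},
    )


class TestDemultiplex:
    def test_two_channel_deinterleave(self):
        stream = make_stream([300, 200] * 10)
        volts, fch = demultiplex(stream)
        lsb_in = stream.config.adc_lsb / 1000.0
        np.testing.assert_allclose(volts[0], (300 - 256) * lsb_in)
        np.testing.assert_allclose(volts[1], (200 - 256) * lsb_in)
        assert fch == 30e3

    def test_downsample_one_is_identity(self):
        stream = make_stream([300, 200] * 10)
        a, _ = demultiplex(stream, downsample=1)
        b, _ = demultiplex(stream)
        np.testing.assert_array_equal(a, b)

    def test_downsample_drops_samples(self):
        stream = make_stream(np.arange(40) % 512)
        volts, fch = demultiplex(stream, downsample=2)
        assert volts.shape[1] == 10
        assert fch == 15e3

    def test_sinusoid_round_trip_amplitude(self):
        # a 2 kHz tone rendered as a long 'template' survives the full
        # simulate -> demultiplex path with < 1 LSB amplitude error
        class SineTemplate(SpikeTemplate):
            def waveform(self, rate):
                n = int(round(self.duration * rate))
                t = np.arange(n) / rate
                return self.amplitude * np.sin(2 * np.pi * 2000.0 * t)

        amp = 200e-6
        cfg = SceneConfig(
            n_electrodes=1, offset_range=(-1e-12, 1e-12), spike_rate=0.0,
            background_noise_rms=0.0, electrode_model=None,
            templates=(SineTemplate(amplitude=amp, duration=0.2),))
        scene = generate_scene(cfg, 1)
        scene.spike_trains[0] = np.array([0.0])
        timing = MuxTiming(M=1, fch=30e3)
        stream = simulate_acquisition(
            scene, timing, FrontEndConfig(), duration=0.2, seed=0,
            lna_noise=False, mux_noise=False)
        volts, fch = demultiplex(stream)
        x = volts[0] - volts[0].mean()
        t = np.arange(x.size) / fch
        meas = 2 * abs(np.mean(x * np.exp(-2j * np.pi * 2000.0 * t)))
        assert abs(meas - amp) < stream.config.adc_lsb / 1000.0


class TestBandpass:
    def test_dc_fully_rejected(self):
        out = bandpass(np.ones(3000), fs=30e3)
        assert np.max(np.abs(out)) < 1e-9

    def test_in_band_tone_preserved(self):
        fs, f0 = 30e3, 2000.0
        t = np.arange(6000) / fs
        out = bandpass(np.sin(2 * np.pi * f0 * t), fs)
        mid = out[1000:-1000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated_20db(self):
        fs, f0 = 30e3, 10e3
        t = np.arange(6000) / fs
        out = bandpass(np.sin(2 * np.pi * f0 * t), fs)
        assert np.max(np.abs(out[1000:-1000])) < 0.1

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), fs=30e3, lo=4000, hi=800)


def insert_template(n, fs, times, tmpl):
    x = np.zeros(n)
    for t_ev in times:
        i = int(round(t_ev * fs))
        x[i: i + tmpl.size] += tmpl[: max(n - i, 0)][: tmpl.size]
    return x


class TestDetectAndSort:
    FS = 30e3

    def template(self):
        return SpikeTemplate(amplitude=100e-6).waveform(self.FS)

    def test_clean_repeats_all_detected_mean_matches(self):
        tmpl = self.template()
        times = np.arange(20) * 10e-3 + 5e-3
        x = insert_template(int(0.3 * self.FS), self.FS, times, tmpl)
        events = detect_and_sort(x, self.FS, threshold=-50e-6)
        assert events.snippets.shape[0] == 20
        trough = events.mean_waveform.min()
        assert trough == pytest.approx(tmpl.min(), rel=1e-6)

    def test_hoop_excluding_second_phase_rejects_all(self):
        tmpl = self.template()
        times = np.arange(10) * 10e-3 + 5e-3
        x = insert_template(int(0.2 * self.FS), self.FS, times, tmpl)
        # the rebound peaks ~45 uV; demand it stay below 10 uV
        hoops = [(0.5e-3, -10e-6, 10e-6)]
        events = detect_and_sort(x, self.FS, threshold=-50e-6, hoops=hoops)
        assert events.snippets.shape[0] == 0

    def test_refractory_lockout_merges_doublets(self):
        tmpl = self.template()
        x = insert_template(int(0.1 * self.FS), self.FS, [10e-3, 10.4e-3], tmpl)
        events = detect_and_sort(x, self.FS, threshold=-50e-6, refractory=1e-3)
        assert events.snippets.shape[0] == 1

    def test_seeded_scene_count_within_5pct(self):
        rng = np.random.default_rng(77)
        fs, dur, rate = 30e3, 20.0, 10.0
        n = int(dur * fs)
        n_true = rng.poisson(rate * dur)
        times = np.sort(rng.uniform(0, dur - 2e-3, n_true))
        tmpl = SpikeTemplate(amplitude=120e-6).waveform(fs)
        x = insert_template(n, fs, times, tmpl)
        x += rng.standard_normal(n) * 15e-6
        xb = bandpass(x, fs)
        noise_rms = np.sqrt(np.mean(bandpass(
            rng.standard_normal(n) * 15e-6, fs) ** 2))
        events = detect_and_sort(xb, fs, threshold=-6.5 * noise_rms)
        assert abs(events.snippets.shape[0] - n_true) <= 0.05 * n_true


class TestSnrWaveforms:
    @staticmethod
    def synthetic_events(ptp=100e-6, sd=50e-6):
        base = np.array([0.0, -0.6, 0.4, 0.0]) * ptp / 1.0
        snips = np.vstack([base + sd, base - sd])
        mean = snips.mean(axis=0)
        dev = snips - mean
        return SortedEvents(
            crossing_times=np.array([0.01, 0.02]), snippets=snips,
            mean_waveform=mean, deviations=dev, sd_eps=float(dev.std()),
            threshold=-50e-6, hoop_windows=(), window=(0.4e-3, 1.0e-3),
            sample_rate=30e3)

    def test_arithmetic_reference(self):
        ev = self.synthetic_events()
        assert snr_waveforms(ev) == pytest.approx(2.0, rel=1e-9)

    def test_identical_snippets_flag_infinite(self):
        ev = self.synthetic_events(sd=0.0)
        assert math.isinf(snr_waveforms(ev))

    def test_gain_invariance(self):
        ev = self.synthetic_events()
        scaled = self.synthetic_events(ptp=100e-6 * 7, sd=50e-6 * 7)
        assert snr_waveforms(scaled) == pytest.approx(snr_waveforms(ev))

    def test_amplitude_doubling_doubles_snr(self):
        # snippets cut at the ground-truth event times (alignment held
        # fixed) so the only change between runs is the template scale
        rng = np.random.default_rng(5)
        fs = 30e3
        tmpl1 = SpikeTemplate(amplitude=100e-6).waveform(fs)
        noise = rng.standard_normal(int(2.0 * fs)) * 8e-6
        times = np.arange(100) * 20e-3 + 3e-3
        snrs = []
        for k in (1, 2):
            x = insert_template(noise.size, fs, times, k * tmpl1) + noise
            snips = np.vstack([
                x[int(round(t * fs)) - 12: int(round(t * fs)) + 31]
                for t in times])
            mean = snips.mean(axis=0)
            dev = snips - mean
            ev = SortedEvents(
                crossing_times=times, snippets=snips, mean_waveform=mean,
                deviations=dev, sd_eps=float(dev.std()), threshold=-50e-6 * k,
                hoop_windows=(), window=(0.4e-3, 1.0e-3), sample_rate=fs)
            snrs.append(snr_waveforms(ev))
        assert snrs[1] / snrs[0] == pytest.approx(2.0, rel=0.10)


class TestNoiseFloor:
    def test_no_events_plain_rms(self):
        x = np.array([3e-6, -4e-6] * 50)
        assert noise_floor(x, 30e3) == pytest.approx(np.sqrt(12.5e-12))

    def test_known_rms_recovered(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(60000) * 8e-6
        assert noise_floor(x, 30e3) == pytest.approx(8e-6, rel=0.05)

    def test_excising_spikes_recovers_background(self):
        rng = np.random.default_rng(9)
        fs = 30e3
        noise = rng.standard_normal(int(4.0 * fs)) * 8e-6
        tmpl = SpikeTemplate(amplitude=150e-6).waveform(fs)
        times = np.arange(150) * 25e-3 + 4e-3
        x = insert_template(noise.size, fs, times, tmpl) + noise
        events = detect_and_sort(x, fs, threshold=-70e-6)
        assert events.snippets.shape[0] > 100
        nf = noise_floor(x, fs, events)
        assert nf == pytest.approx(np.sqrt(np.mean(noise ** 2)), rel=0.05)


class TestInputReferredNoise:
    def test_quantization_floor_when_all_sources_off(
            self, config, timing20, grounded_scene):
        stream = simulate_acquisition(grounded_scene, timing20, config,
                                      duration=0.02, seed=0,
                                      lna_noise=False, mux_noise=False)
        v_rms, _ = input_referred_noise(stream)
        assert v_rms <= config.adc_lsb / 1000.0 / math.sqrt(12)

    def test_lna_density_gives_5uv(self, config, timing20, grounded_scene):
        # 8.7 nV/rtHz over the 333 kHz WIS NEB -> ~5.0 uV rms
        stream = simulate_acquisition(grounded_scene, timing20, config,
                                      duration=0.05, seed=1, mux_noise=False)
        v_rms, spectra = input_referred_noise(stream)
        assert v_rms == pytest.approx(
            8.7e-9 * math.sqrt(1 / (2 * 1.5e-6)), rel=0.10)
        assert set(spectra) == {"fs", "fch"}

    def test_thermal_noise_adds_in_quadrature(self, config, timing20):
        cfg_scene = SceneConfig(
            n_electrodes=20, offset_range=(-1e-12, 1e-12), spike_rate=0.0,
            background_noise_rms=0.0)
        scene = generate_scene(cfg_scene, 4)
        quiet = simulate_acquisition(
            scene, timing20, config, duration=0.05, seed=2, mux_noise=False,
            include=("offset",))
        loud = simulate_acquisition(
            scene, timing20, config, duration=0.05, seed=2, mux_noise=False,
            include=("offset", "thermal"))
        v_quiet, _ = input_referred_noise(quiet)
        v_loud, _ = input_referred_noise(loud)
        # thermal-only rms from a separate electronics-noise-free run
        therm = simulate_acquisition(
            scene, timing20, config, duration=0.05, seed=2, mux_noise=False,
            lna_noise=False, include=("offset", "thermal"))
        v_th, _ = input_referred_noise(therm)
        assert v_loud == pytest.approx(
            math.sqrt(v_quiet ** 2 + v_th ** 2), rel=0.10)


class TestNef:
    def test_scaling_in_vrms_and_current(self):
        base = nef(5e-6, 7e-6, 15e3)
        assert nef(10e-6, 7e-6, 15e3) == pytest.approx(2 * base)
        assert nef(5e-6, 28e-6, 15e3) == pytest.approx(2 * base)

    def test_reference_range(self):
        assert 4.5 < nef(5.6e-6, 7e-6, 15e3) < 4.9

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            nef(-1e-6, 7e-6, 15e3)


class TestThdFft:
    FS = 600e3

    def tone(self, n=60000, a=1.0, f0=1e3):
        t = np.arange(n) / self.FS
        return a * np.sin(2 * np.pi * f0 * t)

    def test_pure_sine_near_zero(self):
        assert thd_fft(self.tone(), self.FS, 1e3) < 1e-4

    def test_quadratic_nonlinearity_half_percent(self):
        x = self.tone()
        y = x + 0.01 * x ** 2
        assert thd_fft(y, self.FS, 1e3) == pytest.approx(0.005, rel=0.05)

    def test_clipped_sine_matches_time_domain_oracle(self):
        x = np.clip(self.tone(), -0.9, 0.9)
        t = np.arange(x.size) / self.FS
        # lock-in extraction of the fundamental; residual power is the
        # distortion (noise-free construction)
        c = 2 * np.mean(x * np.sin(2 * np.pi * 1e3 * t))
        s = 2 * np.mean(x * np.cos(2 * np.pi * 1e3 * t))
        fund = c * np.sin(2 * np.pi * 1e3 * t) + s * np.cos(2 * np.pi * 1e3 * t)
        oracle = math.sqrt(np.mean((x - fund) ** 2) / np.mean(fund ** 2))
        assert thd_fft(x, self.FS, 1e3, n_harmonics=25) == pytest.approx(
            oracle, rel=0.10)

    def test_unresolvable_f0_rejected(self):
        with pytest.raises(ValueError):
            thd_fft(self.tone(n=100), self.FS, 1e3)


class TestAdcHistogramLinearity:
    BITS = 9

    @staticmethod
    def sine_codes(n, config, distort=None, overdrive=1.02):
        # linearly swept (equidistributed) phase: a quasi-deterministic
        # histogram free of Poisson scatter
        phase = (np.arange(n) * 0.61803398875) % 1.0
        v = overdrive * config.adc_fullscale * np.sin(2 * np.pi * phase)
        if distort is not None:
            return distort(v)
        codes, _ = adc_quantize(v, config)
        return codes

    def test_ideal_quantizer_dnl_below_0p05(self, config):
        codes = self.sine_codes(2 ** self.BITS * 1000, config)
        dnl, inl, missing = adc_histogram_linearity(codes, self.BITS)
        assert missing.size == 0
        assert np.nanmax(np.abs(dnl[1:-1])) < 0.05

    def test_widened_code_shows_half_lsb_dnl(self, config):
        k = 200

        def distort(v):
            r = v / config.adc_lsb + 256.0
            code = np.round(r)
            wide = (r >= k - 0.75) & (r < k + 0.75)
            code[wide] = k
            return np.clip(code, 0, 511).astype(int)

        codes = self.sine_codes(2 ** self.BITS * 1500, config, distort=distort)
        dnl, inl, _ = adc_histogram_linearity(codes, self.BITS)
        assert dnl[k] == pytest.approx(0.5, abs=0.1)

    def test_inl_endpoints_near_zero(self, config):
        codes = self.sine_codes(2 ** self.BITS * 1000, config)
        _, inl, _ = adc_histogram_linearity(codes, self.BITS)
        interior = inl[1:-1]
        assert abs(interior[0]) < 0.05 and abs(interior[-1]) < 0.05

    def test_too_few_samples_rejected(self, config):
        with pytest.raises(ValueError):
            adc_histogram_linearity(np.full(1000, 256), self.BITS)


@given(st.floats(1e-6, 1e-3), st.floats(1.1, 10.0))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_snr_gain_invariance_property(scale, ratio):
    base = TestSnrWaveforms.synthetic_events(ptp=scale * ratio, sd=scale)
    scaled = TestSnrWaveforms.synthetic_events(ptp=3 * scale * ratio,
                                               sd=3 * scale)
    assert snr_waveforms(scaled) == pytest.approx(snr_waveforms(base), rel=1e-9)
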