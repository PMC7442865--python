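"""Signal processing: touchdown, detrending, segmentation, and the
frequency/damping estimators against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from acutono import sigproc, simulate
from acutono.types import GroundTruth, PulseFeatures, PulseSegment
from conftest import FS, noiseless_config
from test_simulate import nominal_eye


def segment_of(samples, fs=FS, clipped=False):
    return PulseSegment(measurement_id="T", pulse_index=0, samples=samples,
                        t0=0.0, sample_rate=fs, clipped=clipped)


class TestDetectTouchdown:
    def test_all_zero_pressure_is_false(self):
        assert not sigproc.detect_touchdown(np.zeros(60_000), FS)

    def test_simulator_trace_is_true(self):
        cfg = noiseless_config(n_subjects=1)
        truth = GroundTruth(true_iop=16, true_damping=150, true_frequency=450)
        raw = simulate.synthesize_recording(nominal_eye(), truth, cfg)
        assert sigproc.detect_touchdown(raw.pressure, raw.sample_rate)

    def test_half_threshold_step_is_false(self):
        p = np.zeros(60_000)
        p[30_000:] = 25.0  # half the 50 Pa threshold
        assert not sigproc.detect_touchdown(p, FS, threshold=50.0)

    def test_short_blip_is_not_sustained(self):
        p = np.zeros(60_000)
        p[30_000 : 30_000 + int(0.05 * FS)] = 100.0  # 50 ms << 200 ms
        assert not sigproc.detect_touchdown(p, FS)

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            sigproc.detect_touchdown(np.zeros(100), FS, t_end=5.0)


class TestDetrendOffset:
    def _pulse_train(self, make_pulse, n_pulses=6, gap_s=0.3):
        fs = FS
        n = int((0.5 + n_pulses * gap_s) * fs)
        x = np.zeros(n)
        onsets = []
        for k in range(n_pulses):
            i0 = int((0.2 + k * gap_s) * fs)
            p = make_pulse()
            x[i0 : i0 + p.size] += p
            onsets.append(i0)
        anchors = [(i0 - 800, i0 - 400) for i0 in onsets]
        return x, anchors

    def test_zero_baseline_nearly_unchanged(self, make_pulse):
        x, anchors = self._pulse_train(make_pulse)
        out = sigproc.detrend_offset(x, FS, anchors)
        rms_in = np.sqrt(np.mean(x**2))
        assert np.sqrt(np.mean((out - x) ** 2)) < 1e-3 * rms_in

    def test_removes_cubic_drift(self, make_pulse):
        x, anchors = self._pulse_train(make_pulse)
        t = np.arange(x.size) / FS
        drift_amp = 0.5
        drift = drift_amp * (0.3 + 0.8 * t - 0.5 * t**2 + 0.15 * t**3)
        out = sigproc.detrend_offset(x + drift, FS, anchors)
        # residual baseline measured on the quiet anchor windows
        residual = np.concatenate([out[i0:i1] for i0, i1 in anchors])
        assert np.sqrt(np.mean(residual**2)) < 0.01 * drift_amp

    def test_constant_offset_removed(self, make_pulse):
        x, anchors = self._pulse_train(make_pulse)
        out = sigproc.detrend_offset(x + 3.7, FS, anchors)
        residual = np.concatenate([out[i0:i1] for i0, i1 in anchors])
        assert np.abs(residual).max() < 1e-6

    def test_idempotent(self, make_pulse):
        # a polynomial offset is removed exactly on the first pass, so the
        # second pass must be a near no-op
        x, anchors = self._pulse_train(make_pulse)
        t = np.arange(x.size) / FS
        drift = 0.5 - 1.2 * t + 0.8 * t**2 - 0.2 * t**3
        once = sigproc.detrend_offset(x + drift, FS, anchors)
        twice = sigproc.detrend_offset(once, FS, anchors)
        rms = np.sqrt(np.mean(once**2))
        assert np.sqrt(np.mean((twice - once) ** 2)) < 1e-3 * rms

    def test_few_anchors_falls_back_to_single_cubic(self):
        t = np.arange(20_000) / FS
        drift = 1.0 + 2.0 * t - 3.0 * t**2 + 0.5 * t**3
        out = sigproc.detrend_offset(drift, FS, anchors=[(0, 100), (5000, 5100)])
        assert np.abs(out).max() < 1e-6


class TestZeroCrossings:
    def test_one_full_cycle_has_two_crossings(self):
        f = 97.0  # period not commensurate with the grid: no on-sample zeros
        t = np.arange(int(1.02 / f * FS)) / FS
        assert sigproc.count_zero_crossings(np.sin(2 * np.pi * f * t)) == 2

    def test_damped_sinusoid_matches_analytic_crossing_count(self, make_pulse):
        # zeros of sin(2*pi*f*t) at k/(2f); count those inside the sampled span
        f, lam, dur = 450.0, 200.0, 0.0099
        x = make_pulse(f=f, lam=lam, duration=dur)
        t_max = (x.size - 1) / FS
        expected = int(np.floor(2 * f * t_max))
        assert sigproc.count_zero_crossings(x) == expected

    def test_negation_leaves_count_unchanged(self, make_pulse):
        x = make_pulse()
        assert sigproc.count_zero_crossings(-x) == sigproc.count_zero_crossings(x)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_positive_scaling_invariance(self, scale):
        t = np.arange(300) / FS
        x = np.exp(-120 * t) * np.sin(2 * np.pi * 410 * t + 0.3)
        assert sigproc.count_zero_crossings(scale * x) == sigproc.count_zero_crossings(x)

    def test_all_zero_segment_counts_zero(self):
        assert sigproc.count_zero_crossings(np.zeros(64)) == 0


class TestEstimateFrequency:
    @pytest.mark.parametrize("f,tol", [(450.0, 2.0), (570.0, 3.0)])
    def test_pure_sinusoid(self, make_pulse, f, tol):
        x = make_pulse(f=f, lam=0.0, duration=0.02)
        assert sigproc.estimate_frequency(x, FS) == pytest.approx(f, abs=tol)

    def test_damped_sinusoid(self, make_pulse):
        # damping does not move the zeros, so the estimate stays tight
        x = make_pulse(f=400.0, lam=200.0)
        assert sigproc.estimate_frequency(x, FS) == pytest.approx(400.0, abs=4.0)

    def test_too_few_crossings_raises(self):
        t = np.arange(40) / FS  # 4 ms of a 100 Hz half-wave: no crossings
        with pytest.raises(sigproc.UndefinedFeatureError):
            sigproc.estimate_frequency(np.sin(2 * np.pi * 100 * t), FS)

    def test_fft_cross_check_agrees(self, make_pulse):
        x = make_pulse(f=480.0, lam=100.0)
        zc = sigproc.estimate_frequency(x, FS)
        fft = sigproc.estimate_frequency_fft(x, FS)
        assert abs(zc - fft) / 480.0 < 0.02


class TestEstimateDamping:
    def test_noiseless_within_one_percent(self, make_pulse):
        x = make_pulse(f=450.0, lam=150.0)
        assert 148.5 <= sigproc.estimate_damping(x, FS) <= 151.5

    def test_scale_invariant(self, make_pulse):
        x = make_pulse(f=430.0, lam=180.0)
        a = sigproc.estimate_damping(x, FS)
        b = sigproc.estimate_damping(10.0 * x, FS)
        assert a == pytest.approx(b, rel=1e-9)

    def test_mean_bias_under_noise_below_two_percent(self, make_pulse):
        # Monte-Carlo oracle: 2% additive noise, many replicates
        lam, sd = 150.0, 0.02
        estimates = []
        for seed in range(200):
            x = make_pulse(f=450.0, lam=lam, noise_sd=sd, seed=seed)
            region = sigproc.analysis_region(x, noise_floor=sd)
            estimates.append(sigproc.estimate_damping(region, FS, noise_floor=sd))
        assert abs(np.mean(estimates) - lam) / lam < 0.02

    def test_silent_segment_raises(self):
        with pytest.raises(sigproc.UndefinedFeatureError):
            sigproc.estimate_damping(np.zeros(100), FS)


class TestSegmentPulses:
    def test_simulator_trace_yields_exactly_twenty_segments(self):
        cfg = noiseless_config(n_subjects=1, noise_sd=0.02, drift_amplitude=0.3)
        truth = GroundTruth(true_iop=16, true_damping=150, true_frequency=450)
        raw = simulate.synthesize_recording(nominal_eye(), truth, cfg)
        prep = sigproc.prepare_recording(raw)
        assert len(prep.segments) == 20

    def test_silent_trace_yields_no_segments(self):
        silent = np.zeros(int(6.0 * FS))
        assert sigproc.segment_pulses(silent, FS, t_start=5.0) == []

    def test_clipped_flag_from_raw_rail(self, make_pulse):
        fs, rail = FS, 1.2
        x = np.zeros(int(7.0 * fs))
        for k, amp in enumerate([1.0, 2.0, 1.0]):
            i0 = int((5.5 + 0.5 * k) * fs)
            p = amp * make_pulse()
            x[i0 : i0 + p.size] += p
        raw = np.clip(x, -rail, rail)
        segs = sigproc.segment_pulses(raw, fs, t_start=5.0, raw_trace=raw,
                                      sensor_range=rail)
        assert len(segs) == 3
        assert [s.clipped for s in segs] == [False, True, False]


class TestSummarizeMeasurement:
    def _pf(self, idx, damping, frequency=450.0, amplitude=1.0, valid=True):
        return PulseFeatures(pulse_index=idx, n_zero_crossings=9, frequency=frequency,
                             damping=damping, amplitude=amplitude, valid=valid)

    def test_identical_pulses_have_zero_sd(self):
        feats = [self._pf(i, 150.0) for i in range(5)]
        mf = sigproc.summarize_measurement(feats, True, False)
        assert mf.sd_damping == 0.0
        assert mf.cv_damping_percent == 0.0
        assert mf.mean_damping == pytest.approx(150.0)

    def test_means_use_valid_pulses_only(self):
        feats = [self._pf(0, 100.0), self._pf(1, 200.0),
                 self._pf(2, 999.0, valid=False)]
        mf = sigproc.summarize_measurement(feats, True, False)
        assert mf.mean_damping == pytest.approx(150.0)
        assert mf.n_pulses_total == 3
        assert mf.n_pulses_valid == 2

    def test_zero_valid_pulses_leaves_features_undefined(self):
        feats = [self._pf(0, 100.0, valid=False)]
        mf = sigproc.summarize_measurement(feats, True, False)
        assert mf.mean_damping is None and mf.mean_frequency is None
        assert mf.n_pulses_total == 1 and mf.n_pulses_valid == 0


@pytest.fixture(scope="module")
def noisy_recording():
    cfg = noiseless_config(n_subjects=1, noise_sd=0.02, drift_amplitude=0.3, rng_seed=5)
    truth = GroundTruth(true_iop=16, true_damping=150, true_frequency=450)
    return simulate.synthesize_recording(nominal_eye(), truth, cfg), cfg


class TestPipelineInvariances:
    def _features(self, raw):
        from acutono import pipeline

        mf, _, _ = pipeline.process_recording(raw)
        return mf

    def test_scale_invariance_of_damping_and_frequency(self, noisy_recording):
        import dataclasses

        raw, cfg = noisy_recording
        base = self._features(raw)
        scaled = dataclasses.replace(
            raw, displacement=10.0 * raw.displacement, pressure=raw.pressure.copy(),
            sensor_range=10.0 * cfg.sensor_range,
        )
        out = self._features(scaled)
        assert out.mean_damping == pytest.approx(base.mean_damping, rel=1e-6)
        assert out.mean_frequency == pytest.approx(base.mean_frequency, rel=1e-6)
        assert out.mean_amplitude == pytest.approx(10.0 * base.mean_amplitude, rel=1e-6)

    def test_integer_sample_delay_leaves_features_unchanged(self, noisy_recording):
        import dataclasses

        raw, _ = noisy_recording
        base = self._features(raw)
        k = 7
        delayed = dataclasses.replace(
            raw,
            displacement=np.r_[raw.displacement[:k], raw.displacement[:-k]],
            pressure=np.r_[raw.pressure[:k], raw.pressure[:-k]],
        )
        out = self._features(delayed)
        assert out.mean_frequency == pytest.approx(base.mean_frequency, rel=5e-3)
        assert out.mean_damping == pytest.approx(base.mean_damping, rel=2e-2)
        assert out.n_pulses_total == base.n_pulses_total
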