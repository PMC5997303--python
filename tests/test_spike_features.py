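import numpy as np
import pytest

from fastspike.errors import MeasurementError, PreconditionError, ValidationError
from fastspike.sweep_model import Recording, RecordingMode, StepProtocol
from fastspike.synthetic_data import NeuronModelParams, simulate_current_clamp
from fastspike import spike_features as sf

from conftest import make_sweep, triangle_spike


def _trace(n=7000):
    return np.full(n, -66.0)


def spike_train_sweep(peak_times, rise=0.4, peak_v=0.0, amplitude=300.0, base=-66.0):
    v = np.full(7000, base)
    t = np.arange(7000) * 0.1
    for pt in peak_times:
        triangle_spike(v, t, pt, rise, peak_v, base=base)
    return make_sweep(v, amplitude=amplitude)


class TestDetectSpikes:
    def test_silent_sweep_detects_nothing(self):
        assert sf.detect_spikes(make_sweep(_trace())) == []

    def test_voltage_clamp_rejected(self):
        with pytest.raises(PreconditionError):
            sf.detect_spikes(make_sweep(_trace(), mode=RecordingMode.VOLTAGE_CLAMP))

    def test_refractory_rule_merges_close_peaks(self):
        sweep = spike_train_sweep([300.0, 300.8])
        assert len(sf.detect_spikes(sweep)) == 1

    def test_slow_hump_not_detected(self):
        # peak above -10 mV but rising at only ~2 V/s: no detection
        v = _trace()
        t = np.arange(7000) * 0.1
        triangle_spike(v, t, 300.0, 30.0, -5.0, base=-66.0)
        assert sf.detect_spikes(make_sweep(v)) == []

    def test_matches_simulator_log_on_noiseless_steps(self):
        rec = simulate_current_clamp(
            NeuronModelParams(), StepProtocol(step_amplitudes=[200.0, 600.0]), seed=0
        )
        for sweep, logged in zip(rec.sweeps, rec.annotations["spike_times_ms"]):
            assert [t for t, _ in sf.detect_spikes(sweep)] == pytest.approx(logged)


class TestApThreshold:
    def test_ramp_onset_localized_exactly(self):
        """A 25 V/s ramp preceded by 0 V/s puts the threshold at the ramp foot."""
        v = _trace()
        t0_idx = 3000
        ramp = 25.0 * np.arange(1, 31) * 0.1  # 25 V/s (2.5 mV/sample) for 3 ms
        v[t0_idx + 1 : t0_idx + 31] = -66.0 + ramp
        sweep = make_sweep(v)
        peak_idx = t0_idx + 30
        thr_v, thr_t = sf.ap_threshold(sweep, (peak_idx * 0.1, v[peak_idx]))
        assert thr_t == pytest.approx(t0_idx * 0.1)
        assert thr_v == pytest.approx(-66.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_scan(self, seed):
        """Threshold equals the first sample whose forward-difference
        derivative reaches 20 V/s, found by exhaustive scan."""
        rng = np.random.default_rng(seed)
        rec = simulate_current_clamp(
            NeuronModelParams(noise_sd=float(rng.uniform(0, 3))),
            StepProtocol(step_amplitudes=[float(rng.integers(60, 200))]),
            seed=seed,
        )
        sweep = rec.sweeps[0]
        spikes = sf.detect_spikes(sweep)
        assert spikes, "expected at least one spike"
        dt = sweep.dt_ms
        d = np.diff(sweep.samples) / dt
        for peak_t, peak_v in spikes[:3]:
            i_peak = int(round(peak_t / dt))
            # brute force: scan backward for the start of the final
            # supra-criterion run before the peak
            k = None
            j = i_peak - 1
            while j >= 0 and d[j] < 20.0:
                j -= 1
            while j >= 0 and d[j] >= 20.0:
                k = j
                j -= 1
            _, thr_t = sf.ap_threshold(sweep, (peak_t, peak_v))
            assert thr_t == pytest.approx(k * dt)

    def test_sub_criterion_artifact_is_an_error(self):
        v = _trace()
        t = np.arange(7000) * 0.1
        triangle_spike(v, t, 300.0, 40.0, 0.0, base=-66.0)  # 1.65 V/s rise
        sweep = make_sweep(v)
        with pytest.raises(MeasurementError):
            sf.ap_threshold(sweep, (300.0, 0.0))


class TestSingleApFeatures:
    def test_amplitude_relative_to_threshold(self):
        f = sf.SpikeFeatures(threshold_v=-40.0, peak_v=23.0)
        assert sf.ap_amplitude(f) == pytest.approx(63.0)
        f_zero = sf.SpikeFeatures(threshold_v=-40.0, peak_v=-40.0)
        assert sf.ap_amplitude(f_zero) == 0.0

    def test_simulator_amplitude_equals_peak_minus_threshold(self):
        rec = simulate_current_clamp(
            NeuronModelParams(), StepProtocol.first_ap(), seed=0
        )
        f = sf.first_evoked_ap(rec)
        assert f.peak_v == pytest.approx(NeuronModelParams().V_peak)
        assert f.amplitude == pytest.approx(f.peak_v - f.threshold_v)

    def test_half_width_of_symmetric_triangle(self):
        # 1 ms above the half level: rise/fall 1 ms each
        sweep = spike_train_sweep([300.0], rise=1.0)
        spikes = sf.detect_spikes(sweep)
        f = sf.measure_spike(sweep, spikes[0])
        assert f.half_width == pytest.approx(1.0, abs=0.05)

    def test_half_width_matches_gaussian_fwhm(self):
        sigma = 0.5
        v = _trace()
        t = np.arange(7000) * 0.1
        v += 61.0 * np.exp(-((t - 300.0) ** 2) / (2 * sigma**2))
        sweep = make_sweep(v)
        (peak_t, peak_v), = sf.detect_spikes(sweep)
        # reference the half level to the baseline so the measured width is
        # the analytic full width at half maximum, 2.355 sigma
        f = sf.SpikeFeatures(threshold_v=-66.0, threshold_t=295.0,
                             peak_v=peak_v, peak_t=peak_t)
        fwhm = 2.0 * sigma * np.sqrt(2.0 * np.log(2.0))
        assert sf.ap_half_width(sweep, f) == pytest.approx(fwhm, abs=0.1)

    def test_half_width_halves_under_time_compression(self):
        sigma = 0.6
        t = np.arange(7000) * 0.1
        widths = []
        for s in (sigma, sigma / 2.0):
            v = _trace() + 61.0 * np.exp(-((t - 300.0) ** 2) / (2 * s**2))
            sweep = make_sweep(v)
            (peak_t, peak_v), = sf.detect_spikes(sweep)
            f = sf.SpikeFeatures(threshold_v=-66.0, threshold_t=295.0,
                                 peak_v=peak_v, peak_t=peak_t)
            widths.append(sf.ap_half_width(sweep, f))
        assert widths[1] == pytest.approx(widths[0] / 2.0, abs=0.1)

    def test_truncated_spike_is_an_error(self):
        v = _trace(3010)
        t = np.arange(3010) * 0.1
        v[3000:] = np.linspace(-66.0, 0.0, 10)  # upstroke at the trace end
        sweep = make_sweep(v, onset=100.0, duration=150.0)
        f = sf.SpikeFeatures(threshold_v=-66.0, threshold_t=300.0,
                             peak_v=0.0, peak_t=300.9)
        with pytest.raises(MeasurementError):
            sf.ap_half_width(sweep, f)

    def test_latency_from_stimulus_onset(self):
        sweep = make_sweep(_trace(), onset=100.0)
        f = sf.SpikeFeatures(peak_t=149.5)
        assert sf.ap_latency(sweep, f) == pytest.approx(49.5)
        with pytest.raises(ValidationError):
            sf.ap_latency(sweep, sf.SpikeFeatures(peak_t=50.0))

    def test_fahp_amplitude_and_flagging(self):
        v = np.full(7000, -60.0)  # rest above the fAHP trough
        t = np.arange(7000) * 0.1
        triangle_spike(v, t, 300.0, 0.4, 0.0, base=-60.0)
        trough = (t > 300.35) & (t <= 302.0)
        v[trough] = -62.0
        sweep = make_sweep(v)
        f = sf.SpikeFeatures(threshold_v=-40.0, threshold_t=299.6,
                             peak_v=0.0, peak_t=300.0)
        amp, lat = sf.fahp(sweep, f)
        assert amp == pytest.approx(22.0)
        assert lat > 0
        # monotonic decay settling above threshold (no undershoot): flagged zero
        v2 = np.full(7000, -39.0)
        triangle_spike(v2, t, 300.0, 0.4, 0.0, base=-39.0)
        with pytest.warns(UserWarning, match="fAHP"):
            amp2, lat2 = sf.fahp(make_sweep(v2), f)
        assert amp2 == 0.0 and np.isnan(lat2)

    def test_simulator_fahp_trough_is_the_reset(self):
        params = NeuronModelParams()
        rec = simulate_current_clamp(params, StepProtocol.first_ap(), seed=0)
        f = sf.first_evoked_ap(rec)
        assert f.fahp_amplitude == pytest.approx(
            f.threshold_v - params.V_reset, abs=1.0
        )


class TestTrainFeatures:
    def test_broadening_formula_on_constructed_trains(self):
        # first AP evoked at 40 pA; the 80 pA step carries HW 0.50 then 0.53
        first = spike_train_sweep([300.0], rise=0.5, amplitude=40.0)
        doubled = np.full(7000, -66.0)
        t = np.arange(7000) * 0.1
        triangle_spike(doubled, t, 200.0, 0.50, 0.0, base=-66.0)
        triangle_spike(doubled, t, 400.0, 0.53, 0.0, base=-66.0)
        rec = Recording(sweeps=[first, make_sweep(doubled, amplitude=80.0)])
        assert sf.ap_broadening(rec) == pytest.approx(0.06, abs=0.02)

    def test_no_broadening_in_the_stereotyped_model(self):
        rec = simulate_current_clamp(
            NeuronModelParams(), StepProtocol.standard(), seed=0
        )
        value = sf.ap_broadening(rec)
        assert value is not None and abs(value) < 0.02

    def test_equal_half_widths_give_zero_broadening(self):
        first = spike_train_sweep([300.0], rise=0.5, amplitude=40.0)
        doubled = spike_train_sweep([200.0, 400.0], rise=0.5, amplitude=80.0)
        rec = Recording(sweeps=[first, doubled])
        assert sf.ap_broadening(rec) == pytest.approx(0.0, abs=1e-9)

    def test_max_firing_frequency_counts_spikes_per_half_second(self):
        peaks = 100.0 + 500.0 / 132.0 * np.arange(132) + 1.0
        sweep = spike_train_sweep(list(peaks), rise=0.4, amplitude=900.0)
        rec = Recording(sweeps=[sweep])
        assert sf.max_firing_frequency(rec) == pytest.approx(264.0)

    def test_single_spike_gives_two_hz(self):
        rec = Recording(sweeps=[spike_train_sweep([300.0], amplitude=100.0)])
        assert sf.max_firing_frequency(rec) == pytest.approx(2.0)

    def test_step_with_aborted_spikes_is_skipped(self):
        clean = spike_train_sweep(list(100.0 + 44.0 * np.arange(10) + 5.0),
                                  amplitude=200.0)
        v = np.full(7000, -66.0)
        t = np.arange(7000) * 0.1
        for pt in 100.0 + 44.0 * np.arange(10) + 5.0:
            triangle_spike(v, t, pt, 0.4, 0.0, base=-66.0)
        # aborted spike between two full ones: fast rise but only to -20 mV
        triangle_spike(v, t, 325.0, 0.4, -20.0, base=-66.0)
        failing = make_sweep(v, amplitude=400.0)
        rec = Recording(sweeps=[clean, failing])
        # the failing 400 pA step is excluded; rate comes from the 200 pA step
        assert sf.max_firing_frequency(rec) == pytest.approx(20.0)

    def test_depolarization_block_step_is_skipped(self):
        clean = spike_train_sweep(list(100.0 + 44.0 * np.arange(10) + 5.0),
                                  amplitude=200.0)
        # spikes only in the first 150 ms of the 500 ms step, then silence
        blocked = spike_train_sweep(list(110.0 + 10.0 * np.arange(14)),
                                    amplitude=400.0)
        rec = Recording(sweeps=[clean, blocked])
        assert sf.max_firing_frequency(rec) == pytest.approx(20.0)

    def test_silent_protocol_has_no_max_rate(self):
        rec = Recording(sweeps=[make_sweep(_trace(), amplitude=100.0)])
        assert sf.max_firing_frequency(rec) is None


class TestIfCurve:
    def test_single_cell_curve_equals_its_rates(self):
        sweeps = [
            spike_train_sweep([300.0, 320.0], amplitude=100.0),
            spike_train_sweep([300.0, 320.0, 340.0, 360.0], amplitude=200.0),
        ]
        curve = sf.if_curve([Recording(sweeps=sweeps)])
        np.testing.assert_allclose(curve.currents, [100.0, 200.0])
        np.testing.assert_allclose(curve.mean_rates, [4.0, 8.0])

    def test_two_cell_mean_and_sd(self):
        cells = []
        for n_spikes in (50, 100):  # 100 and 200 Hz at 500 pA
            peaks = 100.0 + 5.0 * np.arange(n_spikes) + 2.0
            cells.append(Recording(sweeps=[spike_train_sweep(list(peaks),
                                                             amplitude=500.0)]))
        curve = sf.if_curve(cells)
        assert curve.mean_rates[0] == pytest.approx(150.0)
        assert curve.sd_rates[0] == pytest.approx(70.71, abs=0.01)
        assert curve.n_cells[0] == 2

    def test_cells_missing_an_amplitude_are_omitted_pointwise(self):
        a = Recording(sweeps=[spike_train_sweep([300.0], amplitude=100.0)])
        b = Recording(sweeps=[spike_train_sweep([300.0], amplitude=200.0)])
        curve = sf.if_curve([a, b])
        np.testing.assert_array_equal(curve.n_cells, [1, 1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            sf.if_curve([])

    def test_population_mean_matches_single_cell_under_noise(self):
        """Identical cells with noise: sd small, mean near the noiseless rate."""
        proto = StepProtocol(step_amplitudes=[300.0])
        noiseless = simulate_current_clamp(NeuronModelParams(), proto, seed=0)
        ref_rate = sf.if_curve([noiseless]).mean_rates[0]
        recs = [
            simulate_current_clamp(NeuronModelParams(noise_sd=10.0), proto, seed=s)
            for s in range(10)
        ]
        curve = sf.if_curve(recs)
        assert curve.mean_rates[0] == pytest.approx(ref_rate, rel=0.10)
        assert curve.sd_rates[0] < 0.2 * ref_rate


class TestAccommodation:
    def test_regular_constant_train(self):
        peaks = 100.0 + 10.0 * np.arange(50) + 5.0
        sweep = spike_train_sweep(list(peaks), amplitude=500.0)
        ratio, attenuation = sf.accommodation_metrics(sweep)
        assert ratio == pytest.approx(1.0)
        assert attenuation == pytest.approx(0.0, abs=1e-9)

    def test_rate_halving_train(self):
        first = 100.0 + 10.0 * np.arange(10) + 5.0      # 10 spikes / first 100 ms
        last = 500.0 + 20.0 * np.arange(5) + 5.0        # 5 spikes / last 100 ms
        sweep = spike_train_sweep(list(first) + list(last), amplitude=500.0)
        ratio, _ = sf.accommodation_metrics(sweep)
        assert ratio == pytest.approx(0.5)

    def test_too_few_spikes_not_applicable(self):
        sweep = spike_train_sweep([300.0, 400.0, 500.0], amplitude=500.0)
        assert sf.accommodation_metrics(sweep) is None

    def test_adapting_model_slows_late_in_the_step(self):
        params = NeuronModelParams(b=30.0, tau_w=120.0)
        rec = simulate_current_clamp(
            params, StepProtocol(step_amplitudes=[500.0]), seed=0
        )
        ratio, _ = sf.accommodation_metrics(rec.sweeps[0])
        assert ratio < 1.0


class TestInvariances:
    def test_time_features_invariant_to_voltage_offset(self):
        rec = simulate_current_clamp(
            NeuronModelParams(), StepProtocol.first_ap(), seed=0
        )
        f0 = sf.first_evoked_ap(rec)
        shifted = Recording(
            sweeps=[s.with_samples(s.samples + 5.0) for s in rec.sweeps]
        )
        f1 = sf.first_evoked_ap(shifted)
        assert f1.threshold_t == pytest.approx(f0.threshold_t)
        assert f1.peak_t == pytest.approx(f0.peak_t)
        assert f1.half_width == pytest.approx(f0.half_width, abs=1e-9)
        assert f1.latency == pytest.approx(f0.latency)
        # voltage-relative features are also offset-invariant
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-9)
        assert f1.fahp_amplitude == pytest.approx(f0.fahp_amplitude, abs=1e-9)

    def test_voltage_features_invariant_to_time_shift(self):
        sweep = spike_train_sweep([300.0], rise=0.5, amplitude=100.0)
        f0 = sf.measure_spike(sweep, sf.detect_spikes(sweep)[0])
        shifted = spike_train_sweep([350.0], rise=0.5, amplitude=100.0)
        f1 = sf.measure_spike(shifted, sf.detect_spikes(shifted)[0])
        assert f1.amplitude == pytest.approx(f0.amplitude, abs=1e-9)
        assert f1.half_width == pytest.approx(f0.half_width, abs=1e-9)
        assert f1.threshold_v == pytest.approx(f0.threshold_v, abs=1e-9)
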