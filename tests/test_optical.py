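"""Tests of DC removal, triggered averaging and the S/N pipeline."""

import numpy as np
import pytest

from vsdqc.optical import (
    FluorescenceTrace,
    SnrConfig,
    compute_snr,
    dc_remove,
    highpass_noise_filter,
    noise_sd,
    signal_amplitude,
    triggered_average,
)
from vsdqc.spike_metrics import detect_bursts
from vsdqc.synthetic import (
    NeuronSpec,
    OpticsSpec,
    RhythmSpec,
    generate_rhythm,
    render_fluorescence,
)


def make_trace(values, dt=0.001):
    return FluorescenceTrace(values=np.asarray(values, float), sample_interval=dt)


def snr_trace(seed, noise_sd_val=0.05, amplitude=1.0, n_cycles=16, dt=0.0015, period=1.0):
    """Synthetic LP trace with known slow-wave amplitude and noise SD,
    together with its LP burst-onset triggers."""
    spec = RhythmSpec(
        cycle_period=period,
        neurons={"LP": NeuronSpec(0.4, 0.3, 20.0)},
        n_cycles=n_cycles,
        require_triphasic=False,
        seed=seed,
    )
    r = generate_rhythm(spec)
    optics = OpticsSpec(
        sample_interval=dt,
        slow_wave_amplitude=amplitude,
        spike_transient_amplitude=0.0,
        noise_sd=noise_sd_val,
        seed=seed + 1000,
    )
    trace = render_fluorescence(
        r.trains["LP"], optics, r, duration=r.duration + spec.cycle_period
    )
    triggers = [b.first_spike for b in detect_bursts(r.trains["LP"], 0.25)]
    return trace, triggers


class TestDcRemove:
    def test_constant_maps_to_zero(self):
        out = dc_remove(make_trace(np.full(5000, 7.3)), half_window=0.5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_linear_ramp_interior_zero(self):
        n, hw = 5000, 500
        out = dc_remove(make_trace(np.arange(n, dtype=float)), half_window=0.5)
        np.testing.assert_allclose(out.values[hw : n - hw], 0.0, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, w",
        [(1.0, 0.5), (1.0, 0.25), (0.5, 0.5)],
    )
    def test_sine_gain_closed_form(self, freq, w):
        """Sliding-mean subtraction has gain 1 - sinc(omega*w) on a sinusoid."""
        dt = 0.001
        t = np.arange(int(20 / dt)) * dt
        omega = 2 * np.pi * freq
        out = dc_remove(make_trace(np.sin(omega * t), dt), half_window=w)
        hw = int(round(w / dt))
        interior = out.values[2 * hw : -2 * hw]
        expected_gain = 1 - np.sin(omega * w) / (omega * w)
        measured = (interior.max() - interior.min()) / 2
        assert measured == pytest.approx(abs(expected_gain), rel=0.01, abs=1e-4)

    def test_window_shorter_than_sample_rejected(self):
        with pytest.raises(ValueError, match="shorter than one sample"):
            dc_remove(make_trace(np.zeros(100), dt=0.0015), half_window=0.0005)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=4000), rng.normal(size=4000)
        a, b = 2.5, -1.3
        lhs = dc_remove(make_trace(a * x + b * y), 0.1).values
        rhs = a * dc_remove(make_trace(x), 0.1).values + b * dc_remove(make_trace(y), 0.1).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestHighpassNoiseFilter:
    def test_constant_maps_to_zero(self):
        out = highpass_noise_filter(make_trace(np.full(3000, 4.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_slow_sine_strongly_attenuated(self):
        dt = 0.0015
        t = np.arange(int(10 / dt)) * dt
        out = highpass_noise_filter(make_trace(np.sin(2 * np.pi * t), dt), time_base=0.01)
        residual = np.abs(out.values[100:-100]).max()
        assert residual < 0.01  # < 1% of unit input amplitude

    def test_white_noise_sd_preserved(self):
        dt = 0.0015
        sigma = 0.5
        rng = np.random.default_rng(3)
        out = highpass_noise_filter(
            make_trace(rng.normal(0, sigma, 100_000), dt), time_base=0.01
        )
        n_w = 2 * round(0.01 / dt) + 1
        expected = sigma * np.sqrt(1 - 1 / n_w)
        assert np.std(out.values) == pytest.approx(expected, rel=0.10)


class TestTriggeredAverage:
    def test_identical_cycles_recovered_exactly(self):
        dt = 0.001
        cycle = np.sin(2 * np.pi * np.arange(500) / 500)
        trace = make_trace(np.tile(cycle, 12), dt)
        triggers = np.arange(12) * 0.5
        res = triggered_average(trace, triggers)
        assert res.n_cycles == 12  # every trigger has a full period after it
        assert res.cycle_period == pytest.approx(0.5)
        np.testing.assert_allclose(res.waveform, cycle, atol=1e-12)

    def test_single_trigger_returns_segment(self):
        dt = 0.001
        values = np.arange(1000, dtype=float)
        trace = make_trace(values, dt)
        with pytest.warns(UserWarning, match="cycle"):
            res = triggered_average(trace, [0.0])
        assert res.n_cycles == 1
        np.testing.assert_array_equal(res.waveform, values[: res.waveform.size])

    def test_no_complete_segment_rejected(self):
        trace = make_trace(np.zeros(100), 0.001)
        with pytest.raises(ValueError, match="complete segment"):
            triggered_average(trace, [10.0, 11.0])

    def test_white_noise_sqrt_n_reduction(self):
        """Averaging 16 noise sweeps shrinks the SD by ~4x."""
        dt, period, sigma = 0.0015, 0.5, 1.0
        triggers = np.arange(16) * period
        n = int(17 * period / dt)
        sds = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            trace = make_trace(rng.normal(0, sigma, n), dt)
            with np.errstate(all="ignore"):
                res = triggered_average(trace, triggers, min_cycles_warning=1)
            sds.append(np.std(res.waveform))
        assert np.mean(sds) == pytest.approx(sigma / 4, rel=0.25)


class TestAmplitudeAndNoise:
    def test_amplitude_peak_to_trough(self):
        w = 3.0 * np.sin(2 * np.pi * np.arange(500) / 500)  # grid hits the peaks
        assert signal_amplitude(w) == pytest.approx(6.0, rel=1e-12)
        assert signal_amplitude(np.full(100, 2.0)) == 0.0

    def test_noiseless_trace_has_negligible_noise(self):
        """Without injected noise only the curvature residual of the 0.01-s
        sliding-mean filter survives (~f''(t) w^2/6), well under 1% of the
        unit slow-wave amplitude."""
        trace, triggers = snr_trace(seed=0, noise_sd_val=0.0)
        sd = noise_sd(trace, triggers)
        assert sd < 0.01 * 1.0

    def test_noise_sd_recovers_sigma_over_sqrt_n(self):
        sigma, n = 0.1, 16
        estimates = []
        for seed in range(50):
            trace, triggers = snr_trace(seed, noise_sd_val=sigma, amplitude=0.0, n_cycles=n)
            estimates.append(noise_sd(trace, triggers))
        assert np.mean(estimates) == pytest.approx(sigma / np.sqrt(n), rel=0.25)

    def test_noise_sd_linear_in_sigma(self):
        for seed in (1, 2, 3):
            t1, trig = snr_trace(seed, noise_sd_val=0.05, amplitude=0.0)
            t2, _ = snr_trace(seed, noise_sd_val=0.10, amplitude=0.0)
            ratio = noise_sd(t2, trig) / noise_sd(t1, trig)
            assert ratio == pytest.approx(2.0, rel=0.05)

    def test_noise_sd_decreases_with_cycles(self):
        sigma = 0.1
        means = []
        for n in (4, 16, 64):
            vals = [
                noise_sd(*snr_trace(seed + 100 * n, noise_sd_val=sigma, amplitude=0.0, n_cycles=n))
                for seed in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestComputeSnr:
    def test_snr_is_amplitude_over_noise(self):
        trace, triggers = snr_trace(seed=5, noise_sd_val=0.05)
        res = compute_snr(trace, triggers)
        assert res.snr == pytest.approx(res.amplitude / res.noise_sd)
        assert not res.infinite_snr
        assert res.n_cycles >= 10

    def test_noiseless_flags_infinite(self):
        dt = 0.001
        cycle = np.zeros(500)
        trace = make_trace(np.tile(cycle, 20), dt)
        res = compute_snr(trace, np.arange(19) * 0.5)
        assert res.infinite_snr and res.snr is None

    def test_parameter_recovery(self):
        """Median relative error of S/N vs A/(sigma/sqrt(16)) below 25%."""
        A, sigma, n = 1.0, 0.05, 16
        errors = []
        for seed in range(20):
            trace, triggers = snr_trace(seed, noise_sd_val=sigma, amplitude=A, n_cycles=n)
            res = compute_snr(trace, triggers)
            expected = A / (sigma / np.sqrt(n))
            errors.append(abs(res.snr - expected) / expected)
        assert np.median(errors) < 0.25

    def test_averaging_improves_snr_by_sqrt_n(self):
        """S/N with 25 averaged cycles over a single sweep: ~sqrt(25) = 5.

        A slow 2-s cycle keeps the slow wave smooth enough that the noise
        branch's curvature leakage and the single-sweep amplitude's
        noise-extreme bias stay small against the sqrt(n) effect."""
        import warnings

        ratios = []
        for seed in range(20):
            trace, triggers = snr_trace(
                seed + 300, noise_sd_val=0.02, amplitude=1.0, n_cycles=25, period=2.0
            )
            multi = compute_snr(trace, triggers)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                single = compute_snr(trace, triggers[:1])
            ratios.append(multi.snr / single.snr)
        assert np.median(ratios) == pytest.approx(5.0, rel=0.30)

    def test_shift_invariance(self):
        trace, triggers = snr_trace(seed=8, noise_sd_val=0.05)
        shifted = FluorescenceTrace(trace.values + 100.0, trace.sample_interval)
        a, b = compute_snr(trace, triggers), compute_snr(shifted, triggers)
        assert b.amplitude == pytest.approx(a.amplitude, rel=1e-9)
        assert b.noise_sd == pytest.approx(a.noise_sd, rel=1e-9)
        assert b.snr == pytest.approx(a.snr, rel=1e-9)

    def test_scale_equivariance(self):
        trace, triggers = snr_trace(seed=9, noise_sd_val=0.05)
        scaled = FluorescenceTrace(trace.values * 3.0, trace.sample_interval)
        a, b = compute_snr(trace, triggers), compute_snr(scaled, triggers)
        assert b.amplitude == pytest.approx(3 * a.amplitude, rel=1e-9)
        assert b.noise_sd == pytest.approx(3 * a.noise_sd, rel=1e-9)
        assert b.snr == pytest.approx(a.snr, rel=1e-9)
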