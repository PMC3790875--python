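"""Tests of the ground-truth generators."""

import math

import numpy as np
import pytest

from vsdqc.photostability import mean_grey
from vsdqc.spike_metrics import SpikeTrain, instantaneous_frequencies
from vsdqc.synthetic import (
    CellSpec,
    DriftSpec,
    NeuronSpec,
    OpticsSpec,
    PathologySpec,
    RhythmSpec,
    StackSpec,
    cell_masks,
    generate_rhythm,
    render_fluorescence,
    render_stack,
)


class TestGenerateRhythm:
    def test_lp_bursts_at_constructed_times(self):
        """Period 1 s, LP at 20 Hz in [0.4, 0.7]: 7 spikes spaced 0.05 s per cycle."""
        spec = RhythmSpec(
            cycle_period=1.0,
            neurons={"LP": NeuronSpec(0.4, 0.3, 20.0)},
            n_cycles=3,
            require_triphasic=False,
            seed=0,
        )
        r = generate_rhythm(spec)
        expected = np.concatenate(
            [base + np.arange(7) * 0.05 for base in (0.4, 1.4, 2.4)]
        )
        np.testing.assert_allclose(r.trains["LP"].times, expected, atol=1e-12)
        np.testing.assert_allclose(
            r.burst_windows["LP"], [(0.4, 0.7), (1.4, 1.7), (2.4, 2.7)], atol=1e-12
        )

    def test_tonic_switch_gives_constant_rate(self):
        spec = RhythmSpec(n_cycles=10, seed=1)
        path = PathologySpec(tonic_switch=True, tonic_rate=5.0, onset_time=0.0)
        r = generate_rhythm(spec, path)
        freqs = instantaneous_frequencies(r.trains["LP"])
        np.testing.assert_allclose(freqs, 5.0, rtol=1e-12)

    def test_period_jitter_sd_matches_draw(self):
        spec = RhythmSpec(n_cycles=200, period_jitter_sd=0.05, seed=42)
        r = generate_rhythm(spec)
        sd = np.std(r.periods, ddof=1)
        assert abs(sd - 0.05) / 0.05 < 0.20

    def test_missing_spikes_binomial(self):
        """Dropped spike count follows Binomial(N, p) within 3 SE at N >= 1e4."""
        spec = RhythmSpec(
            cycle_period=1.0,
            neurons={"LP": NeuronSpec(0.0, 0.5, 40.0)},
            n_cycles=500,
            require_triphasic=False,
            seed=3,
        )
        p = 0.3
        baseline = generate_rhythm(spec)
        n_total = len(baseline.trains["LP"])
        assert n_total >= 10_000
        perturbed = generate_rhythm(
            spec, PathologySpec(missing_spike_prob=p, onset_time=0.0, seed=11)
        )
        n_dropped = n_total - len(perturbed.trains["LP"])
        se = math.sqrt(n_total * p * (1 - p))
        assert abs(n_dropped - p * n_total) <= 3 * se

    def test_triphasic_order_pd_lp_py(self):
        r = generate_rhythm(RhythmSpec(n_cycles=30, period_jitter_sd=0.03, seed=5))
        for i in range(30):
            pd_s = r.burst_windows["PD"][i]
            lp_s = r.burst_windows["LP"][i]
            py_s = r.burst_windows["PY"][i]
            assert pd_s[1] < lp_s[0] < lp_s[1] < py_s[0]

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RhythmSpec(
                neurons={
                    "PD": NeuronSpec(0.0, 0.5, 30.0),
                    "LP": NeuronSpec(0.4, 0.3, 20.0),
                }
            )

    def test_determinism(self):
        a = generate_rhythm(RhythmSpec(n_cycles=20, period_jitter_sd=0.05, seed=9))
        b = generate_rhythm(RhythmSpec(n_cycles=20, period_jitter_sd=0.05, seed=9))
        for label in a.trains:
            np.testing.assert_array_equal(a.trains[label].times, b.trains[label].times)


class TestRenderFluorescence:
    def test_noiseless_peak_to_trough_equals_amplitude(self):
        """With the slow-wave peak on the sample grid the amplitude is exact."""
        spec = RhythmSpec(
            cycle_period=1.0,
            neurons={"LP": NeuronSpec(0.4, 0.3, 20.0)},
            n_cycles=4,
            require_triphasic=False,
            seed=0,
        )
        r = generate_rhythm(spec)
        optics = OpticsSpec(
            sample_interval=0.001,
            slow_wave_amplitude=2.5,
            spike_transient_amplitude=0.0,
            noise_sd=0.0,
        )
        tr = render_fluorescence(r.trains["LP"], optics, r)
        t = tr.times
        for start, end in r.burst_windows["LP"]:
            cyc = tr.values[(t >= start - 0.2) & (t <= end + 0.2)]
            assert cyc.max() - cyc.min() == pytest.approx(2.5, abs=1e-12)
        assert tr.metadata["ground_truth_amplitude"] == 2.5

    def test_pure_noise_sd(self):
        spec = RhythmSpec(n_cycles=1, seed=0)
        r = generate_rhythm(spec)
        optics = OpticsSpec(
            sample_interval=0.0005,
            slow_wave_amplitude=0.0,
            spike_transient_amplitude=0.0,
            noise_sd=0.7,
            seed=21,
        )
        tr = render_fluorescence(SpikeTrain("LP", np.empty(0)), optics, r, duration=50.0)
        assert tr.values.size >= 100_000
        assert abs(np.std(tr.values) - 0.7) / 0.7 < 0.05

    def test_empty_train_flat_with_drift(self):
        r = generate_rhythm(RhythmSpec(n_cycles=2, seed=0))
        optics = OpticsSpec(noise_sd=0.0, drift=DriftSpec(amplitude=1.0, timescale=10.0))
        tr = render_fluorescence(SpikeTrain("Q", np.empty(0)), optics, r)
        expected = 1.0 * np.sin(2 * np.pi * tr.times / 10.0)
        np.testing.assert_allclose(tr.values, expected, atol=1e-12)

    def test_determinism(self):
        r = generate_rhythm(RhythmSpec(n_cycles=3, seed=0))
        optics = OpticsSpec(noise_sd=0.5, seed=4)
        a = render_fluorescence(r.trains["LP"], optics, r)
        b = render_fluorescence(r.trains["LP"], optics, r)
        np.testing.assert_array_equal(a.values, b.values)


class TestRenderStack:
    def test_no_bleach_no_noise_frames_identical(self):
        spec = StackSpec(bleach_time_constant=math.inf, pixel_noise_sd=0.0)
        stack = render_stack(spec)
        for frame in stack.frames[1:]:
            np.testing.assert_array_equal(frame, stack.frames[0])

    def test_pure_bleach_ring_follows_exponential(self):
        spec = StackSpec(
            background=0.0, initial_brightness=200.0, bleach_time_constant=1200.0
        )
        stack = render_stack(spec)
        t = stack.frame_times
        expected = 200.0 * np.exp(-t / 1200.0)
        gt = np.asarray(stack.metadata["ground_truth"]["ring_mean"])
        np.testing.assert_allclose(gt, expected, rtol=1e-12)
        # measured on the quantized frames: within half a grey value
        ring = cell_masks(spec)[0].ring
        measured = np.array([mean_grey(f, ring) for f in stack.frames])
        np.testing.assert_allclose(measured, expected, atol=0.51)

    def test_internalization_ratio_strictly_increases(self):
        """Onset between frames 1 and 2: interior/ring ratio rises from frame 2 on,
        and the interior itself stays at background before the onset."""
        times = tuple(600.0 * i for i in range(7))
        spec = StackSpec(
            frame_times=times,
            internalization_onset=(times[1] + times[2]) / 2,
            pixel_noise_sd=0.0,
        )
        stack = render_stack(spec)
        gt = stack.metadata["ground_truth"]
        interior = np.asarray(gt["interior_mean"])
        ratio = interior / np.asarray(gt["ring_mean"])
        assert np.all(np.diff(ratio[1:]) > 0)
        np.testing.assert_array_equal(interior[:2], spec.background)
        assert gt["internalized"] == [False, False, True, True, True, True, True]

    def test_cells_must_fit_frame(self):
        with pytest.raises(ValueError, match="does not fit"):
            StackSpec(
                frame_shape=(32, 32),
                cells=(CellSpec(center=(30.0, 30.0), radius=12.0, ring_width=3.0, nucleus_radius=4.0),),
            )

    def test_determinism(self):
        spec = StackSpec(pixel_noise_sd=2.0, seed=13)
        np.testing.assert_array_equal(
            render_stack(spec).frames, render_stack(spec).frames
        )
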