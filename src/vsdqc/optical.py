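"""Cycle-triggered signal-to-noise analysis of ROI fluorescence traces.

The optical signal of a voltage-sensitive dye tracks the slow-wave
membrane-potential oscillation of a pyloric neuron, buried in shot-like
camera noise and slow baseline drift from thermal changes of the light
source.  S/N is quantified in two branches that share the same trigger
list (the first LP spike of every LP burst on the extracellular recording):

* signal branch — remove drift by subtracting a symmetric 3-s sliding mean
  ("DC remove"), average the trace over >10 cycles triggered on LP, and
  take the peak-to-trough amplitude of the averaged cycle;
* noise branch — high-pass the raw trace with the same sliding-mean
  subtraction at a 0.01-s half-window (removing neuronal events, passing
  only fast noise), average it over the same triggers, and take the
  standard deviation over one period after the trigger.

S/N = amplitude / noise SD.  Averaging n cycles attenuates uncorrelated
noise by sqrt(n), which is why the averaged S/N greatly exceeds the
single-sweep value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "TriggeredAverageResult",
    "SnrConfig",
    "dc_remove",
    "highpass_noise_filter",
    "triggered_average",
    "signal_amplitude",
    "noise_sd",
    "compute_snr",
]


@dataclass(frozen=True)
class FluorescenceTrace:
    """Uniformly sampled ROI fluorescence, arbitrary units."""

    values: np.ndarray
    sample_interval: float
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a trace needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) * self.sample_interval

    @property
    def duration(self) -> float:
        return (self.values.size - 1) * self.sample_interval


@dataclass(frozen=True)
class TriggeredAverageResult:
    """Cycle-averaged waveform with the derived S/N quantities.

    ``amplitude`` and ``noise_sd`` are in the trace's fluorescence units;
    ``snr`` is dimensionless.  When the noise estimate is exactly zero the
    ratio is undefined and ``infinite_snr`` is set instead of dividing.
    """

    waveform: np.ndarray
    cycle_period: float
    n_cycles: int
    sample_interval: float
    amplitude: float | None = None
    noise_sd: float | None = None
    snr: float | None = None
    infinite_snr: bool = False


@dataclass(frozen=True)
class SnrConfig:
    """Parameters of the two-branch S/N pipeline (seconds)."""

    dc_half_window: float = 3.0
    noise_time_base: float = 0.01
    min_cycles_warning: int = 10


def _sliding_mean(values: np.ndarray, half_width: int) -> np.ndarray:
    """Symmetric moving mean; the window is truncated at the edges."""
    n = values.size
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_width, 0)
    hi = np.minimum(idx + half_width, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def dc_remove(trace: FluorescenceTrace, half_window: float = 3.0) -> FluorescenceTrace:
    """Subtract the symmetric sliding mean over [t - w, t + w] from each sample.

    Removes slow frequency components and baseline drift while leaving the
    pyloric-timed signal (gain for a sinusoid of angular frequency omega is
    1 - sinc(omega * w)).  Near the trace edges the window is truncated to
    the available samples.  Output has the same length and sampling.
    """
    if half_window <= 0:
        raise ValueError("half_window must be > 0")
    hw = int(round(half_window / trace.sample_interval))
    if hw < 1:
        raise ValueError(
            f"half_window {half_window} s is shorter than one sample "
            f"({trace.sample_interval} s)"
        )
    out = trace.values - _sliding_mean(trace.values, hw)
    return FluorescenceTrace(
        values=out,
        sample_interval=trace.sample_interval,
        start_time=trace.start_time,
        metadata=dict(trace.metadata),
    )


def highpass_noise_filter(
    trace: FluorescenceTrace, time_base: float = 0.01
) -> FluorescenceTrace:
    """Isolate fast noise by sliding-mean subtraction at a short time base.

    Identical to :func:`dc_remove` with ``half_window = time_base``; a
    0.01-s window removes neuronal events (slow waves, spikes and synaptic
    potentials), passing only components faster than roughly 1/time_base.
    """
    return dc_remove(trace, half_window=time_base)


def triggered_average(
    trace: FluorescenceTrace,
    triggers: Sequence[float],
    min_cycles_warning: int = 10,
) -> TriggeredAverageResult:
    """Average fixed-length segments of the trace after each trigger.

    The cycle period is the mean inter-trigger interval; a segment of that
    length is taken after each trigger (nearest-sample alignment) and the
    complete segments are averaged pointwise.  Fewer than
    ``min_cycles_warning`` usable cycles issues a warning, not an error.
    """
    trig = np.asarray(triggers, dtype=float)
    if trig.size < 1:
        raise ValueError("at least one trigger is required")
    if trig.size >= 2:
        period = float(np.mean(np.diff(trig)))
    else:
        period = trace.duration + trace.start_time - trig[0]
    if period <= 0:
        raise ValueError("triggers must be increasing")
    n_seg = int(round(period / trace.sample_interval))
    if n_seg < 1:
        raise ValueError("cycle period shorter than one sample")
    starts = np.round((trig - trace.start_time) / trace.sample_interval).astype(int)
    ok = (starts >= 0) & (starts + n_seg <= trace.values.size)
    starts = starts[ok]
    if starts.size == 0:
        raise ValueError("no trigger leaves a complete segment inside the trace")
    if starts.size < min_cycles_warning:
        warnings.warn(
            f"only {starts.size} complete cycle(s) averaged; "
            f"fewer than {min_cycles_warning} reduces noise suppression",
            stacklevel=2,
        )
    segments = trace.values[starts[:, None] + np.arange(n_seg)[None, :]]
    return TriggeredAverageResult(
        waveform=segments.mean(axis=0),
        cycle_period=period,
        n_cycles=int(starts.size),
        sample_interval=trace.sample_interval,
    )


def signal_amplitude(waveform: np.ndarray) -> float:
    """Peak-to-trough amplitude: max minus min over the averaged cycle."""
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    return float(w.max() - w.min())


def noise_sd(
    trace: FluorescenceTrace,
    triggers: Sequence[float],
    time_base: float = 0.01,
    min_cycles_warning: int = 10,
) -> float:
    """Noise level: SD of the high-passed, cycle-averaged waveform.

    The raw trace is high-pass filtered at ``time_base``, averaged over the
    triggers, and the standard deviation is taken over one period after the
    trigger.  Averaging first means the estimate shrinks like sqrt(n_cycles).
    """
    filtered = highpass_noise_filter(trace, time_base=time_base)
    avg = triggered_average(filtered, triggers, min_cycles_warning=min_cycles_warning)
    return float(np.std(avg.waveform))


def compute_snr(
    trace: FluorescenceTrace,
    triggers: Sequence[float],
    config: SnrConfig | None = None,
) -> TriggeredAverageResult:
    """Run the full two-branch S/N pipeline on one trace.

    Signal branch: dc_remove(dc_half_window) -> triggered average ->
    peak-to-trough amplitude.  Noise branch: highpass(noise_time_base) ->
    triggered average -> SD over one period.  snr = amplitude / noise_sd.
    """
    cfg = config or SnrConfig()
    detrended = dc_remove(trace, half_window=cfg.dc_half_window)
    avg = triggered_average(
        detrended, triggers, min_cycles_warning=cfg.min_cycles_warning
    )
    amplitude = signal_amplitude(avg.waveform)
    sd = noise_sd(
        trace,
        triggers,
        time_base=cfg.noise_time_base,
        min_cycles_warning=cfg.min_cycles_warning,
    )
    if sd == 0.0:
        return TriggeredAverageResult(
            waveform=avg.waveform,
            cycle_period=avg.cycle_period,
            n_cycles=avg.n_cycles,
            sample_interval=avg.sample_interval,
            amplitude=amplitude,
            noise_sd=0.0,
            snr=None,
            infinite_snr=True,
        )
    return TriggeredAverageResult(
        waveform=avg.waveform,
        cycle_period=avg.cycle_period,
        n_cycles=avg.n_cycles,
        sample_interval=avg.sample_interval,
        amplitude=amplitude,
        noise_sd=sd,
        snr=amplitude / sd,
    )
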