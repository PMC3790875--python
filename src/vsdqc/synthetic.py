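"""Synthetic pyloric activity, fluorescence traces and image stacks.

Every downstream stage of the package is exercised against data from this
module, whose ground truth is known by construction.  Three generators:

``generate_rhythm``
    A triphasic pyloric rhythm (PD -> LP -> PY burst order, cycle period
    0.5-2 s) as spike trains: each neuron fires a burst of evenly spaced
    spikes at its intraburst frequency (10-55 Hz) inside a fixed phase
    window of every cycle.  Optional pathologies mimic dye toxicity:
    random missing of intraburst spikes (leaving longer interspike
    intervals) and switching from rhythmic to tonic firing at a low rate.

``render_fluorescence``
    An optical observable for one neuron: a half-cosine slow-wave envelope
    per burst window plus a short Gaussian transient per spike, corrupted
    by white noise and a slow sinusoidal baseline drift (thermal drift of
    the light source), sampled at a fixed interval (default 1.5 ms).

``render_stack``
    8-bit greyscale frames of membrane-ring-stained cells: the ring
    bleaches as exp(-t/tau); upon internalization the cell interior
    brightens toward the ring level along a logistic ramp and a dimmer
    nucleus disk remains distinct.

All randomness flows from explicit integer seeds: one seeded generator per
call, never global state.  Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .optical import FluorescenceTrace
from .photostability import CellRois, ImageStack
from .spike_metrics import SpikeTrain

__all__ = [
    "NeuronSpec",
    "RhythmSpec",
    "PathologySpec",
    "OpticsSpec",
    "DriftSpec",
    "CellSpec",
    "StackSpec",
    "RhythmRealization",
    "generate_rhythm",
    "render_fluorescence",
    "render_stack",
    "cell_masks",
]


@dataclass(frozen=True)
class NeuronSpec:
    """Phase window and intraburst frequency of one neuron.

    Phases are fractions of the cycle in [0, 1); the burst occupies
    [burst_onset_phase, burst_onset_phase + burst_duration_phase].
    """

    burst_onset_phase: float
    burst_duration_phase: float
    intraburst_frequency: float

    def __post_init__(self) -> None:
        if not 0 <= self.burst_onset_phase < 1:
            raise ValueError("burst_onset_phase must be in [0, 1)")
        if self.burst_duration_phase <= 0:
            raise ValueError("burst_duration_phase must be > 0")
        if self.burst_onset_phase + self.burst_duration_phase > 1:
            raise ValueError("burst window must not wrap past the cycle end")
        if self.intraburst_frequency <= 0:
            raise ValueError("intraburst_frequency must be > 0")


def _default_neurons() -> dict[str, NeuronSpec]:
    # Triphasic PD -> LP -> PY with non-overlapping windows and intraburst
    # frequencies inside the canonical 10-55 Hz band.
    return {
        "PD": NeuronSpec(0.0, 0.25, 30.0),
        "LP": NeuronSpec(0.4, 0.3, 20.0),
        "PY": NeuronSpec(0.75, 0.2, 25.0),
    }


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of the synthetic triphasic rhythm."""

    cycle_period: float = 1.0
    neurons: Mapping[str, NeuronSpec] = field(default_factory=_default_neurons)
    n_cycles: int = 20
    period_jitter_sd: float = 0.0
    seed: int = 0
    require_triphasic: bool = True

    def __post_init__(self) -> None:
        if self.cycle_period <= 0:
            raise ValueError("cycle_period must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.period_jitter_sd < 0:
            raise ValueError("period_jitter_sd must be >= 0")
        if self.require_triphasic:
            windows = sorted(
                (n.burst_onset_phase, n.burst_onset_phase + n.burst_duration_phase, lab)
                for lab, n in self.neurons.items()
            )
            for (s0, e0, l0), (s1, e1, l1) in zip(windows, windows[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"burst phase windows of {l0!r} and {l1!r} overlap; "
                        "a triphasic rhythm requires disjoint windows"
                    )


@dataclass(frozen=True)
class PathologySpec:
    """Toxicity-like perturbations applied to one neuron after onset_time.

    ``missing_spike_prob`` drops each intraburst spike independently,
    leaving gaps with longer interspike intervals.  ``tonic_switch``
    replaces rhythmic bursting by regular tonic firing at ``tonic_rate``
    (default inside the 3-9 Hz band between the interburst and intraburst
    bands of a healthy rhythm).
    """

    missing_spike_prob: float = 0.0
    tonic_switch: bool = False
    tonic_rate: float = 5.0
    onset_time: float = 0.0
    target: str = "LP"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_spike_prob <= 1:
            raise ValueError("missing_spike_prob must be a probability")
        if self.tonic_rate <= 0:
            raise ValueError("tonic_rate must be > 0")


@dataclass(frozen=True)
class DriftSpec:
    """Slow baseline drift: one sinusoid plus an optional linear trend."""

    amplitude: float = 0.0
    timescale: float = 30.0  # seconds; >= 10 s so the 3-s DC window removes it
    linear_slope: float = 0.0  # units per second

    def __post_init__(self) -> None:
        if self.timescale <= 0:
            raise ValueError("drift timescale must be > 0")


@dataclass(frozen=True)
class OpticsSpec:
    """Observable model for rendering a fluorescence trace."""

    sample_interval: float = 0.0015
    slow_wave_amplitude: float = 1.0
    spike_transient_amplitude: float = 0.2
    spike_transient_width: float = 0.002  # Gaussian SD, seconds
    noise_sd: float = 0.0
    drift: DriftSpec = field(default_factory=DriftSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CellSpec:
    """Geometry of one ring-stained cell in a synthetic frame."""

    center: tuple[float, float]  # (row, col), pixels
    radius: float
    ring_width: float
    nucleus_radius: float

    def __post_init__(self) -> None:
        if not 0 < self.ring_width < self.radius:
            raise ValueError("need 0 < ring_width < radius")
        if not 0 < self.nucleus_radius < self.radius - self.ring_width:
            raise ValueError("nucleus must fit inside the cell interior")


@dataclass(frozen=True)
class StackSpec:
    """Parameters of a synthetic bleaching / internalization image stack."""

    frame_shape: tuple[int, int] = (64, 64)
    frame_times: tuple[float, ...] = tuple(600.0 * i for i in range(7))
    cells: tuple[CellSpec, ...] = (
        CellSpec(center=(22.0, 22.0), radius=12.0, ring_width=3.0, nucleus_radius=4.0),
        CellSpec(center=(44.0, 42.0), radius=12.0, ring_width=3.0, nucleus_radius=4.0),
    )
    initial_brightness: float = 200.0
    bleach_time_constant: float = 1800.0  # seconds; math.inf disables bleaching
    internalization_onset: float | None = None  # seconds; None = no internalization
    internalization_rate: float = 0.005  # 1/s, logistic ramp steepness
    background: float = 20.0
    pixel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.initial_brightness <= 255:
            raise ValueError("initial_brightness must be a grey value in [0, 255]")
        if not 0 <= self.background <= 255:
            raise ValueError("background must be a grey value in [0, 255]")
        if self.bleach_time_constant <= 0:
            raise ValueError("bleach_time_constant must be > 0")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if len(self.frame_times) < 1:
            raise ValueError("at least one frame time is required")
        if any(b <= a for a, b in zip(self.frame_times, self.frame_times[1:])):
            raise ValueError("frame_times must be strictly increasing")
        h, w = self.frame_shape
        for c in self.cells:
            r, col = c.center
            if not (c.radius <= r <= h - 1 - c.radius and c.radius <= col <= w - 1 - c.radius):
                raise ValueError(f"cell at {c.center} does not fit inside {self.frame_shape}")


@dataclass(frozen=True)
class RhythmRealization:
    """A generated rhythm with its ground truth.

    ``trains`` holds the (possibly pathology-perturbed) spike trains;
    ``burst_windows`` the unperturbed per-cycle burst boundaries
    (start, end) of every neuron; ``cycle_onsets`` the PD-referenced cycle
    start times (length n_cycles + 1: the last entry closes the final
    cycle); ``periods`` the realized cycle periods.
    """

    trains: dict[str, SpikeTrain]
    burst_windows: dict[str, list[tuple[float, float]]]
    cycle_onsets: np.ndarray
    periods: np.ndarray
    spec: RhythmSpec
    pathology: PathologySpec | None = None

    @property
    def duration(self) -> float:
        return float(self.cycle_onsets[-1])


def _burst_spikes(start: float, duration: float, frequency: float) -> np.ndarray:
    """Evenly spaced spikes at `frequency` filling [start, start+duration]."""
    n = int(math.floor(duration * frequency + 1e-9)) + 1
    return start + np.arange(n) / frequency


def generate_rhythm(
    spec: RhythmSpec, pathology: PathologySpec | None = None
) -> RhythmRealization:
    """Generate spike trains of a (possibly perturbed) triphasic rhythm.

    Each cycle i spans [onset_i, onset_i + P_i] where P_i is the cycle
    period plus Gaussian jitter (clipped at 10% of the nominal period so
    periods stay positive).  Within a cycle each neuron emits one burst of
    evenly spaced spikes at its intraburst frequency inside its phase
    window.  Pathologies apply to the target neuron after
    ``pathology.onset_time`` only.
    """
    rng = np.random.default_rng(spec.seed)
    periods = np.full(spec.n_cycles, spec.cycle_period)
    if spec.period_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.period_jitter_sd, size=spec.n_cycles)
        periods = np.maximum(periods + jitter, 0.1 * spec.cycle_period)
    onsets = np.concatenate(([0.0], np.cumsum(periods)))

    trains: dict[str, SpikeTrain] = {}
    windows: dict[str, list[tuple[float, float]]] = {}
    for label, neuron in spec.neurons.items():
        spikes = []
        wins = []
        for i in range(spec.n_cycles):
            start = onsets[i] + neuron.burst_onset_phase * periods[i]
            dur = neuron.burst_duration_phase * periods[i]
            spikes.append(_burst_spikes(start, dur, neuron.intraburst_frequency))
            wins.append((float(start), float(start + dur)))
        trains[label] = SpikeTrain(label, np.concatenate(spikes))
        windows[label] = wins

    if pathology is not None:
        trains[pathology.target] = _apply_pathology(
            trains[pathology.target], pathology, recording_end=float(onsets[-1])
        )

    return RhythmRealization(
        trains=trains,
        burst_windows=windows,
        cycle_onsets=onsets,
        periods=periods,
        spec=spec,
        pathology=pathology,
    )


def _apply_pathology(
    train: SpikeTrain, pathology: PathologySpec, recording_end: float
) -> SpikeTrain:
    rng = np.random.default_rng(pathology.seed)
    t = train.times
    before = t[t < pathology.onset_time]
    after = t[t >= pathology.onset_time]
    if pathology.tonic_switch:
        start = max(pathology.onset_time, 0.0)
        n = int(math.floor((recording_end - start) * pathology.tonic_rate)) + 1
        after = start + np.arange(max(n, 0)) / pathology.tonic_rate
    elif pathology.missing_spike_prob > 0:
        keep = rng.random(after.size) >= pathology.missing_spike_prob
        after = after[keep]
    return SpikeTrain(train.neuron_label, np.concatenate([before, after]))


def render_fluorescence(
    spikes: SpikeTrain,
    optics: OpticsSpec,
    rhythm: RhythmRealization,
    duration: float | None = None,
) -> FluorescenceTrace:
    """Render the optical observable of one neuron.

    Per burst window [s, s+d] the slow wave is a half-cosine arch
    ``A * sin(pi (t - s) / d)``, so the noiseless peak-to-trough amplitude
    of each cycle equals ``A`` exactly.  Each spike adds a Gaussian
    transient; white noise and drift are added last.  An empty spike train
    yields a flat trace (noise + drift only).

    Ground truth (slow-wave amplitude, noise SD) is stored in
    ``trace.metadata`` for recovery tests.
    """
    rng = np.random.default_rng(optics.seed)
    if duration is None:
        duration = rhythm.duration
        if spikes.times.size:
            duration = max(duration, float(spikes.times[-1]) + 0.1)
    n = int(round(duration / optics.sample_interval)) + 1
    t = np.arange(n) * optics.sample_interval
    values = np.zeros(n)

    if optics.slow_wave_amplitude != 0:
        for start, end in rhythm.burst_windows.get(spikes.neuron_label, []):
            d = end - start
            if d <= 0:
                continue
            i0 = np.searchsorted(t, start, side="left")
            i1 = np.searchsorted(t, end, side="right")
            seg = t[i0:i1]
            values[i0:i1] += optics.slow_wave_amplitude * np.sin(
                np.pi * (seg - start) / d
            )

    if optics.spike_transient_amplitude != 0 and spikes.times.size:
        w = optics.spike_transient_width
        half = 4.0 * w
        for ts in spikes.times:
            i0 = np.searchsorted(t, ts - half, side="left")
            i1 = np.searchsorted(t, ts + half, side="right")
            seg = t[i0:i1]
            values[i0:i1] += optics.spike_transient_amplitude * np.exp(
                -0.5 * ((seg - ts) / w) ** 2
            )

    if optics.drift.amplitude != 0:
        values += optics.drift.amplitude * np.sin(
            2 * np.pi * t / optics.drift.timescale
        )
    if optics.drift.linear_slope != 0:
        values += optics.drift.linear_slope * t
    if optics.noise_sd > 0:
        values += rng.normal(0.0, optics.noise_sd, size=n)

    return FluorescenceTrace(
        values=values,
        sample_interval=optics.sample_interval,
        start_time=0.0,
        metadata={
            "neuron_label": spikes.neuron_label,
            "ground_truth_amplitude": float(optics.slow_wave_amplitude),
            "ground_truth_noise_sd": float(optics.noise_sd),
        },
    )


def cell_masks(spec: StackSpec) -> list[CellRois]:
    """Boolean interior / ring masks for every cell of a stack spec.

    The membrane ring is the annulus radius - ring_width <= r <= radius;
    the interior is the open disk inside it (nucleus included).
    """
    h, w = spec.frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    out = []
    for k, c in enumerate(spec.cells):
        r = np.hypot(rows - c.center[0], cols - c.center[1])
        ring = (r >= c.radius - c.ring_width) & (r <= c.radius)
        interior = r < c.radius - c.ring_width
        out.append(CellRois(interior=interior, ring=ring, label=f"cell{k}"))
    return out


def _logistic_ramp(t: np.ndarray, onset: float, rate: float) -> np.ndarray:
    """0 before onset, then rises 0 -> 1 along a logistic curve."""
    g = np.zeros_like(t)
    after = t >= onset
    g[after] = 2.0 / (1.0 + np.exp(-rate * (t[after] - onset))) - 1.0
    return g


def render_stack(spec: StackSpec) -> ImageStack:
    """Render an 8-bit stack of bleaching, optionally internalizing cells.

    Ring brightness at frame time t is
    ``background + (initial_brightness - background) * exp(-t / tau)``.
    After the internalization onset the interior rises from background
    toward the concurrent ring brightness along a logistic ramp; a nucleus
    disk at 50% of the interior's excess brightness stays distinct.
    Gaussian pixel noise is added before clipping to [0, 255] and
    quantizing to uint8.

    Noise-free per-frame ring and interior mean grey values and the
    internalization state are stored in ``stack.metadata["ground_truth"]``.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.frame_times, dtype=float)
    tau = spec.bleach_time_constant
    decay = np.ones_like(t) if math.isinf(tau) else np.exp(-t / tau)
    ring_levels = spec.background + (spec.initial_brightness - spec.background) * decay
    if spec.internalization_onset is not None:
        g = _logistic_ramp(t, spec.internalization_onset, spec.internalization_rate)
    else:
        g = np.zeros_like(t)
    interior_levels = spec.background + (ring_levels - spec.background) * g
    nucleus_levels = spec.background + 0.5 * (interior_levels - spec.background)

    h, w = spec.frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    masks = cell_masks(spec)
    nucleus_masks = []
    for c in spec.cells:
        r = np.hypot(rows - c.center[0], cols - c.center[1])
        nucleus_masks.append(r < c.nucleus_radius)

    frames = np.empty((t.size, h, w), dtype=np.uint8)
    for i in range(t.size):
        img = np.full((h, w), spec.background, dtype=float)
        for cell, nuc in zip(masks, nucleus_masks):
            img[cell.interior] = interior_levels[i]
            img[nuc] = nucleus_levels[i]
            img[cell.ring] = ring_levels[i]
        if spec.pixel_noise_sd > 0:
            img = img + rng.normal(0.0, spec.pixel_noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ground_truth = {
        "ring_mean": ring_levels.tolist(),
        "interior_mean": interior_levels.tolist(),
        "nucleus_mean": nucleus_levels.tolist(),
        "internalized": (g > 0).tolist(),
        "internalization_onset_s": spec.internalization_onset,
        "bleach_time_constant_s": (None if math.isinf(tau) else tau),
    }
    return ImageStack(
        frames=frames,
        frame_times=t,
        metadata={"ground_truth": ground_truth},
    )
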