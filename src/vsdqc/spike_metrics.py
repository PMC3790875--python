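"""Burst detection and pyloric pattern statistics.

The pyloric rhythm of the crustacean stomatogastric ganglion is a
continuously active triphasic motor pattern (PD -> LP -> PY firing order,
cycle period 0.5-2 s).  This module computes the standard descriptive
statistics of that pattern from spike-time tables: cycle period (PD burst
onset to the next PD burst onset), burst duration (first to last spike of a
burst), intraburst frequency ((spikes - 1) / duration), instantaneous
frequency (reciprocal interspike interval), and phase (event time within a
cycle, normalised to the cycle period and referenced to PD burst onset).

Bursts are delimited with a fixed interspike-interval threshold.  The
default of 0.25 s sits between the intraburst band (>= 10 Hz, so ISIs
<= 0.1 s) and the interburst gaps (cycle rates of 0.5-2 Hz, so gaps
>= ~0.5 s), cleanly separating the two time scales of a healthy rhythm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "Burst",
    "DEFAULT_ISI_THRESHOLD",
    "detect_bursts",
    "cycle_periods",
    "intraburst_frequency",
    "instantaneous_frequencies",
    "phases",
    "cycle_metrics",
    "phase_diagram",
]

#: Default burst-separation ISI threshold in seconds (see module docstring).
DEFAULT_ISI_THRESHOLD = 0.25


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron, in seconds, strictly increasing."""

    neuron_label: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"spike times of {self.neuron_label!r} must be strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Burst:
    """A group of consecutive spikes separated by short ISIs."""

    first_spike: float
    last_spike: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.last_spike < self.first_spike:
            raise ValueError("last_spike must be >= first_spike")
        if self.n_spikes < 1:
            raise ValueError("a burst contains at least one spike")

    @property
    def duration(self) -> float:
        return self.last_spike - self.first_spike


def detect_bursts(
    train: SpikeTrain, max_intraburst_isi: float = DEFAULT_ISI_THRESHOLD
) -> list[Burst]:
    """Partition a spike train into bursts by an ISI threshold.

    Consecutive spikes whose interspike interval is <= ``max_intraburst_isi``
    belong to the same burst.  The partition is exhaustive and ordered;
    single-spike bursts are allowed (duration 0).

    Parameters
    ----------
    train
        Spike train with strictly increasing times.
    max_intraburst_isi
        Largest ISI, in seconds, joining two spikes into one burst.

    Returns
    -------
    list of Burst, empty for an empty train.
    """
    if max_intraburst_isi <= 0:
        raise ValueError("max_intraburst_isi must be > 0")
    t = train.times
    if t.size == 0:
        return []
    # split after every gap exceeding the threshold
    gaps = np.flatnonzero(np.diff(t) > max_intraburst_isi)
    starts = np.concatenate(([0], gaps + 1))
    ends = np.concatenate((gaps, [t.size - 1]))
    return [
        Burst(first_spike=float(t[i]), last_spike=float(t[j]), n_spikes=int(j - i + 1))
        for i, j in zip(starts, ends)
    ]


def cycle_periods(pd_burst_onsets: Sequence[float]) -> np.ndarray:
    """Cycle periods as successive differences of PD burst onsets.

    The cycle period of the pyloric rhythm is the duration between the
    onset of one PD burst and the onset of the subsequent PD burst.
    Fewer than two onsets yield an empty result.
    """
    onsets = np.asarray(pd_burst_onsets, dtype=float)
    if onsets.size < 2:
        return np.empty(0)
    periods = np.diff(onsets)
    if np.any(periods <= 0):
        raise ValueError("PD burst onsets must be strictly increasing")
    return periods


def intraburst_frequency(burst: Burst) -> float:
    """Intraburst spike frequency: (spikes per burst - 1) / burst duration.

    Undefined for single-spike bursts or zero duration; returns NaN so that
    degraded rhythms do not abort batch analysis.
    """
    if burst.n_spikes < 2 or burst.duration == 0:
        return float("nan")
    return (burst.n_spikes - 1) / burst.duration


def instantaneous_frequencies(train: SpikeTrain) -> np.ndarray:
    """Instantaneous firing frequencies: reciprocals of interspike intervals.

    Returns n-1 values for n spikes, order preserved; empty for fewer than
    two spikes.  Duplicate timestamps (zero ISI) raise.
    """
    t = train.times
    if t.size < 2:
        return np.empty(0)
    isi = np.diff(t)
    if np.any(isi == 0):
        raise ValueError("duplicate spike times give a zero interspike interval")
    return 1.0 / isi


def phases(
    event_times: Sequence[float], pd_onsets: Sequence[float]
) -> tuple[np.ndarray, int]:
    """Normalise event times to the cycle period, referenced to PD onset.

    For an event t in the half-open cycle [onset_i, onset_{i+1}):
    phase = (t - onset_i) / (onset_{i+1} - onset_i), in [0, 1).
    Events outside [first onset, last onset) are dropped; their count is
    returned and a warning is issued.

    Returns
    -------
    (phases, n_dropped)
    """
    events = np.asarray(event_times, dtype=float)
    onsets = np.asarray(pd_onsets, dtype=float)
    if onsets.size < 2:
        raise ValueError("at least two PD onsets are needed to define a cycle")
    inside = (events >= onsets[0]) & (events < onsets[-1])
    n_dropped = int(events.size - np.count_nonzero(inside))
    if n_dropped:
        warnings.warn(
            f"{n_dropped} event(s) outside the span covered by PD onsets were dropped",
            stacklevel=2,
        )
    ev = events[inside]
    idx = np.searchsorted(onsets, ev, side="right") - 1
    ph = (ev - onsets[idx]) / (onsets[idx + 1] - onsets[idx])
    return ph, n_dropped


def _bursts_in_cycle(bursts: list[Burst], start: float, end: float) -> list[Burst]:
    return [b for b in bursts if start <= b.first_spike < end]


def cycle_metrics(
    trains: Mapping[str, SpikeTrain],
    max_intraburst_isi: float = DEFAULT_ISI_THRESHOLD,
    pd_label: str = "PD",
) -> pd.DataFrame:
    """Per-cycle pattern statistics for every neuron.

    Cycles are delimited by PD burst onsets (half-open, [onset, next onset)).
    For each cycle and neuron the table reports burst duration, spike count,
    intraburst frequency and on/off phases of the first burst whose onset
    falls in the cycle.  Neurons silent in a cycle produce NaN rows.

    Returns a tidy DataFrame with columns: cycle, cycle_start_s,
    cycle_period_s, neuron, burst_duration_s, n_spikes,
    intraburst_frequency_hz, onset_phase, offset_phase.
    """
    if pd_label not in trains:
        raise KeyError(f"no spike train labelled {pd_label!r}")
    pd_bursts = detect_bursts(trains[pd_label], max_intraburst_isi)
    onsets = np.array([b.first_spike for b in pd_bursts])
    if onsets.size < 2:
        raise ValueError("need at least two PD bursts to delimit cycles")
    all_bursts = {
        label: detect_bursts(train, max_intraburst_isi)
        for label, train in trains.items()
    }
    rows = []
    for i in range(onsets.size - 1):
        start, end = onsets[i], onsets[i + 1]
        period = end - start
        for label, bursts in all_bursts.items():
            inside = _bursts_in_cycle(bursts, start, end)
            if inside:
                b = inside[0]
                rows.append(
                    {
                        "cycle": i,
                        "cycle_start_s": start,
                        "cycle_period_s": period,
                        "neuron": label,
                        "burst_duration_s": b.duration,
                        "n_spikes": b.n_spikes,
                        "intraburst_frequency_hz": intraburst_frequency(b),
                        "onset_phase": (b.first_spike - start) / period,
                        "offset_phase": (b.last_spike - start) / period,
                    }
                )
            else:
                rows.append(
                    {
                        "cycle": i,
                        "cycle_start_s": start,
                        "cycle_period_s": period,
                        "neuron": label,
                        "burst_duration_s": np.nan,
                        "n_spikes": 0,
                        "intraburst_frequency_hz": np.nan,
                        "onset_phase": np.nan,
                        "offset_phase": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def phase_diagram(metrics: pd.DataFrame) -> dict:
    """Mean on/off phases per neuron, as plotted in pyloric phase diagrams.

    Takes the output of :func:`cycle_metrics` and returns
    ``{neuron: {"onset_phase": mean, "offset_phase": mean, "n_cycles": k}}``
    over cycles in which the neuron fired.
    """
    out: dict[str, dict[str, float]] = {}
    for label, grp in metrics.groupby("neuron"):
        active = grp.dropna(subset=["onset_phase"])
        out[str(label)] = {
            "onset_phase": float(active["onset_phase"].mean()) if len(active) else float("nan"),
            "offset_phase": float(active["offset_phase"].mean()) if len(active) else float("nan"),
            "n_cycles": int(len(active)),
        }
    return out
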