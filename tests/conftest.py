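"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (O(n^2) loops, explicit
enumeration) so they stay independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from vsdqc.spike_metrics import Burst, SpikeTrain
from vsdqc.synthetic import NeuronSpec, RhythmSpec, generate_rhythm


def brute_force_bursts(times: np.ndarray, threshold: float) -> list[Burst]:
    """O(n^2)-style burst grouping by explicit accumulation."""
    groups: list[list[float]] = []
    for t in times:
        if groups and t - groups[-1][-1] <= threshold:
            groups[-1].append(t)
        else:
            groups.append([t])
    return [Burst(g[0], g[-1], len(g)) for g in groups]


def brute_force_band(freq: float) -> str:
    """Direct enumeration of the printed frequency bands, closed bounds."""
    if 0.0 <= freq <= 2.0:
        return "interburst"
    if 3.0 <= freq <= 9.0:
        return "intermediate"
    if 10.0 <= freq <= 55.0:
        return "intraburst"
    return "other"


def random_train(rng: np.random.Generator, n_max: int = 30) -> SpikeTrain:
    n = int(rng.integers(0, n_max + 1))
    gaps = rng.exponential(0.3, size=n)
    return SpikeTrain("X", np.cumsum(gaps) + 0.01)


@pytest.fixture
def jitter_free_rhythm():
    """A deterministic 1.2-s rhythm with LP onset phase 0.45 (50 cycles)."""
    spec = RhythmSpec(
        cycle_period=1.2,
        neurons={
            "PD": NeuronSpec(0.0, 0.25, 30.0),
            "LP": NeuronSpec(0.45, 0.25, 20.0),
            "PY": NeuronSpec(0.75, 0.2, 25.0),
        },
        n_cycles=50,
        period_jitter_sd=0.0,
        seed=7,
    )
    return generate_rhythm(spec)
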