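# Methods

This note documents the models behind `vsdqc`, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to know about.

## The synthetic rhythm

The generator produces a stylized triphasic pyloric rhythm. Cycle *i*
spans `[onset_i, onset_i + P_i]` with `P_i = P + ε_i`, `ε_i ~ N(0,
jitter_sd²)` clipped at `0.1·P` so periods stay positive. Each neuron
(defaults: PD phases 0.00–0.25 at 30 Hz, LP 0.40–0.70 at 20 Hz, PY
0.75–0.95 at 25 Hz) fires one burst per cycle of evenly spaced spikes at
its intraburst frequency, filling its phase window inclusive of both ends.
Default phase windows are disjoint, giving the PD → LP → PY order; a spec
with overlapping windows is rejected when the triphasic flag is set.

Two pathologies emulate dye toxicity, applied to one target neuron
(default LP) after an onset time: each spike is dropped independently with
probability `missing_spike_prob` (gaps → longer interspike intervals →
instantaneous frequencies entering the otherwise empty 3–9 Hz band), or
the neuron switches to regular tonic firing at `tonic_rate` (default 5 Hz,
chosen inside the 3–9 Hz band).

All generators draw from one `numpy.random.Generator` seeded per call;
seeds are explicit arguments, never global state, so identical seeds give
bit-identical outputs.

### Fluorescence observable

Per burst window `[s, s + d]` the slow wave is a half-cosine arch
`A·sin(π(t − s)/d)`; its noiseless peak-to-trough per cycle equals `A`
exactly, which is what the recovery tests exploit. Each spike adds a
Gaussian transient (default amplitude 0.2, SD 2 ms). Drift is one sinusoid
(default timescale 30 s ≥ 10 s, so the 3-s DC window removes it) plus an
optional linear trend; white Gaussian noise is added last. Sampling
defaults to 1.5 ms. Amplitudes are arbitrary fluorescence units: no
quantitative ΔF/F calibration for STG neurons exists to calibrate against,
so they are free parameters.

### Image stacks

Cells are membrane rings (annulus `r ∈ [R − w, R]`) on a uniform
background. Ring level at frame time *t* is
`background + (B₀ − background)·e^(−t/τ)`; the background offset is kept
so a fully bleached frame settles at the camera floor rather than 0 (with
`background = 0` this is exactly `B₀·e^(−t/τ)`). After an internalization
onset the interior rises from background toward the *concurrent* ring
level along a logistic ramp `2/(1 + e^(−rate(t−onset))) − 1` (0 at the
onset instant, saturating at 1); a nucleus disk at 50% of the interior's
excess brightness stays distinct — the synthetic counterpart of "the
nucleus becomes visible". Gaussian pixel noise is added before clipping to
[0, 255] and quantizing to uint8. Noise-free per-frame ring/interior means
and the internalization state are stored in stack metadata as ground
truth. "Internalization at frame k" in tests means an onset time strictly
between frames k−1 and k, since the ramp is zero at the onset instant
itself.

### What the generator does not emulate

Conductance-based membrane dynamics, realistic extracellular spike
waveforms, camera shot-noise physics (noise is additive Gaussian, not
Poisson), flat-field inhomogeneity, focus drift, and cell-to-cell
variability of staining. Passing tests therefore demonstrate that the
analysis chain recovers what it claims from data obeying its stated
observation model — not that the chain is robust to every artifact of real
recordings.

## Burst detection and pattern statistics

Bursts are maximal runs of spikes with consecutive ISIs ≤ θ (default
θ = 0.25 s, a CLI flag). The two time scales of a healthy rhythm —
intraburst ISIs ≤ 0.1 s (≥ 10 Hz) and interburst gaps ≥ 0.5 s (cycle
rates 0.5–2 Hz) — leave a wide valley around 0.25 s, so the partition is
insensitive to the exact value there. Consequence worth knowing: every
detected multi-spike burst has intraburst frequency ≥ 1/θ.

Cycles are half-open `[onset_i, onset_{i+1})`, phases in `[0, 1)`, so a
boundary event belongs to exactly one cycle and PD onsets map to phase 0.
Single-spike bursts return NaN intraburst frequency rather than raising:
degraded rhythms produce them routinely and batch analysis must continue.
Events outside the span covered by PD onsets are dropped with a warning
and a returned count, never silently.

## The S/N procedure

Fixed pipeline order: `dc_remove(3 s) → triggered average → peak-to-trough
amplitude` and, separately, `highpass(0.01 s) → triggered average → SD
over one period`; `S/N = amplitude / noise SD` (flagged infinite, not
divided, if the noise estimate is exactly 0).

`dc_remove` subtracts the symmetric sliding mean over `[t − w, t + w]`;
`w` is the *half*-window, matching the "average of t − 3 s to t + 3 s"
description of the 3-s case. Its gain on a sinusoid of angular frequency
ω is `1 − sin(ωw)/(ωw)`, the closed form the filter tests check. Edge
handling: the window is truncated to the available samples, keeping output
length equal to input; closed-form assertions use interior samples only.
The 0.01-s variant is the same operation; at 1.5-ms sampling its discrete
half-width is 7 samples.

Triggered averaging uses the mean inter-trigger interval as the cycle
period, nearest-sample trigger alignment (sub-sample interpolation is
unwarranted at 1.5 ms), and only complete segments; fewer than 10 usable
cycles warns but proceeds. The noise SD is computed on the averaged
filtered waveform, not per sweep, so it shrinks like √n_cycles.

Two measurement biases matter when checking the √n law itself:

* the sliding-mean high-pass passes a curvature residual `≈ f″(t)·w²/6`
  of the slow wave — deterministic, so it does *not* average away and
  floors the noise estimate at ~0.3% of `A` for a 1-s cycle with a 0.3-s
  burst (four times smaller at a 2-s cycle);
* the single-sweep peak-to-trough amplitude is biased upward by the
  expected extremes of the noise within one period
  (`≈ σ·√(2 ln n_samples)` per extremum).

The averaging-law experiment therefore runs at a 2-s cycle period (within
the physiological 0.5–2 s range) with σ = 0.02 on unit amplitude, where
the measured 25-cycle gain is ≈ 4.2 against the ideal 5 — the residual
shortfall is exactly these two biases, which affect real recordings the
same way. The parameter-recovery experiment (16 cycles, σ = 0.05, 1-s
cycle) recovers `A/(σ/√16)` with a median relative error of ~6%.

## Photostability

Bleach curves normalize ROI mean grey values to the brightest frame
(usually the first). The exponential fit `a·e^(−t/τ) + b` is an *added*
quantification beyond the normalized curve and is flagged as such in all
outputs; its initial τ comes from the first decay step
(`Δt / ln((m₀−b)/(m₁−b))`), which keeps the least-squares fit out of a
slow-τ local minimum that a naive half-span initialization can fall into.
A constant stack reports no time constant rather than failing. Saturated
pixels (255) are included in means but counted per frame, so clipping is
visible in QC output.

Luminosity histograms are frequency densities over exactly 256 unit-width
bins; they sum to 1 for every frame and ROI by construction.

### Internalization detection

The primary criterion in practice is visual (nucleus visible). The
quantitative surrogate: per frame transition and cell, internalization is
called when the interior mean brightens by more than a threshold while the
membrane ring dims or stays (change ≤ the same tolerance) — dye moving
inward rather than extra staining, which would brighten both. The
histogram right-shift is corroborating output, not the decision variable.

The threshold default is 0.5 grey values — half a quantization step. A
zero threshold cannot work under noise: in a pure-bleach stack the
interior mean is flat, so the sign of its frame-to-frame change is a coin
flip and false positives accrue on every transition. At 0.5, with ~450
interior pixels per cell, the noise SD of the change in an interior mean
at pixel noise SD 2 is ≈ 0.13 grey values, putting the threshold at ~4σ,
while any real internalization step is tens of grey values. ROI masks are
pixel-coordinate, 0-based, row-major; polygon/disk ROIs rasterize with
center-of-pixel inclusion.

## Toxicity profile

Bands are closed on both ends as printed (0–2, 3–9, 10–55 Hz); the gaps
(2–3, 9–10) and the tail (> 55 Hz) go to an explicit "other" class so
occupancies always sum to 1. Each interspike-interval pair contributes one
frequency, assigned to the 60-s window containing its *first* spike
(windows half-open `[T, T + 60)`). Windows without a usable pair are
flagged missing, never silently zeroed, and are classed "extreme"
downstream — mirroring rhythms so degraded that spikes cannot be
identified.

Deviation from the pre-exposure control is the total-variation distance
`½·Σ|p − q|` — bounded in [0, 1], symmetric, zero iff equal. The color
classes of deviation heatmaps are qualitative in origin; here the cut
points are explicit configuration (defaults: none < 0.1 ≤ moderate < 0.3 ≤
strong < 0.6 ≤ severe, with "extreme" reserved for the missing-window
flag). In a healthy synthetic rhythm the LP occupancy is ~1/7 interburst
and ~6/7 intraburst with zero intermediate mass, so healthy deviations
stay in the "none" class; a tonic switch moves all mass to the
intermediate band and drives the distance to ~1.

## Problem sizes

The test suite and the acceptance script use: 16–25-cycle traces at 1.5-ms
sampling for the S/N experiments (20 seeds each); 100-cycle jitter-free
rhythms for exactness checks and 1000 random trains against the
brute-force burst oracle; 7-frame 64×64 stacks (two cells of radius 12)
for bleaching and a 20-stack panel for the internalization confusion
matrix; ~72-minute rhythms (4300 cycles) for the toxicity experiments, 20
healthy and 10 tonic-switch seeds, on an 8-point schedule. The full suite
runs in well under a minute.

## Known limitations

* The burst ISI threshold is a documented choice; no canonical value
  exists and pathological rhythms can blur the two-time-scale assumption
  it relies on.
* The S/N noise floor from slow-wave curvature leakage (above) means
  "noiseless" inputs do not yield exactly zero noise SD — about 0.3% of
  the amplitude at a 1-s cycle.
* The sliding-mean DC-remove is the literal symmetric-window subtraction;
  no attempt is made to replicate any recursive commercial variant, and
  whether such implementations use `w` or `2w` total width is moot here:
  `w` is the half-window throughout.
* The internalization detector assumes per-cell interior and ring masks;
  it does not segment cells, correct illumination, or handle multi-channel
  stacks.
* Whether "relative occurrence" of band frequencies should weight by
  frequency count or spike count is ambiguous; frequencies (ISI-derived
  values) are counted here.
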