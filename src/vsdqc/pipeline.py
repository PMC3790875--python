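"""Configuration handling and the end-to-end pipeline.

A single JSON configuration drives the whole chain
simulate -> bursts -> snr -> bleach -> internalization -> toxicity.
All randomness flows from the one config seed; stage sub-seeds are derived
from it deterministically, so a fixed config reproduces every output
byte-for-byte.  The run report records, per stage, the parameters used and
every file written (with a SHA-256 checksum), plus any warnings raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import io as vio
from .optical import SnrConfig, compute_snr
from .photostability import (
    DEFAULT_SHIFT_THRESHOLD,
    bleach_curve,
    detect_internalization,
    luminosity_histogram,
)
from .spike_metrics import (
    DEFAULT_ISI_THRESHOLD,
    cycle_metrics,
    detect_bursts,
    phase_diagram,
)
from .synthetic import (
    DriftSpec,
    NeuronSpec,
    OpticsSpec,
    PathologySpec,
    RhythmSpec,
    StackSpec,
    CellSpec,
    cell_masks,
    generate_rhythm,
    render_fluorescence,
    render_stack,
)
from .toxicity import (
    DEFAULT_CLASS_CUTS,
    DEFAULT_SCHEDULE,
    BandScheme,
    band_occupancy,
    deviation_from_control,
)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "spec_from_dict",
    "spec_to_dict",
]

log = logging.getLogger("vsdqc")

KNOWN_STAGES = ("simulate", "bursts", "snr", "bleach", "internalization", "toxicity")


def _build(cls, data: Mapping[str, Any], nested: Mapping[str, Any] | None = None):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    nested = nested or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in nested and value is not None:
            kwargs[key] = nested[key](value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _neurons_from_dict(d: Mapping[str, Any]) -> dict[str, NeuronSpec]:
    return {label: _build(NeuronSpec, nd) for label, nd in d.items()}


def spec_from_dict(kind: str, data: Mapping[str, Any]):
    """Reconstruct a generator spec from its JSON form; unknown keys reject."""
    builders = {
        "rhythm": lambda d: _build(RhythmSpec, d, {"neurons": _neurons_from_dict}),
        "pathology": lambda d: _build(PathologySpec, d),
        "optics": lambda d: _build(OpticsSpec, d, {"drift": lambda x: _build(DriftSpec, x)}),
        "stack": lambda d: _build(
            StackSpec,
            {
                **d,
                **(
                    {"frame_shape": tuple(d["frame_shape"])}
                    if "frame_shape" in d
                    else {}
                ),
                **(
                    {"frame_times": tuple(d["frame_times"])}
                    if "frame_times" in d
                    else {}
                ),
                **(
                    {
                        "cells": tuple(
                            _build(
                                CellSpec,
                                {**c, "center": tuple(c["center"])},
                            )
                            for c in d["cells"]
                        )
                    }
                    if "cells" in d
                    else {}
                ),
            },
        ),
    }
    if kind not in builders:
        raise ValueError(f"unknown spec kind {kind!r}")
    return builders[kind](data)


def spec_to_dict(spec) -> dict:
    """JSON-serializable form of any generator spec (lossless round-trip)."""
    return json.loads(json.dumps(dataclasses.asdict(spec)))


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of an end-to-end run."""

    seed: int = 0
    stages: tuple[str, ...] = KNOWN_STAGES
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # pre-existing files per kind
    bursts: dict = field(default_factory=dict)
    snr: dict = field(default_factory=dict)
    bleach: dict = field(default_factory=dict)
    internalization: dict = field(default_factory=dict)
    toxicity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = dict(data)
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return _build(cls, cfg)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class RunReport:
    """Provenance of one pipeline run."""

    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
            "outputs": self.outputs,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(report: RunReport, path: Path) -> str:
    report.outputs[path.name] = _sha256(path)
    return path.name


def _validate_dependencies(config: PipelineConfig) -> None:
    """Fail before execution if a stage's inputs can be produced by no one."""
    produces_spikes = "simulate" in config.stages or "spikes" in config.inputs
    produces_trace = "simulate" in config.stages or "trace" in config.inputs
    produces_stack = "simulate" in config.stages or "stack" in config.inputs
    needs = {
        "bursts": produces_spikes,
        "toxicity": produces_spikes,
        "snr": produces_trace and produces_spikes,
        "bleach": produces_stack,
        "internalization": produces_stack,
    }
    for stage in config.stages:
        if stage in needs and not needs[stage]:
            raise ValueError(
                f"stage {stage!r} requires inputs that no earlier stage or "
                "'inputs' entry provides"
            )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the configured stages in order and write a JSON report.

    Any stage failure aborts the run with the stage name in the error.
    Warnings raised inside stages are collected into the report, never
    suppressed.
    """
    _validate_dependencies(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    state: dict[str, Any] = {}

    if "spikes" in config.inputs:
        state["trains"] = vio.read_spikes(config.inputs["spikes"])
    if "trace" in config.inputs:
        state["traces"] = vio.read_trace(config.inputs["trace"])
    if "stack" in config.inputs:
        state["stack"] = vio.read_stack(config.inputs["stack"])
        if "roi" in config.inputs:
            state["rois"] = vio.read_roi(
                config.inputs["roi"], shape=state["stack"].frames.shape[1:]
            )

    for stage in config.stages:
        log.info("stage=%s starting", stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                params = _STAGE_RUNNERS[stage](config, state, out, report)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for w in caught:
            report.warnings.append(f"{stage}: {w.message}")
        report.stages.append({"stage": stage, "parameters": params})
        log.info("stage=%s done params=%s", stage, params)

    report_path = out / "run_report.json"
    report_path.write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
    )
    return report


# ------------------------------------------------------------- stage runners

def _stage_simulate(config, state, out: Path, report) -> dict:
    block = dict(config.simulate)
    rhythm_spec = spec_from_dict("rhythm", {**block.get("rhythm", {}), "seed": config.seed})
    pathology = (
        spec_from_dict("pathology", {**block["pathology"], "seed": config.seed + 1})
        if block.get("pathology")
        else None
    )
    realization = generate_rhythm(rhythm_spec, pathology)
    state["realization"] = realization
    state["trains"] = realization.trains
    spikes_path = out / "spikes.csv"
    vio.write_spikes(spikes_path, realization.trains)
    _register(report, spikes_path)

    optics = spec_from_dict("optics", {**block.get("optics", {}), "seed": config.seed + 2})
    neuron = block.get("trace_neuron", "LP")
    trace = render_fluorescence(realization.trains[neuron], optics, realization)
    state["traces"] = {neuron: trace}
    trace_path = out / "trace.csv"
    vio.write_trace(trace_path, {neuron: trace})
    _register(report, trace_path)

    stack_spec = spec_from_dict("stack", {**block.get("stack", {}), "seed": config.seed + 3})
    stack = render_stack(stack_spec)
    state["stack"] = stack
    state["rois"] = {c.label: c for c in cell_masks(stack_spec)}
    stack_path = out / "stack.tiff"
    vio.write_stack(stack_path, stack)
    _register(report, stack_path)
    _register(report, stack_path.with_suffix(".tiff.json"))
    return {
        "rhythm": spec_to_dict(rhythm_spec),
        "pathology": spec_to_dict(pathology) if pathology else None,
        "optics": spec_to_dict(optics),
        "stack": spec_to_dict(stack_spec),
    }


def _stage_bursts(config, state, out: Path, report) -> dict:
    params = {
        "isi_threshold": config.bursts.get("isi_threshold", DEFAULT_ISI_THRESHOLD),
        "pd_label": config.bursts.get("pd_label", "PD"),
    }
    metrics = cycle_metrics(
        state["trains"],
        max_intraburst_isi=params["isi_threshold"],
        pd_label=params["pd_label"],
    )
    metrics_path = out / "cycle_metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    _register(report, metrics_path)
    diagram_path = out / "phase_diagram.json"
    diagram_path.write_text(
        json.dumps(phase_diagram(metrics), indent=1), encoding="utf-8"
    )
    _register(report, diagram_path)
    state["cycle_metrics"] = metrics
    return params


def _stage_snr(config, state, out: Path, report) -> dict:
    block = config.snr
    trigger_neuron = block.get("trigger_neuron", "LP")
    isi_threshold = block.get("isi_threshold", DEFAULT_ISI_THRESHOLD)
    cfg = SnrConfig(
        dc_half_window=block.get("dc_window", 3.0),
        noise_time_base=block.get("noise_timebase", 0.01),
    )
    bursts = detect_bursts(state["trains"][trigger_neuron], isi_threshold)
    triggers = [b.first_spike for b in bursts]
    name, trace = next(iter(state["traces"].items()))
    result = compute_snr(trace, triggers, cfg)
    result_path = out / "snr.json"
    result_path.write_text(
        json.dumps(
            {
                "roi": name,
                "amplitude": result.amplitude,
                "noise_sd": result.noise_sd,
                "snr": result.snr,
                "infinite_snr": result.infinite_snr,
                "n_cycles": result.n_cycles,
                "cycle_period_s": result.cycle_period,
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    _register(report, result_path)
    wf_path = out / "snr_waveform.csv"
    np.savetxt(
        wf_path,
        result.waveform,
        delimiter=",",
        header="averaged_waveform",
        comments="",
    )
    _register(report, wf_path)
    state["snr"] = result
    return {
        "trigger_neuron": trigger_neuron,
        "dc_window": cfg.dc_half_window,
        "noise_timebase": cfg.noise_time_base,
    }


def _soma_roi(state) -> np.ndarray:
    rois = state.get("rois", {})
    if "soma" in rois:
        return rois["soma"]
    masks = [r.interior | r.ring for r in rois.values() if hasattr(r, "interior")]
    if not masks:
        raise ValueError("no soma ROI and no per-cell masks available")
    return np.logical_or.reduce(masks)


def _stage_bleach(config, state, out: Path, report) -> dict:
    stack = state["stack"]
    roi = _soma_roi(state)
    curve = bleach_curve(stack, roi, fit=config.bleach.get("fit", True))
    import pandas as pd

    curve_path = out / "bleach_curve.csv"
    pd.DataFrame(
        {
            "time_s": curve.times,
            "mean_grey": curve.mean_grey,
            "normalized": curve.normalized,
            "n_saturated": curve.n_saturated,
        }
    ).to_csv(curve_path, index=False)
    _register(report, curve_path)
    hist_path = out / "luminosity_histograms.csv"
    hists = np.vstack(
        [luminosity_histogram(f, roi).density for f in stack.frames]
    )
    pd.DataFrame(
        hists, index=pd.Index(stack.frame_times, name="time_s")
    ).to_csv(hist_path)
    _register(report, hist_path)
    state["bleach_curve"] = curve
    return {
        "fit": config.bleach.get("fit", True),
        "fitted_time_constant_s": curve.fitted_time_constant,
        "fit_is_added_quantification": True,
    }


def _stage_internalization(config, state, out: Path, report) -> dict:
    stack = state["stack"]
    cells = [r for r in state.get("rois", {}).values() if hasattr(r, "interior")]
    threshold = config.internalization.get("threshold", DEFAULT_SHIFT_THRESHOLD)
    call = detect_internalization(stack, cells, threshold=threshold)
    call_path = out / "internalization.json"
    call_path.write_text(
        json.dumps(
            {
                "detected": call.detected,
                "onset_frame": call.onset_frame,
                "shift_statistic": call.shift_statistic.tolist(),
                "criterion": call.criterion,
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    _register(report, call_path)
    state["internalization"] = call
    return {"threshold": threshold, "n_cells": len(cells)}


def _stage_toxicity(config, state, out: Path, report) -> dict:
    import pandas as pd

    block = config.toxicity
    schedule = tuple(block.get("schedule", DEFAULT_SCHEDULE))
    window = block.get("window", 60.0)
    cuts = tuple(block.get("cuts", DEFAULT_CLASS_CUTS))
    neuron = block.get("neuron", "LP")
    scheme = BandScheme()
    train = state["trains"][neuron]
    profile = band_occupancy(train, schedule=schedule, window=window, scheme=scheme)
    if "control" in config.inputs:
        control_trains = vio.read_spikes(config.inputs["control"])
        control_profile = band_occupancy(
            control_trains[neuron], schedule=(0.0,), window=window, scheme=scheme
        )
        control = control_profile.occupancy.iloc[0]
    else:
        control = profile.occupancy.iloc[0]
    dev = deviation_from_control(profile, control, cuts=cuts)
    occ_path = out / "band_occupancy.csv"
    profile.occupancy.assign(
        missing=profile.missing, n_frequencies=profile.n_frequencies
    ).to_csv(occ_path)
    _register(report, occ_path)
    dev_path = out / "deviation.json"
    dev_path.write_text(
        json.dumps(
            {
                "time_s": dev.deviation.index.tolist(),
                "tv_deviation": [
                    None if not np.isfinite(v) else float(v) for v in dev.deviation
                ],
                "class": dev.deviation_class.tolist(),
                "cuts": list(dev.cuts),
                "control": {k: float(v) for k, v in dev.control.items()},
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    _register(report, dev_path)
    state["deviation"] = dev
    return {"schedule": list(schedule), "window": window, "cuts": list(cuts), "neuron": neuron}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "bursts": _stage_bursts,
    "snr": _stage_snr,
    "bleach": _stage_bleach,
    "internalization": _stage_internalization,
    "toxicity": _stage_toxicity,
}
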