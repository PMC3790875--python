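"""Readers and writers for the package's on-disk formats.

Conventions, enforced by every reader: times are seconds as floating
point; frame and sample indices are 0-based; CSV files are comma-separated
UTF-8 with a mandatory header row; image stacks are multi-page 8-bit
greyscale TIFF with a JSON sidecar carrying frame times and ground-truth
metadata; ROI files are JSON.  All writers round-trip losslessly through
their paired reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .optical import FluorescenceTrace
from .photostability import CellRois, ImageStack
from .spike_metrics import SpikeTrain

__all__ = [
    "read_spikes",
    "write_spikes",
    "read_trace",
    "write_trace",
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi",
    "rasterize_roi",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


# ---------------------------------------------------------------- spikes

def write_spikes(path: str | Path, trains: Mapping[str, SpikeTrain]) -> None:
    """Write spike trains as CSV with columns (neuron, time_s)."""
    frames = [
        pd.DataFrame({"neuron": label, "time_s": train.times})
        for label, train in trains.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes(path: str | Path) -> dict[str, SpikeTrain]:
    """Read a (neuron, time_s) spike CSV into per-neuron trains."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = {"neuron", "time_s"}
    if not expected.issubset(df.columns):
        raise FormatError(
            f"{path}: spike CSV must have columns {sorted(expected)}, "
            f"found {list(df.columns)}"
        )
    out = {}
    for label, grp in df.groupby("neuron", sort=False):
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise FormatError(
                f"{path}: times of neuron {label!r} not strictly increasing "
                f"at entry {bad}"
            )
        out[str(label)] = SpikeTrain(str(label), times)
    return out


# ----------------------------------------------------------------- trace

def write_trace(
    path: str | Path, traces: Mapping[str, FluorescenceTrace] | FluorescenceTrace
) -> None:
    """Write ROI traces as CSV; the header row carries sample_interval_s.

    Layout: first line ``# sample_interval_s=<dt> start_time_s=<t0>``,
    then a header row with one column per ROI, then the samples.  All
    traces must share sampling and length.
    """
    if isinstance(traces, FluorescenceTrace):
        traces = {"roi_0": traces}
    items = list(traces.items())
    dt = items[0][1].sample_interval
    t0 = items[0][1].start_time
    n = items[0][1].values.size
    for name, tr in items:
        if tr.sample_interval != dt or tr.start_time != t0 or tr.values.size != n:
            raise ValueError(f"trace {name!r} has mismatched sampling or length")
    df = pd.DataFrame({name: tr.values for name, tr in items})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_interval_s={dt!r} start_time_s={t0!r}\n")
        df.to_csv(fh, index=False)


def read_trace(path: str | Path) -> dict[str, FluorescenceTrace]:
    """Read a trace CSV written by :func:`write_trace`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("# sample_interval_s="):
            raise FormatError(
                f"{path}: first line must carry '# sample_interval_s=...', "
                f"got {first[:60]!r}"
            )
        fields = dict(
            kv.split("=", 1) for kv in first.lstrip("# ").split() if "=" in kv
        )
        try:
            dt = float(fields["sample_interval_s"])
            t0 = float(fields.get("start_time_s", "0.0"))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: malformed metadata line: {first!r}") from exc
        df = pd.read_csv(fh)
    return {
        str(col): FluorescenceTrace(
            values=df[col].to_numpy(dtype=float), sample_interval=dt, start_time=t0
        )
        for col in df.columns
    }


# ----------------------------------------------------------------- stack

def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a multi-page 8-bit TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = {
        "frame_times_s": stack.frame_times.tolist(),
        "exposure_s": stack.exposure,
        "metadata": stack.metadata,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8"
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF and its JSON sidecar; rejects non-8-bit data."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype != np.uint8:
        raise FormatError(
            f"{path}: frames are {frames.dtype}; stacks must be 8-bit "
            "greyscale (uint8, grey values 0-255)"
        )
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
    if "frame_times_s" not in sidecar:
        raise FormatError(f"{sidecar_path}: missing 'frame_times_s'")
    return ImageStack(
        frames=frames,
        frame_times=np.asarray(sidecar["frame_times_s"], dtype=float),
        exposure=sidecar.get("exposure_s"),
        metadata=sidecar.get("metadata", {}),
    )


# ------------------------------------------------------------------- ROI

def rasterize_roi(shape: tuple[int, int], roi: Mapping) -> np.ndarray:
    """Rasterize a JSON ROI description into a boolean mask.

    Supported shapes (pixel coordinates, 0-based, row-major,
    center-of-pixel inclusion):

    * ``{"type": "rect", "top": r0, "left": c0, "height": h, "width": w}``
    * ``{"type": "disk", "center": [r, c], "radius": x}``
    * ``{"type": "annulus", "center": [r, c], "inner_radius": a, "outer_radius": b}``
    * ``{"type": "pixels", "rows": [...], "cols": [...]}``
    """
    h, w = shape
    kind = roi.get("type")
    if kind == "rect":
        mask = np.zeros(shape, dtype=bool)
        r0, c0 = int(roi["top"]), int(roi["left"])
        mask[r0 : r0 + int(roi["height"]), c0 : c0 + int(roi["width"])] = True
        return mask
    rows, cols = np.mgrid[0:h, 0:w]
    if kind == "disk":
        r = np.hypot(rows - roi["center"][0], cols - roi["center"][1])
        return r < float(roi["radius"])
    if kind == "annulus":
        r = np.hypot(rows - roi["center"][0], cols - roi["center"][1])
        return (r >= float(roi["inner_radius"])) & (r <= float(roi["outer_radius"]))
    if kind == "pixels":
        mask = np.zeros(shape, dtype=bool)
        mask[np.asarray(roi["rows"], dtype=int), np.asarray(roi["cols"], dtype=int)] = True
        return mask
    raise FormatError(f"unknown ROI type {kind!r}")


def write_roi(path: str | Path, rois: Mapping) -> None:
    """Write a named-ROI JSON document."""
    Path(path).write_text(json.dumps(rois, indent=1), encoding="utf-8")


def read_roi(
    path: str | Path, shape: tuple[int, int] | None = None
) -> dict:
    """Read a named-ROI JSON document.

    The document maps names to ROI descriptions; per-cell entries may nest
    ``{"interior": ..., "ring": ...}``.  With ``shape`` given, descriptions
    are rasterized: nested cell entries become :class:`CellRois`, flat
    entries become boolean masks.
    """
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: ROI document must be a JSON object")
    if shape is None:
        return doc
    out: dict = {}
    for name, entry in doc.items():
        if isinstance(entry, dict) and "interior" in entry and "ring" in entry:
            out[name] = CellRois(
                interior=rasterize_roi(shape, entry["interior"]),
                ring=rasterize_roi(shape, entry["ring"]),
                label=name,
            )
        else:
            out[name] = rasterize_roi(shape, entry)
    return out
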