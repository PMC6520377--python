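"""Readers and writers for the pipeline's on-disk formats.

Formats:

* trace CSV — columns ``time_s``, ``signal``, ``stim_flag`` (1 at stimulus
  onsets, 0 elsewhere); pacing rate inferred from stimulus intervals.
* MEA HDF5 — dataset ``traces`` (channels x samples, uV) with root attributes
  ``fs_hz``, ``pitch_um``, ``rows``, ``cols``, ``omitted_corners``,
  ``stim_channel`` and ``stim_times``; channels are row-major over the grid
  positions present.  A CSV fallback stores the wide matrix with the same
  metadata in a JSON sidecar.
* TIFF — single-channel image with the pixel size encoded in the resolution
  tags (pixels per micrometre).
* JSON — stretch calibrations and generator ground-truth sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .geometry import StretchCalibration
from .mea import MEALayout, MEARecording, build_mea_layout
from .synthetic import GroundTruth
from .traces import TransientTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_mea_h5",
    "read_mea_h5",
    "write_mea_csv",
    "read_mea_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_calibration_json",
    "read_calibration_json",
    "write_ground_truth_json",
]


# ---------------------------------------------------------------------------
# trace CSV


def write_trace_csv(path, trace: TransientTrace) -> None:
    stim_flag = np.zeros(trace.signal.size, dtype=int)
    t0 = trace.time_s[0]
    for s in trace.stim_times:
        idx = int(round((s - t0) * trace.fs_hz))
        if 0 <= idx < stim_flag.size:
            stim_flag[idx] = 1
    pd.DataFrame(
        {"time_s": trace.time_s, "signal": trace.signal, "stim_flag": stim_flag}
    ).to_csv(path, index=False)


def read_trace_csv(path, pacing_rate_hz: float | None = None) -> TransientTrace:
    frame = pd.read_csv(path)
    for col in ("time_s", "signal", "stim_flag"):
        if col not in frame.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    time = frame["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise ValueError("trace too short")
    fs = 1.0 / float(np.median(np.diff(time)))
    stim_times = list(time[frame["stim_flag"].to_numpy() > 0])
    if pacing_rate_hz is None:
        if len(stim_times) >= 2:
            pacing_rate_hz = 1.0 / float(np.median(np.diff(stim_times)))
        else:
            raise ValueError(
                "pacing rate cannot be inferred from fewer than two stimuli; "
                "pass pacing_rate_hz"
            )
    return TransientTrace(
        time_s=time,
        signal=frame["signal"].to_numpy(dtype=float),
        fs_hz=fs,
        stim_times=stim_times,
        pacing_rate_hz=pacing_rate_hz,
    )


# ---------------------------------------------------------------------------
# MEA recordings


def _layout_meta(layout: MEALayout) -> dict:
    omit_corners = layout.omitted_positions == frozenset(
        {
            (0, 0),
            (0, layout.cols - 1),
            (layout.rows - 1, 0),
            (layout.rows - 1, layout.cols - 1),
        }
    )
    if not omit_corners and layout.omitted_positions:
        raise ValueError("only corner-omitted or full-grid layouts are serialisable")
    return {
        "rows": layout.rows,
        "cols": layout.cols,
        "pitch_um": layout.pitch_um,
        "omitted_corners": omit_corners,
    }


def _layout_from_meta(meta: dict) -> MEALayout:
    return build_mea_layout(
        rows=int(meta["rows"]),
        cols=int(meta["cols"]),
        pitch_um=float(meta["pitch_um"]),
        omit_corners=bool(meta["omitted_corners"]),
    )


def write_mea_h5(path, recording: MEARecording) -> None:
    meta = _layout_meta(recording.layout)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=recording.traces)
        fh.attrs["fs_hz"] = recording.fs_hz
        fh.attrs["stim_channel"] = recording.stim_channel
        fh.attrs["stim_times"] = np.asarray(recording.stim_times)
        for key, value in meta.items():
            fh.attrs[key] = value


def read_mea_h5(path) -> MEARecording:
    with h5py.File(path, "r") as fh:
        traces = fh["traces"][()]
        attrs = dict(fh.attrs)
    return MEARecording(
        traces=traces,
        fs_hz=float(attrs["fs_hz"]),
        layout=_layout_from_meta(attrs),
        stim_channel=int(attrs["stim_channel"]),
        stim_times=[float(s) for s in np.atleast_1d(attrs["stim_times"])],
    )


def write_mea_csv(path, recording: MEARecording) -> None:
    """CSV fallback: wide channel-per-row matrix plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(recording.traces).to_csv(path, index=False, header=False)
    meta = _layout_meta(recording.layout) | {
        "fs_hz": recording.fs_hz,
        "stim_channel": recording.stim_channel,
        "stim_times": list(recording.stim_times),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_mea_csv(path) -> MEARecording:
    path = Path(path)
    traces = pd.read_csv(path, header=None).to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MEARecording(
        traces=traces,
        fs_hz=float(meta["fs_hz"]),
        layout=_layout_from_meta(meta),
        stim_channel=int(meta["stim_channel"]),
        stim_times=[float(s) for s in meta["stim_times"]],
    )


# ---------------------------------------------------------------------------
# images


def write_image_tiff(path, pixels: np.ndarray, pixel_um: float) -> None:
    """Write a single-channel TIFF with the pixel size in the resolution tags
    (pixels per micrometre, resolution unit left unset/none)."""
    if pixel_um <= 0:
        raise ValueError("pixel size must be positive")
    tifffile.imwrite(
        path,
        np.asarray(pixels, dtype=np.float32),
        resolution=(1.0 / pixel_um, 1.0 / pixel_um),
    )


def read_image_tiff(path, pixel_um: float | None = None) -> tuple[np.ndarray, float]:
    """Read a TIFF and its pixel size (um/px) from the resolution tags; an
    explicit ``pixel_um`` overrides the metadata."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        if pixel_um is None:
            tag = page.tags.get("XResolution")
            if tag is None:
                raise ValueError("TIFF has no resolution metadata; pass pixel_um")
            num, den = tag.value
            if num == 0:
                raise ValueError("invalid zero resolution tag; pass pixel_um")
            pixel_um = den / num
    return np.asarray(pixels, dtype=float), float(pixel_um)


# ---------------------------------------------------------------------------
# JSON records


def write_calibration_json(path, calibration: StretchCalibration) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope": calibration.slope,
                "intercept": calibration.intercept,
                "r_squared": calibration.r_squared,
                "n": calibration.n,
            },
            indent=1,
        )
    )


def read_calibration_json(path) -> StretchCalibration:
    data = json.loads(Path(path).read_text())
    return StretchCalibration(
        slope=float(data["slope"]),
        intercept=float(data["intercept"]),
        r_squared=float(data["r_squared"]),
        n=int(data["n"]),
    )


def _jsonable(value):
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return _jsonable(dataclasses.asdict(value))
    return value


def write_ground_truth_json(path, truth: GroundTruth) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "generator_name": truth.generator_name,
                "parameters": _jsonable(truth.parameters),
                "derived_truths": _jsonable(truth.derived_truths),
            },
            indent=1,
        )
    )
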