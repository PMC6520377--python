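"""Multielectrode-array activation mapping and conduction-velocity estimation.

A myocardial slice rests on a grid of extracellular electrodes (the standard
array is 8 x 8 with a 700 um pitch and the four corners absent, giving 60
channels).  Point stimulation at one electrode launches an activation
wavefront; the local activation time at each electrode is taken as the time of
maximum absolute field-potential amplitude after a post-stimulus blanking
interval.  Conduction velocity along a chosen axis (longitudinal or transverse
to the myofibril direction) is the inverse slope of a least-squares fit of
activation time against distance along that axis, using only electrodes lying
in a narrow angular sector about the axis through the stimulation site.  The
ratio of longitudinal to transverse velocity quantifies conduction anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MEALayout",
    "MEARecording",
    "ActivationMap",
    "ConductionResult",
    "build_mea_layout",
    "detect_activation_time",
    "activation_map",
    "conduction_velocity",
    "anisotropy_ratio",
]

_UM_PER_CM = 1.0e4


@dataclass(frozen=True)
class MEALayout:
    """Geometry of a rectangular electrode grid.

    Coordinates: x runs along columns, y along rows, origin at the top-left
    grid position, units um.  Channel ids are 0-based, assigned row-major over
    the grid positions that are present.
    """

    rows: int
    cols: int
    pitch_um: float
    omitted_positions: frozenset[tuple[int, int]]
    #: (channel id, x um, y um) per electrode, row-major.
    electrode_positions: tuple[tuple[int, float, float], ...]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_positions)

    @property
    def side_span_um(self) -> float:
        """Distance between the outermost columns (= rows for a square grid)."""
        return (self.cols - 1) * self.pitch_um

    def position_of(self, channel: int) -> tuple[float, float]:
        for cid, x, y in self.electrode_positions:
            if cid == channel:
                return x, y
        raise KeyError(f"channel {channel} not in layout")

    def __contains__(self, channel: int) -> bool:
        return any(cid == channel for cid, _, _ in self.electrode_positions)


def build_mea_layout(
    rows: int = 8, cols: int = 8, pitch_um: float = 700.0, omit_corners: bool = True
) -> MEALayout:
    """Regular grid layout; the standard array omits the four corner positions."""
    if rows < 2 or cols < 2:
        raise ValueError("layout needs at least 2 rows and 2 columns")
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    omitted: set[tuple[int, int]] = set()
    if omit_corners:
        omitted = {(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1)}
    positions = []
    cid = 0
    for r in range(rows):
        for c in range(cols):
            if (r, c) in omitted:
                continue
            positions.append((cid, c * pitch_um, r * pitch_um))
            cid += 1
    return MEALayout(
        rows=rows,
        cols=cols,
        pitch_um=pitch_um,
        omitted_positions=frozenset(omitted),
        electrode_positions=tuple(positions),
    )


@dataclass
class MEARecording:
    """Multichannel field-potential recording with grid metadata.

    ``traces`` is (n_channels, n_samples) in uV; channel order follows the
    layout's channel ids.  ``stim_times`` are stimulus onsets in seconds from
    the start of the recording.
    """

    traces: np.ndarray
    fs_hz: float
    layout: MEALayout
    stim_channel: int
    stim_times: list[float]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (channels x samples)")
        if self.traces.shape[0] != self.layout.n_electrodes:
            raise ValueError(
                f"{self.traces.shape[0]} traces for {self.layout.n_electrodes} electrodes"
            )
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.stim_channel not in self.layout:
            raise ValueError(f"stimulation channel {self.stim_channel} not in layout")
        if not self.stim_times:
            raise ValueError("at least one stimulus time is required")

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.fs_hz


@dataclass
class ActivationMap:
    """Local activation times (s, relative to the stimulus) per electrode.

    ``quality_flags`` marks each channel ``"ok"``, ``"missing"`` (detection
    failed the SNR gate) or ``"stim"`` (the stimulation electrode, excluded).
    """

    activation_time: dict[int, float]
    stim_channel: int
    quality_flags: dict[int, str] = field(default_factory=dict)

    @property
    def n_detected(self) -> int:
        return len(self.activation_time)


@dataclass(frozen=True)
class ConductionResult:
    cv_cm_s: float
    direction_deg: float
    n_electrodes_used: int
    fit_residual_s: float

    def __post_init__(self) -> None:
        if self.cv_cm_s <= 0:
            raise ValueError("conduction velocity must be positive")


def detect_activation_time(
    trace: np.ndarray,
    fs_hz: float,
    stim_time: float,
    blanking_ms: float = 2.0,
    window_ms: float = 80.0,
    method: str = "max_amplitude",
    snr_min: float = 5.0,
) -> float | None:
    """Local activation time (s after the stimulus) on one channel, or None.

    The search window starts ``blanking_ms`` after the stimulus (to skip the
    stimulus artifact) and lasts ``window_ms``.  ``method`` is
    ``"max_amplitude"`` (time of maximum absolute signal, the conventional
    criterion) or ``"max_downstroke"`` (time of the steepest negative
    deflection).  A detection is rejected (None) when the peak fails an SNR
    gate of ``snr_min`` times the robust noise level estimated from the
    pre-stimulus segment (or the window itself when no pre-stimulus samples
    exist).  Ties resolve to the earlier sample.
    """
    trace = np.asarray(trace, dtype=float)
    start = int(round((stim_time + blanking_ms * 1e-3) * fs_hz))
    stop = min(trace.size, int(round((stim_time + (blanking_ms + window_ms) * 1e-3) * fs_hz)))
    if start < 0 or start >= trace.size or stop <= start:
        raise ValueError("detection window falls outside the trace")
    window = trace[start:stop]

    pre_stop = int(round(stim_time * fs_hz))
    reference = trace[:pre_stop] if pre_stop >= 10 else window
    baseline = float(np.median(reference))
    noise = 1.4826 * float(np.median(np.abs(reference - baseline)))

    centred = window - baseline
    if method == "max_amplitude":
        idx = int(np.argmax(np.abs(centred)))
        peak = abs(centred[idx])
        if idx in (0, centred.size - 1):
            # an extremum on the window boundary is a truncated deflection
            # (e.g. a spike straddling the blanking interval), not a peak
            return None
    elif method == "max_downstroke":
        diff = np.diff(centred)
        if diff.size == 0:
            return None
        idx = int(np.argmin(diff))
        peak = float(np.max(np.abs(centred)))
    else:
        raise ValueError(f"unknown detection method {method!r}")

    if peak <= 0 or (noise > 0 and peak < snr_min * noise):
        return None
    return (start + idx) / fs_hz - stim_time


def activation_map(
    recording: MEARecording,
    blanking_ms: float = 2.0,
    window_ms: float = 80.0,
    method: str = "max_amplitude",
    snr_min: float = 5.0,
    min_detected_fraction: float = 0.25,
) -> ActivationMap:
    """Per-electrode activation times, averaged over all stimuli.

    The stimulation electrode is flagged and excluded.  Raises when fewer than
    ``min_detected_fraction`` of the remaining electrodes yield a detection on
    every stimulus (the map is then considered unusable).
    """
    times: dict[int, float] = {}
    flags: dict[int, str] = {}
    for cid, _, _ in recording.layout.electrode_positions:
        if cid == recording.stim_channel:
            flags[cid] = "stim"
            continue
        per_stim = []
        for stim_time in recording.stim_times:
            t = detect_activation_time(
                recording.traces[cid],
                recording.fs_hz,
                stim_time,
                blanking_ms=blanking_ms,
                window_ms=window_ms,
                method=method,
                snr_min=snr_min,
            )
            if t is not None:
                per_stim.append(t)
        if len(per_stim) == len(recording.stim_times):
            times[cid] = float(np.mean(per_stim))
            flags[cid] = "ok"
        else:
            flags[cid] = "missing"

    n_candidates = recording.layout.n_electrodes - 1
    if len(times) < min_detected_fraction * n_candidates:
        raise ValueError(
            f"only {len(times)}/{n_candidates} electrodes detected: map unusable"
        )
    return ActivationMap(
        activation_time=times,
        stim_channel=recording.stim_channel,
        quality_flags=flags,
    )


def conduction_velocity(
    amap: ActivationMap,
    layout: MEALayout,
    axis_deg: float,
    sector_halfwidth_deg: float = 8.0,
    min_electrodes: int = 4,
) -> ConductionResult:
    """Conduction velocity (cm/s) along an axis through the stimulation site.

    Electrodes whose direction from the stimulation site lies within
    ``sector_halfwidth_deg`` of the axis ray (``axis_deg`` and ``axis_deg +
    180`` are therefore distinct sectors) enter an ordinary least-squares fit
    of activation time against distance along the axis; the velocity is the
    inverse slope.  The default sector is narrow so that, on the standard
    grid, only near-collinear electrodes are used — off-axis electrodes see
    an elliptical wavefront arrive late by a factor
    sqrt(1 + tan^2(theta) * (vL/vT)^2) and would bias the slope.

    Raises when fewer than ``min_electrodes`` qualify, or when the fitted
    slope is not positive (retrograde apparent propagation / failed capture).
    """
    sx, sy = layout.position_of(amap.stim_channel)
    ax = math.radians(axis_deg)
    ux, uy = math.cos(ax), math.sin(ax)

    along_cm, times = [], []
    for cid, t in amap.activation_time.items():
        x, y = layout.position_of(cid)
        dx, dy = x - sx, y - sy
        dist = math.hypot(dx, dy)
        if dist == 0:
            continue
        along = dx * ux + dy * uy
        if along <= 0:
            continue
        angle = math.degrees(math.acos(min(1.0, along / dist)))
        if angle <= sector_halfwidth_deg + 1e-9:
            along_cm.append(along / _UM_PER_CM)
            times.append(t)

    if len(times) < min_electrodes:
        raise ValueError(
            f"{len(times)} electrodes in sector around {axis_deg} deg "
            f"(need {min_electrodes})"
        )
    along_arr = np.asarray(along_cm)
    t_arr = np.asarray(times)
    slope, intercept = np.polyfit(along_arr, t_arr, 1)
    if slope <= 0:
        raise ValueError(
            "non-positive distance-time slope: retrograde propagation or failed capture"
        )
    residual = float(np.sqrt(np.mean((t_arr - (slope * along_arr + intercept)) ** 2)))
    return ConductionResult(
        cv_cm_s=float(1.0 / slope),
        direction_deg=float(axis_deg),
        n_electrodes_used=len(times),
        fit_residual_s=residual,
    )


def anisotropy_ratio(cv_long_cm_s: float, cv_trans_cm_s: float) -> float:
    """Conduction anisotropy CV_L:CV_T."""
    if cv_trans_cm_s <= 0 or cv_long_cm_s <= 0:
        raise ValueError("conduction velocities must be positive")
    return cv_long_cm_s / cv_trans_cm_s
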