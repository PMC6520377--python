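"""Beat segmentation and feature extraction for force and Ca2+ transients.

Paced recordings (isometric force from a transducer, or regional Fluo-4
fluorescence) are cut into one window per stimulus.  Each beat yields the
standard kinetic descriptors: amplitude above the diastolic baseline, time to
peak from the stimulus, time to 50% and 90% decay (first crossings of 50% and
10% of the amplitude after the peak), and the maximum rates of rise and decay
from a smoothed derivative.  Contractility is peak force normalised either to
the slice cross-sectional area (width x nominal thickness) or to width alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "TransientTrace",
    "TransientFeatures",
    "SliceDimensions",
    "BeatWindow",
    "segment_beats",
    "transient_features",
    "contractility",
    "max_contractility",
]


@dataclass
class TransientTrace:
    """A uniformly sampled paced trace with stimulus annotations."""

    time_s: np.ndarray
    signal: np.ndarray
    fs_hz: float
    stim_times: list[float]
    pacing_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape:
            raise ValueError("time and signal must have the same length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("trace must be uniformly sampled")
        if self.pacing_rate_hz <= 0:
            raise ValueError("pacing rate must be positive")
        if sorted(self.stim_times) != list(self.stim_times):
            raise ValueError("stimulus times must be sorted")


@dataclass(frozen=True)
class TransientFeatures:
    """Per-beat amplitude and kinetics.  Rates are positive magnitudes."""

    amplitude: float
    time_to_peak_s: float
    t50_decay_s: float
    t90_decay_s: float
    max_rise_rate: float
    max_decay_rate: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (self.t90_decay_s >= self.t50_decay_s > 0):
            raise ValueError("decay times must satisfy t90 >= t50 > 0")


@dataclass(frozen=True)
class SliceDimensions:
    """Slice geometry for force normalisation; thickness defaults to the
    nominal 300 um cutting thickness."""

    width_mm: float
    length_mm: float
    thickness_um: float = 300.0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.length_mm, self.thickness_um) <= 0:
            raise ValueError("slice dimensions must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return self.width_mm * self.thickness_um * 1e-3


@dataclass(frozen=True)
class BeatWindow:
    """One beat: sample span [start, stop) and the owning stimulus time."""

    start: int
    stop: int
    stim_time_s: float


def segment_beats(trace: TransientTrace) -> list[BeatWindow]:
    """One window per stimulus, from each stimulus to the next.

    The final beat's window is one pacing interval long.
    """
    if not trace.stim_times:
        raise ValueError("trace has no stimuli")
    interval = 1.0 / trace.pacing_rate_hz
    t0 = trace.time_s[0]
    n = trace.signal.size
    windows = []
    bounds = list(trace.stim_times) + [trace.stim_times[-1] + interval]
    for stim, nxt in zip(bounds[:-1], bounds[1:]):
        start = int(round((stim - t0) * trace.fs_hz))
        stop = min(n, int(round((nxt - t0) * trace.fs_hz)))
        if stop <= start:
            raise ValueError("empty beat window: check stimulus times")
        windows.append(BeatWindow(start=start, stop=stop, stim_time_s=stim))
    return windows


def transient_features(
    trace: TransientTrace,
    beat: BeatWindow,
    baseline_ms: float = 20.0,
    smooth_ms: float = 5.0,
    noise_gate: float = 3.0,
) -> TransientFeatures:
    """Extract amplitude and kinetics from one beat.

    Baseline is the median of the ``baseline_ms`` preceding the stimulus
    (falling back to the first sample of the window at the trace start).
    Decay landmarks are first crossings, linearly interpolated between
    samples, of 50% (t50) and 10% (t90: 90% decayed) of the amplitude above
    baseline after the peak.  Rates come from a Savitzky-Golay first
    derivative with a ``smooth_ms`` window.  Raises when the peak does not
    exceed ``noise_gate`` times the robust baseline noise.
    """
    y = trace.signal
    fs = trace.fs_hz
    n_base = max(1, int(round(baseline_ms * 1e-3 * fs)))
    b0 = max(0, beat.start - n_base)
    pre = y[b0:beat.start] if beat.start > b0 else y[beat.start : beat.start + 1]
    baseline = float(np.median(pre))
    noise = 1.4826 * float(np.median(np.abs(pre - baseline)))

    seg = y[beat.start : beat.stop] - baseline
    peak_idx = int(np.argmax(seg))
    amplitude = float(seg[peak_idx])
    if amplitude <= 0 or (noise > 0 and amplitude < noise_gate * noise):
        raise ValueError("no peak above the baseline noise gate")

    time_to_peak = peak_idx / fs

    t50 = _first_decay_crossing(seg, peak_idx, 0.5 * amplitude, fs)
    t90 = _first_decay_crossing(seg, peak_idx, 0.1 * amplitude, fs)
    if t50 is None or t90 is None:
        raise ValueError("beat does not relax to the decay landmarks in its window")

    deriv = _smoothed_derivative(seg, fs, smooth_ms)
    max_rise = float(np.max(deriv[: peak_idx + 1])) if peak_idx >= 0 else 0.0
    max_decay = float(-np.min(deriv[peak_idx:]))

    return TransientFeatures(
        amplitude=amplitude,
        time_to_peak_s=time_to_peak,
        t50_decay_s=t50,
        t90_decay_s=t90,
        max_rise_rate=max_rise,
        max_decay_rate=max_decay,
    )


def _first_decay_crossing(
    seg: np.ndarray, peak_idx: int, level: float, fs: float
) -> float | None:
    """Time (s from window start) of the first fall below ``level`` after the
    peak, linearly interpolated between the bracketing samples."""
    below = np.nonzero(seg[peak_idx:] <= level)[0]
    if below.size == 0:
        return None
    j = peak_idx + int(below[0])
    if j == peak_idx:
        return peak_idx / fs
    y1, y2 = seg[j - 1], seg[j]
    frac = (y1 - level) / (y1 - y2) if y1 != y2 else 0.0
    return (j - 1 + frac) / fs


def _smoothed_derivative(seg: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    window = max(3, int(round(smooth_ms * 1e-3 * fs)))
    if window % 2 == 0:
        window += 1
    if window >= seg.size:
        window = seg.size - 1 if seg.size % 2 == 0 else seg.size - 2
        window = max(3, window)
    if seg.size <= 3:
        return np.gradient(seg) * fs
    return savgol_filter(seg, window, polyorder=2, deriv=1, delta=1.0 / fs)


def contractility(
    peak_force_mn: float, dims: SliceDimensions, per: str = "area"
) -> float:
    """Peak force normalised to cross-sectional area (mN/mm^2, default) or to
    slice width (mN/mm, ``per="width"``)."""
    if peak_force_mn <= 0:
        raise ValueError("peak force must be positive")
    if per == "area":
        return peak_force_mn / dims.cross_section_mm2
    if per == "width":
        return peak_force_mn / dims.width_mm
    raise ValueError(f"unknown normalisation {per!r}")


def max_contractility(
    per_step_peak_forces: list[tuple[float, float]],
    dims: SliceDimensions,
    per: str = "area",
) -> float:
    """Contractility at the stretch step with maximal peak force.

    ``per_step_peak_forces`` is a list of (stretch level, peak force mN) pairs
    from a stepwise stretch protocol run to maximum isometric contraction.
    """
    if not per_step_peak_forces:
        raise ValueError("no stretch steps provided")
    best = max(per_step_peak_forces, key=lambda sf: sf[1])
    return contractility(best[1], dims, per=per)
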