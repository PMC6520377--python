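"""Isoproterenol dose-escalation analysis: aftercontractions, tachyarrhythmia
threshold, arrhythmogenicity score, and four-parameter-logistic EC50 fitting.

Slices are paced while isoproterenol is added cumulatively in half-log steps
from 1e-9 to 3e-6 M.  Arrhythmic propensity is quantified two ways: the rate
of aftercontractions (spontaneous diastolic events between paced beats) at
each concentration, and the lowest concentration at which sustained
tachyarrhythmia appears once point stimulation stops.  That threshold maps
onto a linear 0-9 arrhythmogenicity score (tachyarrhythmia before any drug
scores 9; never developing one scores 0).  The beta-adrenergic sensitivity of
any contractile response is summarised by the EC50 of a four-parameter
logistic fitted on log10 concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .traces import TransientTrace, segment_beats

__all__ = [
    "DoseResponseFit",
    "ArrhythmiaAssessment",
    "isoproterenol_series",
    "arrhythmogenicity_score",
    "detect_aftercontractions",
    "detect_sustained_tachyarrhythmia",
    "fit_dose_response",
    "assess_dose_escalation",
]

#: concentrations (M) of the standard half-log escalation using the 1-3
#: labelling convention (3e-9 stands for the 10^-8.5 half-log step)
_SERIES: tuple[float, ...] = (1e-9, 3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6)

PRE_DRUG = "pre-drug"


def isoproterenol_series() -> list[float]:
    """The 8-level isoproterenol escalation, 1e-9 to 3e-6 M in half-log steps."""
    return list(_SERIES)


def arrhythmogenicity_score(threshold: float | str | None) -> int:
    """Linear 0-9 score from the tachyarrhythmia threshold concentration.

    ``"pre-drug"`` (tachyarrhythmia at or before zero isoproterenol) scores 9,
    the series concentrations score 8 (1e-9 M) down to 1 (3e-6 M), and None
    (no tachyarrhythmia at any concentration) scores 0.
    """
    if threshold is None:
        return 0
    if threshold == PRE_DRUG:
        return 9
    for i, conc in enumerate(_SERIES):
        if math.isclose(float(threshold), conc, rel_tol=1e-6):
            return 8 - i
    raise ValueError(f"threshold {threshold!r} is not in the concentration series")


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit: ec50 (M), Hill slope, bottom/top plateaus,
    and the root-mean-square residual of the fit."""

    ec50_m: float
    hill: float
    bottom: float
    top: float
    rmse: float

    def __post_init__(self) -> None:
        if self.ec50_m <= 0:
            raise ValueError("EC50 must be positive")
        if self.top < self.bottom:
            raise ValueError("top plateau below bottom plateau")

    def predict(self, concentration_m) -> np.ndarray:
        c = np.asarray(concentration_m, dtype=float)
        return _four_pl(np.log10(c), self.bottom, self.top, np.log10(self.ec50_m), self.hill)


@dataclass
class ArrhythmiaAssessment:
    """Outcome of a dose-escalation experiment on one slice."""

    aftercontraction_rate_per_min: dict[float, float]
    tachy_threshold_m: float | str | None
    score: int = field(default=0)

    def __post_init__(self) -> None:
        self.score = arrhythmogenicity_score(self.tachy_threshold_m)


def _paced_beat_stats(trace: TransientTrace) -> tuple[float, float]:
    """Median paced amplitude and baseline over the paced windows."""
    windows = segment_beats(trace)
    amps, bases = [], []
    n_base = max(1, int(round(0.02 * trace.fs_hz)))
    for w in windows:
        b0 = max(0, w.start - n_base)
        base = float(np.median(trace.signal[b0 : w.start] if w.start > b0 else trace.signal[w.start : w.start + 1]))
        seg = trace.signal[w.start : w.stop] - base
        amps.append(float(np.max(seg)))
        bases.append(base)
    amplitude = float(np.median(amps))
    if amplitude <= 0:
        raise ValueError("no paced beats detectable")
    return amplitude, float(np.median(bases))


def detect_aftercontractions(
    trace: TransientTrace,
    prominence_fraction: float = 0.10,
    relaxation_fraction: float = 0.90,
) -> float:
    """Rate of diastolic aftercontractions, events per minute.

    For each paced beat the diastolic interval starts once the beat has
    relaxed by ``relaxation_fraction`` of its amplitude (first crossing below
    10% of the paced amplitude above baseline, by default) and ends at the
    next stimulus.  Local maxima in that interval with prominence of at least
    ``prominence_fraction`` times the median paced amplitude count as
    aftercontractions; the count is normalised to the paced duration.
    Relative thresholds make the count invariant to trace gain.
    """
    windows = segment_beats(trace)
    paced_amp, _ = _paced_beat_stats(trace)
    min_prominence = prominence_fraction * paced_amp
    residual_level = (1.0 - relaxation_fraction) * paced_amp

    count = 0
    for w in windows:
        n_base = max(1, int(round(0.02 * trace.fs_hz)))
        b0 = max(0, w.start - n_base)
        base = float(np.median(trace.signal[b0 : w.start] if w.start > b0 else trace.signal[w.start : w.start + 1]))
        seg = trace.signal[w.start : w.stop] - base
        peak_idx = int(np.argmax(seg))
        relaxed = np.nonzero(seg[peak_idx:] <= residual_level)[0]
        if relaxed.size == 0:
            continue  # beat never relaxes within its window: no diastole
        dia_start = peak_idx + int(relaxed[0])
        dia = seg[dia_start:]
        if dia.size < 3:
            continue
        peaks, _ = find_peaks(dia, prominence=min_prominence)
        count += int(peaks.size)

    paced_duration_s = len(windows) / trace.pacing_rate_hz
    return 60.0 * count / paced_duration_s


def detect_sustained_tachyarrhythmia(
    trace: TransientTrace,
    pacing_rate_hz: float | None = None,
    stim_stop_time_s: float | None = None,
    rate_factor: float = 1.5,
    min_duration_s: float = 10.0,
    prominence_fraction: float = 0.10,
) -> bool:
    """Whether sustained tachyarrhythmia follows the end of pacing.

    True when spontaneous contractions after ``stim_stop_time_s`` (default:
    one pacing interval after the last stimulus) run faster than
    ``rate_factor`` times the pacing rate continuously for at least
    ``min_duration_s``.  Raises when the trace does not extend
    ``min_duration_s`` beyond the stimulation stop.
    """
    if pacing_rate_hz is None:
        pacing_rate_hz = trace.pacing_rate_hz
    if stim_stop_time_s is None:
        stim_stop_time_s = trace.stim_times[-1] + 1.0 / pacing_rate_hz
    t_end = trace.time_s[-1]
    if t_end - stim_stop_time_s < min_duration_s:
        raise ValueError(
            "trace must extend at least the minimum sustained duration beyond "
            "the stimulation stop"
        )
    paced_amp, base = _paced_beat_stats(trace)
    start = int(round((stim_stop_time_s - trace.time_s[0]) * trace.fs_hz))
    post = trace.signal[start:] - base
    peaks, _ = find_peaks(post, prominence=prominence_fraction * paced_amp)
    if peaks.size < 2:
        return False
    times = trace.time_s[start:][peaks]
    max_interval = 1.0 / (rate_factor * pacing_rate_hz)
    fast = np.diff(times) <= max_interval

    # longest run of consecutive fast intervals; sustained if its time span
    # covers min_duration_s
    run_start = None
    for i, ok in enumerate(np.append(fast, False)):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if times[i] - times[run_start] >= min_duration_s:
                return True
            run_start = None
    return False


def _four_pl(log_c, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - log_c)))


def fit_dose_response(concentrations_m, responses) -> DoseResponseFit:
    """Least-squares four-parameter logistic on log10 concentration.

    Initialised from the response range and the concentration at which the
    response first crosses mid-range.  Raises on fewer than five levels, a
    flat response range, or non-convergence.
    """
    c = np.asarray(concentrations_m, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 5:
        raise ValueError("EC50 fitting requires at least five concentration levels")
    if c.size != y.size:
        raise ValueError("concentrations and responses must have equal length")
    if np.any(c <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("concentrations must be positive and responses finite")
    span = float(np.max(y) - np.min(y))
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(np.max(y)))):
        raise ValueError("flat response range: no dose-response relation to fit")

    log_c = np.log10(c)
    mid = float(np.min(y)) + 0.5 * span
    above = np.nonzero(y >= mid)[0]
    log_ec50_init = float(log_c[above[0]]) if above.size else float(np.median(log_c))
    p0 = [float(np.min(y)), float(np.max(y)), log_ec50_init, 1.0]
    try:
        popt, _ = curve_fit(_four_pl, log_c, y, p0=p0, maxfev=20_000)
    except RuntimeError as err:
        raise ValueError(f"dose-response fit did not converge: {err}") from err
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if top < bottom:
        # reflected solution: swap plateaus and flip the Hill slope
        bottom, top, hill = top, bottom, -hill
    fitted = _four_pl(log_c, bottom, top, log_ec50, hill)
    rmse = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return DoseResponseFit(
        ec50_m=float(10.0**log_ec50), hill=hill, bottom=bottom, top=top, rmse=rmse
    )


def assess_dose_escalation(
    traces_by_concentration: dict[float, TransientTrace],
    pre_drug_trace: TransientTrace | None = None,
    rate_factor: float = 1.5,
    min_duration_s: float = 10.0,
    prominence_fraction: float = 0.10,
) -> ArrhythmiaAssessment:
    """Full escalation on one slice: per-concentration aftercontraction rates,
    the tachyarrhythmia threshold, and the arrhythmogenicity score.

    Concentrations are analysed in increasing order; the threshold is the
    first concentration whose trace shows sustained tachyarrhythmia (the
    pre-drug trace, when given and positive, sets the threshold to
    ``"pre-drug"``).  Aftercontraction rates are reported for every
    concentration provided.
    """
    if not traces_by_concentration:
        raise ValueError("no traces provided")

    def _tachy(trace: TransientTrace) -> bool:
        try:
            return detect_sustained_tachyarrhythmia(
                trace,
                rate_factor=rate_factor,
                min_duration_s=min_duration_s,
                prominence_fraction=prominence_fraction,
            )
        except ValueError:
            # trace too short after pacing to judge sustained activity
            return False

    threshold: float | str | None = None
    if pre_drug_trace is not None and _tachy(pre_drug_trace):
        threshold = PRE_DRUG

    rates: dict[float, float] = {}
    for conc in sorted(traces_by_concentration):
        trace = traces_by_concentration[conc]
        rates[conc] = detect_aftercontractions(
            trace, prominence_fraction=prominence_fraction
        )
        if threshold is None and _tachy(trace):
            threshold = conc
    return ArrhythmiaAssessment(
        aftercontraction_rate_per_min=rates, tachy_threshold_m=threshold
    )
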