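"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator draws from a single explicitly seeded pseudo-random stream
(``numpy.random.default_rng(seed)``; no global state), returns its data
alongside a :class:`GroundTruth` record holding every generative parameter and
the analytically derived quantities the corresponding analysis step should
recover, and is bit-reproducible under a fixed seed.

The generators emulate the laboratory inputs of an electromechanically
stimulated myocardial-slice experiment: first-order laser-diffraction band
positions for a given sarcomere length; grid multielectrode-array recordings
of a planar or elliptical activation wavefront; paced force/Ca2+ transient
trains built from a difference-of-exponentials beat (chosen because its peak
time, decay landmarks and extreme derivatives have closed or one-dimensional
root-findable forms); four-parameter-logistic dose-response tables; striated
(t-tubule-like) fluorescence images of known period; and noisy samples of the
percent-stretch vs sarcomere-length calibration line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import DiffractionGeometry, band_distance_from_sl
from .mea import MEALayout, MEARecording, build_mea_layout
from .traces import TransientTrace

__all__ = [
    "GroundTruth",
    "TachySpec",
    "gen_diffraction_observation",
    "gen_mea_recording",
    "gen_transient_train",
    "gen_dose_response",
    "gen_striated_image",
    "gen_stretch_samples",
]


@dataclass
class GroundTruth:
    """Generator provenance: name, all generative parameters (incl. seed) and
    the derived quantities the analysis should recover."""

    generator_name: str
    parameters: dict = field(default_factory=dict)
    derived_truths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# laser diffraction


def gen_diffraction_observation(
    sl_um: float,
    geometry: DiffractionGeometry = DiffractionGeometry(),
    noise_cm: float = 0.0,
    seed: int = 0,
) -> tuple[float, GroundTruth]:
    """Observed zero-to-first-order band distance (cm) for a sarcomere length.

    Forward grating-equation projection plus zero-mean Gaussian measurement
    noise.  Raises (via the projection) when no first-order band exists.
    """
    if noise_cm < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    true_distance = band_distance_from_sl(sl_um, geometry)
    observed = true_distance + (rng.normal(0.0, noise_cm) if noise_cm > 0 else 0.0)
    truth = GroundTruth(
        generator_name="diffraction_observation",
        parameters={
            "sl_um": sl_um,
            "wavelength_nm": geometry.wavelength_nm,
            "slice_to_grid_cm": geometry.slice_to_grid_cm,
            "order": geometry.order,
            "noise_cm": noise_cm,
            "seed": seed,
        },
        derived_truths={"band_distance_cm": true_distance, "sl_um": sl_um},
    )
    return float(observed), truth


# ---------------------------------------------------------------------------
# multielectrode array


def _activation_times_s(
    layout: MEALayout,
    stim_channel: int,
    cv_long_cm_s: float,
    cv_trans_cm_s: float,
    fiber_angle_deg: float,
    wavefront: str,
) -> dict[int, float]:
    sx, sy = layout.position_of(stim_channel)
    th = math.radians(fiber_angle_deg)
    times: dict[int, float] = {}
    for cid, x, y in layout.electrode_positions:
        dx_cm = (x - sx) / 1e4
        dy_cm = (y - sy) / 1e4
        a = dx_cm * math.cos(th) + dy_cm * math.sin(th)
        b = -dx_cm * math.sin(th) + dy_cm * math.cos(th)
        if wavefront == "elliptical":
            times[cid] = math.hypot(a / cv_long_cm_s, b / cv_trans_cm_s)
        elif wavefront == "planar":
            times[cid] = a / cv_long_cm_s
        else:
            raise ValueError(f"unknown wavefront {wavefront!r}")
    if wavefront == "planar":
        # a plane wave sweeps the whole array: shift so the earliest electrode
        # activates at zero delay
        t0 = min(times.values())
        times = {cid: t - t0 for cid, t in times.items()}
    return times


def gen_mea_recording(
    cv_long_cm_s: float,
    cv_trans_cm_s: float,
    fiber_angle_deg: float = 0.0,
    stim_channel: int = 7,
    layout: MEALayout | None = None,
    fs_hz: float = 50_000.0,
    spike_amplitude_uv: float = 500.0,
    spike_width_ms: float = 0.3,
    noise_sd_uv: float = 0.0,
    seed: int = 0,
    wavefront: str = "elliptical",
    n_stim: int = 1,
    stim_interval_s: float = 1.0,
    pre_stim_s: float = 0.01,
) -> tuple[MEARecording, GroundTruth]:
    """Grid MEA recording of an activation wavefront from a point stimulus.

    Each electrode's trace carries one biphasic spike per stimulus, centred at
    the stimulus time plus the electrode's activation delay
    ``t_i = sqrt((a_i/cv_long)^2 + (b_i/cv_trans)^2)`` where ``(a_i, b_i)``
    are the electrode offsets from the stimulation site rotated into the fiber
    frame (``wavefront="planar"`` instead sweeps a plane wave along the fiber
    axis at ``cv_long``).  The spike is a dominant negative Gaussian lobe at
    the activation time followed by a smaller positive lobe four widths later,
    so its absolute extremum sits exactly at the activation time.
    """
    if not (cv_long_cm_s >= cv_trans_cm_s > 0):
        raise ValueError("require cv_long >= cv_trans > 0")
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if layout is None:
        layout = build_mea_layout()
    if stim_channel not in layout:
        raise ValueError(f"stimulation electrode {stim_channel} not in layout")

    rng = np.random.default_rng(seed)
    delays = _activation_times_s(
        layout, stim_channel, cv_long_cm_s, cv_trans_cm_s, fiber_angle_deg, wavefront
    )
    sigma = spike_width_ms * 1e-3
    t_max = max(delays.values())
    duration = pre_stim_s + (n_stim - 1) * stim_interval_s + t_max + 10 * sigma + 5e-3
    n_samples = int(round(duration * fs_hz))
    t = np.arange(n_samples) / fs_hz
    stim_times = [pre_stim_s + k * stim_interval_s for k in range(n_stim)]

    traces = np.zeros((layout.n_electrodes, n_samples))
    for cid, _, _ in layout.electrode_positions:
        if cid == stim_channel:
            continue
        for s in stim_times:
            centre = s + delays[cid]
            u = (t - centre) / sigma
            v = (t - centre - 4 * sigma) / sigma
            traces[cid] += spike_amplitude_uv * (
                -np.exp(-0.5 * u**2) + 0.5 * np.exp(-0.5 * v**2)
            )
    if noise_sd_uv > 0:
        traces += rng.normal(0.0, noise_sd_uv, size=traces.shape)

    recording = MEARecording(
        traces=traces,
        fs_hz=fs_hz,
        layout=layout,
        stim_channel=stim_channel,
        stim_times=stim_times,
    )
    truth = GroundTruth(
        generator_name="mea_recording",
        parameters={
            "cv_long_cm_s": cv_long_cm_s,
            "cv_trans_cm_s": cv_trans_cm_s,
            "fiber_angle_deg": fiber_angle_deg,
            "stim_channel": stim_channel,
            "fs_hz": fs_hz,
            "spike_amplitude_uv": spike_amplitude_uv,
            "spike_width_ms": spike_width_ms,
            "noise_sd_uv": noise_sd_uv,
            "wavefront": wavefront,
            "n_stim": n_stim,
            "stim_interval_s": stim_interval_s,
            "pre_stim_s": pre_stim_s,
            "seed": seed,
        },
        derived_truths={
            "activation_time_s": delays,
            "cv_long_cm_s": cv_long_cm_s,
            "cv_trans_cm_s": cv_trans_cm_s,
            "anisotropy_ratio": cv_long_cm_s / cv_trans_cm_s,
        },
    )
    return recording, truth


# ---------------------------------------------------------------------------
# transient trains


@dataclass(frozen=True)
class TachySpec:
    """Spontaneous tachyarrhythmic activity: onset (s, absolute trace time)
    and rate (Hz) of unpaced beats continuing to the end of the trace."""

    onset_s: float
    rate_hz: float


def _beat_template_truths(
    amplitude: float, tau_rise_s: float, tau_decay_s: float
) -> dict[str, float]:
    """Closed-form / root-found per-beat features of the scaled
    difference-of-exponentials beat ``A_n * (exp(-t/td) - exp(-t/tr))``."""
    tr, td = tau_rise_s, tau_decay_s
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    unit = lambda t: math.exp(-t / td) - math.exp(-t / tr)  # noqa: E731
    u_peak = unit(t_peak)
    scale = amplitude / u_peak
    # decay landmarks: first times after the peak where the beat has fallen to
    # 50% / 10% of its amplitude
    t_hi = 20 * td
    t50 = brentq(lambda t: unit(t) - 0.5 * u_peak, t_peak, t_hi)
    t90 = brentq(lambda t: unit(t) - 0.1 * u_peak, t_peak, t_hi)
    # derivative extremes: the rise rate is maximal at onset, the decay rate
    # at twice the peak time (root of the second derivative)
    max_rise = scale * (1.0 / tr - 1.0 / td)
    t_dd = 2.0 * t_peak
    max_decay = scale * (math.exp(-t_dd / tr) / tr - math.exp(-t_dd / td) / td)
    return {
        "time_to_peak_s": t_peak,
        "amplitude": amplitude,
        "t50_decay_s": t50,
        "t90_decay_s": t90,
        "max_rise_rate": max_rise,
        "max_decay_rate": abs(max_decay),
    }


def gen_transient_train(
    amplitude: float = 1.0,
    tau_rise_s: float = 0.02,
    tau_decay_s: float = 0.2,
    pacing_hz: float = 1.0,
    n_beats: int = 10,
    aftercontractions: Sequence[tuple[float, float]] | None = None,
    tachy: TachySpec | None = None,
    noise_sd: float = 0.0,
    fs_hz: float = 1_000.0,
    seed: int = 0,
    post_s: float = 0.0,
) -> tuple[TransientTrace, GroundTruth]:
    """Paced train of difference-of-exponentials beats.

    Beats start at each stimulus (first stimulus at t = 0, pacing at
    ``pacing_hz``) and are scaled so the peak equals ``amplitude``.
    ``aftercontractions`` are (absolute time s, relative amplitude) pairs
    injected as scaled beats; each must fall in the diastolic interval of its
    owning beat (after the paced beat's 90%-decay landmark, before the next
    stimulus), otherwise raises.  ``tachy`` appends spontaneous beats at the
    given rate from its onset to the end of the trace, emulating sustained
    tachyarrhythmia after pacing stops.  ``post_s`` extends the trace beyond
    the last paced beat window.
    """
    if not (tau_decay_s > tau_rise_s > 0):
        raise ValueError("require tau_decay > tau_rise > 0")
    if pacing_hz <= 0 or n_beats < 1:
        raise ValueError("need a positive pacing rate and at least one beat")
    rng = np.random.default_rng(seed)
    interval = 1.0 / pacing_hz
    stim_times = [k * interval for k in range(n_beats)]
    stim_stop = n_beats * interval
    duration = stim_stop + post_s
    n = int(round(duration * fs_hz))
    t = np.arange(n) / fs_hz

    beat_truth = _beat_template_truths(amplitude, tau_rise_s, tau_decay_s)
    u_peak_inv = amplitude / (
        math.exp(-beat_truth["time_to_peak_s"] / tau_decay_s)
        - math.exp(-beat_truth["time_to_peak_s"] / tau_rise_s)
    )

    def add_beat(signal: np.ndarray, onset: float, amp_scale: float) -> None:
        tt = t - onset
        active = tt >= 0
        signal[active] += (
            amp_scale
            * u_peak_inv
            * (np.exp(-tt[active] / tau_decay_s) - np.exp(-tt[active] / tau_rise_s))
        )

    signal = np.zeros(n)
    for s in stim_times:
        add_beat(signal, s, 1.0)

    aftercontractions = list(aftercontractions or [])
    for ac_time, rel_amp in aftercontractions:
        owners = [s for s in stim_times if s <= ac_time]
        if not owners:
            raise ValueError("aftercontraction precedes the first stimulus")
        owner = owners[-1]
        diastole_start = owner + beat_truth["t90_decay_s"]
        diastole_end = owner + interval
        if not (diastole_start <= ac_time < diastole_end) or ac_time >= stim_stop:
            raise ValueError(
                f"aftercontraction at {ac_time} s lies outside the diastolic "
                f"interval [{diastole_start:.3f}, {diastole_end:.3f}) s"
            )
        add_beat(signal, ac_time, rel_amp)

    tachy_beat_times: list[float] = []
    if tachy is not None:
        if tachy.rate_hz <= 0:
            raise ValueError("tachyarrhythmia rate must be positive")
        if tachy.onset_s >= duration:
            raise ValueError("tachyarrhythmia onset lies beyond the trace")
        beat_time = tachy.onset_s
        while beat_time < duration:
            tachy_beat_times.append(beat_time)
            add_beat(signal, beat_time, 1.0)
            beat_time += 1.0 / tachy.rate_hz

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n)

    trace = TransientTrace(
        time_s=t,
        signal=signal,
        fs_hz=fs_hz,
        stim_times=stim_times,
        pacing_rate_hz=pacing_hz,
    )
    truth = GroundTruth(
        generator_name="transient_train",
        parameters={
            "amplitude": amplitude,
            "tau_rise_s": tau_rise_s,
            "tau_decay_s": tau_decay_s,
            "pacing_hz": pacing_hz,
            "n_beats": n_beats,
            "aftercontractions": aftercontractions,
            "tachy": tachy,
            "noise_sd": noise_sd,
            "fs_hz": fs_hz,
            "post_s": post_s,
            "seed": seed,
        },
        derived_truths={
            **beat_truth,
            "n_beats": n_beats,
            "stim_stop_s": stim_stop,
            "aftercontraction_count": len(aftercontractions),
            "aftercontraction_rate_per_min": 60.0 * len(aftercontractions) / stim_stop,
            "tachy_present": tachy is not None,
            "tachy_rate_hz": tachy.rate_hz if tachy is not None else 0.0,
            "tachy_beat_times_s": tachy_beat_times,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# dose-response


def gen_dose_response(
    ec50_m: float = 1e-8,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 1.0,
    concentrations_m: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Four-parameter-logistic dose-response table.

    ``response = bottom + (top - bottom) / (1 + (ec50/c)^hill) + noise``.
    Defaults to the standard isoproterenol half-log series when no
    concentrations are given.
    """
    if ec50_m <= 0:
        raise ValueError("EC50 must be positive")
    if concentrations_m is None:
        from .arrhythmia import isoproterenol_series

        concentrations_m = isoproterenol_series()
    conc = np.asarray(list(concentrations_m), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if not np.all(np.diff(conc) > 0):
        raise ValueError("concentrations must be strictly increasing")
    rng = np.random.default_rng(seed)
    response = bottom + (top - bottom) / (1.0 + (ec50_m / conc) ** hill)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=conc.size)
    table = pd.DataFrame({"concentration_m": conc, "response": response})
    truth = GroundTruth(
        generator_name="dose_response",
        parameters={
            "ec50_m": ec50_m,
            "hill": hill,
            "bottom": bottom,
            "top": top,
            "concentrations_m": conc.tolist(),
            "noise_sd": noise_sd,
            "seed": seed,
        },
        derived_truths={"ec50_m": ec50_m, "hill": hill, "bottom": bottom, "top": top},
    )
    return table, truth


# ---------------------------------------------------------------------------
# striated images


def gen_striated_image(
    period_um: float = 1.9,
    pixel_um: float = 0.1,
    orientation_deg: float = 0.0,
    cell_mask_shape: tuple[int, int] = (64, 256),
    positive_fraction: float = 0.5,
    phase_jitter_sd_um: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    pattern: str = "binary",
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Striated fluorescence image with a known period, plus its cell mask.

    The intensity varies along ``orientation_deg`` (the cell long axis; 0 =
    along image columns, x) with the stated spatial period.  ``pattern`` is
    ``"binary"`` — stripes thresholded so a ``positive_fraction`` of pixels is
    bright, emulating hard-thresholded t-tubule staining — or ``"sine"``, a
    pure raised sinusoid (for which the spectral regularity is maximal).
    ``phase_jitter_sd_um`` adds an independent Gaussian phase offset per pixel
    line perpendicular to the axis, degrading striation regularity without
    changing the period.  Raises below the Nyquist limit
    (``period <= 2 * pixel``).
    """
    if period_um <= 2.0 * pixel_um:
        raise ValueError("period must exceed twice the pixel size (Nyquist)")
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = cell_mask_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    th = math.radians(orientation_deg)
    along_um = (xx * math.cos(th) + yy * math.sin(th)) * pixel_um
    perp_px = np.rint(-xx * math.sin(th) + yy * math.cos(th)).astype(int)
    perp_px -= perp_px.min()
    n_lines = perp_px.max() + 1
    # deterministic sub-pixel phase dither across the width: spans exactly one
    # pixel, so stripe-edge quantisation averages out over lines while leaving
    # cross-width phase coherence essentially intact
    dither_um = pixel_um * (np.arange(n_lines) / max(1, n_lines))
    # positional jitter displaces each striation (period cell along the axis)
    # independently, degrading longitudinal periodicity — the t-tubule
    # disarray the regularity metric is sensitive to — while leaving the
    # stripes coherent across the cell width
    stripe_idx = np.floor_divide(along_um, period_um).astype(int)
    stripe_idx -= stripe_idx.min()
    n_stripes = stripe_idx.max() + 1
    stripe_jitter_um = (
        rng.normal(0.0, phase_jitter_sd_um, size=n_stripes)
        if phase_jitter_sd_um > 0
        else np.zeros(n_stripes)
    )
    phase = (
        2.0
        * math.pi
        * (along_um + dither_um[perp_px] + stripe_jitter_um[stripe_idx])
        / period_um
    )
    if pattern == "binary":
        image = amplitude * (np.cos(phase) >= math.cos(math.pi * positive_fraction))
        image = image.astype(float)
    elif pattern == "sine":
        image = amplitude * 0.5 * (1.0 + np.cos(phase))
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    mask = np.ones((h, w), dtype=bool)
    truth = GroundTruth(
        generator_name="striated_image",
        parameters={
            "period_um": period_um,
            "pixel_um": pixel_um,
            "orientation_deg": orientation_deg,
            "cell_mask_shape": tuple(cell_mask_shape),
            "positive_fraction": positive_fraction,
            "phase_jitter_sd_um": phase_jitter_sd_um,
            "amplitude": amplitude,
            "pattern": pattern,
            "seed": seed,
        },
        derived_truths={
            "period_um": period_um,
            "orientation_deg": orientation_deg,
            "positive_fraction": positive_fraction,
        },
    )
    return image, mask, truth


# ---------------------------------------------------------------------------
# stretch calibration samples


def gen_stretch_samples(
    true_slope: float = 41.67,
    true_intercept: float = -69.26,
    sd: float = 3.0,
    sls_um: Sequence[float] = (2.0, 2.1, 2.2, 2.3, 2.4),
    n_per_sl: int = 14,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Noisy (sarcomere length, percent stretch) calibration samples.

    ``percent_stretch = slope * SL + intercept + N(0, sd)``.  The default
    design mirrors the calibration experiment: five SL levels from 2.0 to
    2.4 um (diffraction cannot resolve shorter SLs) with about a dozen slices
    per level, and the published line as the generating truth.
    """
    sls = list(sls_um)
    if not sls:
        raise ValueError("at least one sarcomere length is required")
    if n_per_sl < 1:
        raise ValueError("need at least one sample per sarcomere length")
    rng = np.random.default_rng(seed)
    rows = []
    for sl in sls:
        noise = rng.normal(0.0, sd, size=n_per_sl) if sd > 0 else np.zeros(n_per_sl)
        for e in noise:
            rows.append((sl, true_slope * sl + true_intercept + e))
    table = pd.DataFrame(rows, columns=["sl_um", "percent_stretch"])
    truth = GroundTruth(
        generator_name="stretch_samples",
        parameters={
            "true_slope": true_slope,
            "true_intercept": true_intercept,
            "sd": sd,
            "sls_um": sls,
            "n_per_sl": n_per_sl,
            "seed": seed,
        },
        derived_truths={"slope": true_slope, "intercept": true_intercept},
    )
    return table, truth
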