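"""Sarcomere-length estimation from laser diffraction and the stretch calibration line.

A myocardial slice acts as a diffraction grating for a laser directed at its
surface: the periodic sarcomere lattice (spacing = sarcomere length, SL)
produces first-order diffraction bands at an angle ``theta`` satisfying the
grating equation ``SL * sin(theta) = m * lambda``.  With the pattern projected
onto a grid a known distance ``L`` below the slice, the zero-to-first-order
band distance ``x`` obeys ``x = L * tan(theta)``, so measuring ``x`` yields SL.

Preload applied to a slice in culture is expressed as percent stretch
(engineering strain x 100 of the post-to-post distance relative to the resting
tissue length).  A linear regression of percent stretch on SL, built from
diffraction measurements at several stretches, lets the stretch required for a
target SL be read off even below the diffraction-measurable range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiffractionGeometry",
    "StretchCalibration",
    "percent_stretch",
    "sl_from_band_distance",
    "band_distance_from_sl",
    "fit_stretch_calibration",
    "predict_percent_stretch",
]

#: nanometres per micrometre, used for the wavelength conversion below.
_NM_PER_UM = 1000.0


@dataclass(frozen=True)
class DiffractionGeometry:
    """Optical geometry of the laser-diffraction sarcomere-length measurement.

    Parameters
    ----------
    wavelength_nm
        Laser wavelength in nanometres.  Default 633 (helium-neon laser).
    slice_to_grid_cm
        Distance from the slice surface to the projection grid in centimetres.
        The diffraction pattern originates at the slice, so the laser-to-slice
        offset above the tissue plays no role in the projection and is not a
        parameter here.
    order
        Diffraction order of the measured band (first order by default).
    """

    wavelength_nm: float = 633.0
    slice_to_grid_cm: float = 20.5
    order: int = 1

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.slice_to_grid_cm <= 0:
            raise ValueError("slice-to-grid distance must be positive")
        if self.order < 1:
            raise ValueError("diffraction order must be >= 1")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / _NM_PER_UM


@dataclass(frozen=True)
class StretchCalibration:
    """Linear calibration of percent stretch against sarcomere length.

    ``percent_stretch = slope * SL_um + intercept``, with ``slope`` in %/um
    and ``intercept`` in %.  ``r_squared`` is the coefficient of determination
    of the fit and ``n`` the number of samples used.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("a calibration needs at least two samples")


def percent_stretch(post_distance_mm: float, resting_length_mm: float) -> float:
    """Percent stretch of a mounted slice, as engineering strain x 100.

    ``100 * (post_distance - resting_length) / resting_length``.  Compression
    (post distance below resting length) is not modelled and raises.
    """
    if resting_length_mm <= 0:
        raise ValueError("resting length must be positive")
    if post_distance_mm < resting_length_mm:
        raise ValueError(
            "post distance below resting length: compression is not modelled"
        )
    return 100.0 * (post_distance_mm - resting_length_mm) / resting_length_mm


def band_distance_from_sl(
    sl_um: float, geometry: DiffractionGeometry = DiffractionGeometry()
) -> float:
    """Zero-to-first-order band distance (cm) for a given sarcomere length (um).

    Forward grating-equation projection:
    ``x = L * tan(arcsin(m * lambda / SL))``.  Requires ``SL > m * lambda``;
    at or below that bound the diffracted beam would not leave the grating
    plane and no band exists.
    """
    m_lambda_um = geometry.order * geometry.wavelength_um
    if sl_um <= m_lambda_um:
        raise ValueError(
            f"no order-{geometry.order} band exists for SL = {sl_um} um "
            f"<= {m_lambda_um} um (m * wavelength)"
        )
    theta = math.asin(m_lambda_um / sl_um)
    return geometry.slice_to_grid_cm * math.tan(theta)


def sl_from_band_distance(
    band_distance_cm: float, geometry: DiffractionGeometry = DiffractionGeometry()
) -> float:
    """Sarcomere length (um) from the measured band distance (cm).

    Inverse of :func:`band_distance_from_sl`:
    ``theta = arctan(x / L)``; ``SL = m * lambda / sin(theta)``.
    """
    if band_distance_cm <= 0:
        raise ValueError("band distance must be positive")
    theta = math.atan2(band_distance_cm, geometry.slice_to_grid_cm)
    return geometry.order * geometry.wavelength_um / math.sin(theta)


def fit_stretch_calibration(samples) -> StretchCalibration:
    """Ordinary least squares of percent stretch on sarcomere length.

    Parameters
    ----------
    samples
        Table with columns ``sl_um`` and ``percent_stretch`` (a DataFrame or
        anything convertible), or a 2-column array-like ``(sl, stretch)``.
    """
    sl, stretch = _as_sl_stretch(samples)
    if sl.size < 2:
        raise ValueError("calibration requires at least two samples")
    if np.unique(sl).size < 2:
        raise ValueError("all sarcomere lengths identical: singular design")
    result = stats.linregress(sl, stretch)
    return StretchCalibration(
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue**2),
        n=int(sl.size),
    )


def predict_percent_stretch(calibration: StretchCalibration, sl_um: float) -> float:
    """Percent stretch predicted by a calibration line at a sarcomere length."""
    return calibration.slope * sl_um + calibration.intercept


def _as_sl_stretch(samples) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(samples, "columns"):
        cols = set(samples.columns)
        if {"sl_um", "percent_stretch"} <= cols:
            return (
                np.asarray(samples["sl_um"], dtype=float),
                np.asarray(samples["percent_stretch"], dtype=float),
            )
        raise ValueError("table must have columns 'sl_um' and 'percent_stretch'")
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (sl_um, percent_stretch)")
    return arr[:, 0], arr[:, 1]
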