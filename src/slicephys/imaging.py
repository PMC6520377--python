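"""Confocal image metrics: stained-area fractions, t-tubule density and
spectral regularity, stain heterogeneity, and cardiomyocyte morphometrics.

All operations work on 2-D single-channel intensity arrays with a known pixel
size (z-stacks should be reduced by maximum projection first).  Cell masks are
labelled integer images (background 0) produced upstream; segmentation itself
is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

__all__ = [
    "RegularityResult",
    "percent_positive_area",
    "ttubule_density",
    "ttubule_regularity",
    "cell_morphometrics",
    "heterogeneity_index",
]


@dataclass(frozen=True)
class RegularityResult:
    """Dominant striation period (um) and its normalised spectral power.

    ``regularity_power`` is the power of the largest spectral peak within the
    searched period band divided by the total power of the (detrended,
    zero-frequency-excluded) profile spectrum, so it lies in [0, 1] and
    approaches 1 for a pure in-band sinusoid.
    """

    peak_period_um: float
    regularity_power: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.regularity_power <= 1.0 + 1e-9):
            raise ValueError("regularity power must lie in [0, 1]")


def _resolve_threshold(image: np.ndarray, threshold_method) -> float:
    if isinstance(threshold_method, (int, float)):
        return float(threshold_method)
    if threshold_method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("constant image: automatic threshold undefined")
        return float(threshold_otsu(image))
    raise ValueError(f"unknown threshold method {threshold_method!r}")


def percent_positive_area(
    image: np.ndarray, threshold_method="otsu", mask: np.ndarray | None = None
) -> float:
    """Percent of (masked) pixels above threshold.

    ``threshold_method`` is ``"otsu"`` or a fixed numeric threshold.  Pixels
    strictly above the threshold count as positive.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        values = image[mask]
        if values.size == 0:
            raise ValueError("mask selects no pixels")
    else:
        values = image.ravel()
    thr = _resolve_threshold(image, threshold_method)
    return 100.0 * float(np.count_nonzero(values > thr)) / values.size


def ttubule_density(
    cav3_image: np.ndarray,
    cell_mask: np.ndarray,
    threshold_method="otsu",
    pixel_um: float = 1.0,
    erosion_margin_um: float = 1.0,
) -> float:
    """Positive-pixel fraction within the cell interior.

    The surface sarcolemma is removed by eroding the mask by
    ``erosion_margin_um`` before counting, so only transverse-tubule staining
    in the interior contributes.  Raises when the interior is empty after
    erosion.
    """
    image = np.asarray(cav3_image, dtype=float)
    mask = np.asarray(cell_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    margin_px = int(round(erosion_margin_um / pixel_um))
    interior = ndimage.binary_erosion(mask, iterations=margin_px) if margin_px else mask
    if not interior.any():
        raise ValueError("cell interior empty after sarcolemmal erosion")
    thr = _resolve_threshold(image, threshold_method)
    values = image[interior]
    return float(np.count_nonzero(values > thr)) / values.size


def ttubule_regularity(
    cav3_image: np.ndarray,
    cell_mask: np.ndarray,
    axis_deg: float,
    pixel_um: float,
    period_band_um: tuple[float, float] = (1.6, 2.4),
    min_periods: float = 5.0,
) -> RegularityResult:
    """Spectral regularity of striations along the cell long axis.

    The masked intensity is averaged across the cell width onto a profile
    along ``axis_deg``, linearly detrended, Hann-windowed and Fourier
    transformed; the result is the period of the largest in-band spectral
    peak and its power — integrated over the window's mainlobe (peak bin
    ± 2) so a pure sinusoid scores ~1 regardless of how its period aligns
    with the profile length — as a fraction of the total spectral power
    (zero frequency excluded).  Raises when the profile is shorter than
    ``min_periods`` times the band's upper period bound.
    """
    image = np.asarray(cav3_image, dtype=float)
    mask = np.asarray(cell_mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty cell mask")

    ys, xs = np.nonzero(mask)
    th = math.radians(axis_deg)
    along = xs * math.cos(th) + ys * math.sin(th)
    bins = np.rint(along - along.min()).astype(int)
    n_bins = bins.max() + 1
    profile_sum = np.bincount(bins, weights=image[ys, xs], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    valid = counts > 0
    profile = profile_sum[valid] / counts[valid]

    lo_um, hi_um = period_band_um
    if profile.size * pixel_um < min_periods * hi_um:
        raise ValueError(
            f"profile of {profile.size * pixel_um:.1f} um is too short for the "
            f"{lo_um}-{hi_um} um period band (need {min_periods} upper-bound periods)"
        )

    x = np.arange(profile.size)
    slope, intercept = np.polyfit(x, profile, 1)
    detrended = profile - (slope * x + intercept)

    spectrum = np.fft.rfft(detrended * np.hanning(profile.size))
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(profile.size, d=pixel_um)  # cycles per um
    power[0] = 0.0
    total = float(power.sum())
    # a (near-)constant profile has no striation signal: only float residue
    # survives detrending, and a ratio of rounding noise is meaningless
    if total <= 1e-18 * max(1.0, float(np.sum(profile**2))) * profile.size:
        return RegularityResult(peak_period_um=float(hi_um), regularity_power=0.0)
    in_band = (freqs >= 1.0 / hi_um) & (freqs <= 1.0 / lo_um)
    if not in_band.any():
        raise ValueError("no spectral bins fall inside the period band")
    k = int(np.flatnonzero(in_band)[np.argmax(power[in_band])])
    mainlobe = slice(max(1, k - 2), min(power.size, k + 3))
    return RegularityResult(
        peak_period_um=1.0 / float(freqs[k]),
        regularity_power=min(1.0, float(power[mainlobe].sum() / total)),
    )


def cell_morphometrics(
    cell_mask: np.ndarray, pixel_um: float, min_area_px: int = 10
) -> pd.DataFrame:
    """Per-cell area (um^2) and long-to-short axis ratio of the best-fit
    ellipse, one row per labelled region.

    Regions smaller than ``min_area_px`` are excluded (and reported in the
    ``excluded`` attribute of the returned frame).  Raises when the mask has
    no labelled regions at all.
    """
    labels = np.asarray(cell_mask)
    if labels.max() == 0:
        raise ValueError("mask contains no labelled regions")
    rows, excluded = [], []
    for region in regionprops(labels.astype(int)):
        if region.area < min_area_px:
            excluded.append(int(region.label))
            continue
        minor = region.axis_minor_length
        ratio = region.axis_major_length / minor if minor > 0 else np.nan
        rows.append(
            {
                "label": int(region.label),
                "area_um2": float(region.area) * pixel_um**2,
                "length_width_ratio": float(ratio),
                "orientation_deg": float(np.degrees(region.orientation)),
            }
        )
    if not rows:
        raise ValueError("all regions below the minimum size")
    frame = pd.DataFrame(rows)
    frame.attrs["excluded"] = excluded
    return frame


def heterogeneity_index(
    image: np.ndarray,
    tile_um: float = 20.0,
    pixel_um: float = 1.0,
    threshold_method="otsu",
) -> float:
    """Coefficient of variation of percent-positive area across square tiles.

    The image is cut into non-overlapping tiles of side ``tile_um`` (partial
    edge tiles are dropped); the index is sd/mean of the per-tile positive
    percentages under a single global threshold.  Raises with fewer than four
    complete tiles or when no tile contains stain.
    """
    image = np.asarray(image, dtype=float)
    tile_px = max(1, int(round(tile_um / pixel_um)))
    n_ty = image.shape[0] // tile_px
    n_tx = image.shape[1] // tile_px
    if n_ty * n_tx < 4:
        raise ValueError("image spans fewer than four tiles")
    thr = _resolve_threshold(image, threshold_method)
    fractions = []
    for iy in range(n_ty):
        for ix in range(n_tx):
            tile = image[
                iy * tile_px : (iy + 1) * tile_px, ix * tile_px : (ix + 1) * tile_px
            ]
            fractions.append(
                100.0 * np.count_nonzero(tile > thr) / tile.size
            )
    fractions = np.asarray(fractions)
    mean = float(fractions.mean())
    if mean == 0:
        raise ValueError("no positive pixels in any tile")
    return float(fractions.std(ddof=0) / mean)
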