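"""Measurement pipeline: the image- and track-analysis stages.

Composable, pure stages that mirror how the wet experiments are read
out: per-cell line fits for stalk elongation, two-point Stern-Volmer
calibration and inversion for oxygen imaging, sequential-frame
differencing for cell density, front detection with a cross-front
profile, and the veil-production line fit against integrated cell
number.  Every stage is deterministic given its inputs, so the
generators in :mod:`veilflow.synthetic` double as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.stats import linregress

__all__ = [
    "CalibrationModel",
    "ElongationEstimate",
    "FrontReport",
    "fit_elongation_rate",
    "calibrate",
    "oxygen_map",
    "cell_density_map",
    "front_report",
    "veil_production_fit",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Stern-Volmer calibration: I = I0 / (1 + K_sv c)."""

    i0: float
    k_sv_per_pct: float

    def __post_init__(self) -> None:
        if self.i0 <= 0 or self.k_sv_per_pct <= 0:
            raise ValueError("I0 and K_sv must be positive")


@dataclass(frozen=True)
class ElongationEstimate:
    """Mean stalk-elongation rate with its standard error across tracks."""

    rate_um_s: float
    standard_error: float
    per_track_rates: np.ndarray


def fit_elongation_rate(tracks: pd.DataFrame) -> ElongationEstimate:
    """Per-track OLS slope of displacement against time, averaged.

    Displacement is measured from each track's first point along the
    track's principal displacement axis (with point tracks the principal
    axis stands in for the unknown stalk direction), so isotropic
    localization noise does not bias the direction.  The aggregate is
    the unweighted mean of per-track slopes; the uncertainty is the
    standard error across tracks.
    """
    required = {"track_id", "time_s", "x_um", "y_um"}
    if not required.issubset(tracks.columns):
        raise ValueError(f"track table needs columns {sorted(required)}")
    slopes = []
    for _, tr in tracks.groupby("track_id"):
        t = tr["time_s"].to_numpy()
        if len(t) < 3:
            raise ValueError("each track needs at least 3 points")
        if np.ptp(t) == 0:
            raise ValueError("degenerate track: all samples at the same time")
        xy = tr[["x_um", "y_um"]].to_numpy()
        rel = xy - xy[0]
        # principal displacement axis, oriented with increasing time
        _, _, vt = np.linalg.svd(rel - rel.mean(axis=0), full_matrices=False)
        axis = vt[0]
        disp = rel @ axis
        if linregress(t, disp).slope < 0:
            disp = -disp
        slopes.append(linregress(t, disp).slope)
    slopes = np.asarray(slopes)
    se = slopes.std(ddof=1) / np.sqrt(len(slopes)) if len(slopes) > 1 else 0.0
    return ElongationEstimate(float(slopes.mean()), float(se), slopes)


def calibrate(
    intensity_zero: float, intensity_saturated: float, saturation_pct: float = 100.0
) -> CalibrationModel:
    """Two-point Stern-Volmer calibration.

    From the intensity at zero oxygen and at ``saturation_pct`` (default
    100% atm), solve I = I0 / (1 + K_sv c) at both points:
    I0 = I(0) and K_sv = (I(0)/I(sat) - 1) / sat.
    """
    if intensity_zero <= 0 or intensity_saturated <= 0:
        raise ValueError("calibration intensities must be positive")
    if intensity_zero == intensity_saturated:
        raise ValueError("equal intensities: no quenching to calibrate against")
    k = (intensity_zero / intensity_saturated - 1.0) / saturation_pct
    return CalibrationModel(i0=intensity_zero, k_sv_per_pct=k)


def oxygen_map(
    fluorescence: np.ndarray,
    calibration: CalibrationModel,
    saturated_reference: np.ndarray,
    saturation_pct: float = 100.0,
) -> np.ndarray:
    """Invert a fluorescence image to an oxygen map (% atm).

    The image is first divided by a reference taken at full saturation,
    which cancels any spatial inhomogeneity of the dye (a pixelwise gain
    field), then the Stern-Volmer relation is inverted:

        c = [ (1 + K_sv c_sat) / (I / I_ref) - 1 ] / K_sv
    """
    img = np.asarray(fluorescence, dtype=float)
    ref = np.asarray(saturated_reference, dtype=float)
    if img.shape != ref.shape:
        raise ValueError("fluorescence and reference shapes differ")
    if np.any(img <= 0) or np.any(ref <= 0):
        raise ValueError("intensities must be strictly positive")
    k = calibration.k_sv_per_pct
    ratio = img / ref
    return ((1.0 + k * saturation_pct) / ratio - 1.0) / k


def cell_density_map(
    frame: np.ndarray, previous_frame: np.ndarray, smoothing_sigma_px: float = 2.0
) -> np.ndarray:
    """Cell density proxy from sequential-frame differencing.

    Fast-moving cells dominate the time derivative of the image, so the
    absolute difference of consecutive frames, Gaussian smoothed, maps
    where cells are.  Non-negative by construction.
    """
    a = np.asarray(frame, dtype=float)
    b = np.asarray(previous_frame, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    return gaussian_filter(np.abs(a - b), smoothing_sigma_px)


@dataclass(frozen=True)
class FrontReport:
    """Detected cell front and its oxygen environment.

    ``front_concentration_pct`` is the median oxygen over front pixels;
    ``profile`` holds band-normal averages of density and oxygen as a
    function of signed distance from the front (negative side = lower
    oxygen than the front).
    """

    front_mask: np.ndarray
    front_concentration_pct: float
    profile: pd.DataFrame


def front_report(
    density: np.ndarray,
    oxygen_pct: np.ndarray,
    quantile: float = 0.99,
    profile_halfwidth_px: int = 20,
) -> FrontReport:
    """Locate the dense cell front and read the oxygen it sits at.

    Front pixels are those whose density exceeds the given quantile of
    the density map.  The concentration is the median (robust to the
    band's ends) of the oxygen over those pixels.  The cross-front
    profile bins every pixel by its distance to the nearest front pixel,
    signed by whether the local oxygen is below or above the front
    concentration.
    """
    dens = np.asarray(density, dtype=float)
    oxy = np.asarray(oxygen_pct, dtype=float)
    if dens.shape != oxy.shape:
        raise ValueError("density and oxygen grids must have the same shape")
    if np.ptp(dens) == 0:
        raise ValueError("density is uniform: no front to detect")
    threshold = np.quantile(dens, quantile)
    mask = dens >= threshold
    if not mask.any() or np.isclose(threshold, dens.min()):
        raise ValueError("front threshold selects no distinct pixels")
    front_c = float(np.median(oxy[mask]))
    dist = distance_transform_edt(~mask)
    signed = np.where(oxy < front_c, -dist, dist)
    bins = np.arange(-profile_halfwidth_px - 0.5, profile_halfwidth_px + 1.5)
    centers = 0.5 * (bins[:-1] + bins[1:])
    rows = []
    idx = np.digitize(signed.ravel(), bins) - 1
    dens_flat, oxy_flat = dens.ravel(), oxy.ravel()
    for b, center in enumerate(centers):
        sel = idx == b
        if sel.any():
            rows.append(
                (center, float(dens_flat[sel].mean()), float(oxy_flat[sel].mean()))
            )
    profile = pd.DataFrame(
        rows, columns=["distance_px", "mean_density", "mean_oxygen_pct"]
    )
    return FrontReport(mask, front_c, profile)


def veil_production_fit(series: pd.DataFrame) -> tuple[float, float, float]:
    """OLS fit of scattered-light change against integrated cell number.

    Returns (slope, intercept, R^2).  The intensity change is measured
    from the first sample; R^2 near 1 diagnoses the linear accumulation
    of veil material.
    """
    required = {"integrated_cell_number", "scattered_intensity"}
    if not required.issubset(series.columns):
        raise ValueError(f"series needs columns {sorted(required)}")
    if len(series) < 3:
        raise ValueError("need at least 3 samples to fit")
    x = series["integrated_cell_number"].to_numpy()
    y = series["scattered_intensity"].to_numpy()
    y = y - y[0]
    if np.ptp(x) == 0:
        raise ValueError("integrated cell number is constant: nothing to regress on")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
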