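"""Spot-to-concentration pipeline: outlier screening, mean gray, inversion, remark.

This module implements the readout algorithm for a single assay image:

    read image -> gray matrix -> CMY -> ROI pixels -> sort & eliminate
    outliers -> mean gray -> calibration equation -> ppm -> concluding remark

Outlier pixels (dust, coffee-ring residue, specular glints) are removed with
a single pass of Tukey's 1.5 x IQR fences.  The mean CMY gray of the
surviving pixels is pushed through the inverse calibration curve to a uric
acid concentration in ppm (mg/L), scaled by the urine dilution factor so the
report refers to the undiluted sample.  The concluding remark classifies the
estimate against the published urinary acceptable range of 300-700 ppm.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

from ._exceptions import InputError
from .calibrate import (
    CalibrationCurve,
    TemperatureModel,
    correct_temperature,
    invert_calibration,
)
from .colorimg import RoiSpec, detect_spot_roi, extract_roi, load_image, rgb_to_gray, to_cmy

__all__ = [
    "ACCEPTABLE_RANGE_PPM",
    "Remark",
    "ConcentrationEstimate",
    "QuantResult",
    "eliminate_outliers",
    "mean_gray",
    "estimate_concentration",
    "make_remark",
    "quantify_image",
]

logger = logging.getLogger(__name__)

#: Published acceptable urinary uric acid range (ppm), boundaries inclusive.
ACCEPTABLE_RANGE_PPM = (300.0, 700.0)

#: One-sided 95% normal quantile for the delta-method interval half-width.
_Z95 = float(stats.norm.ppf(0.95))

Remark = Literal["below_range", "within_acceptable_limit", "above_acceptable_limit"]


@dataclasses.dataclass(frozen=True)
class ConcentrationEstimate:
    """A uric acid concentration estimate on the undiluted-sample scale."""

    ppm: float
    half_width: float  # delta-method interval half-width, ppm
    censored: Literal["none", "above_saturation"]
    dilution_factor: float
    temperature_c: float

    def __post_init__(self) -> None:
        if self.ppm < 0:
            raise InputError("concentration estimate must be >= 0 ppm")


@dataclasses.dataclass(frozen=True)
class QuantResult:
    """Full readout of one spot image."""

    mean_gray_cmy: float
    n_pixels_total: int
    n_outliers_removed: int
    estimate: ConcentrationEstimate
    remark: Remark

    def to_dict(self) -> dict:
        return {
            "mean_gray_cmy": self.mean_gray_cmy,
            "n_pixels_total": self.n_pixels_total,
            "n_outliers_removed": self.n_outliers_removed,
            "ppm": self.estimate.ppm,
            "half_width": self.estimate.half_width,
            "censored": self.estimate.censored,
            "remark": self.remark,
            "dilution_factor": self.estimate.dilution_factor,
            "temperature_c": self.estimate.temperature_c,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def report_line(self) -> str:
        bound = ">= " if self.estimate.censored == "above_saturation" else ""
        return (
            f"uric acid {bound}{self.estimate.ppm:.0f} ppm "
            f"(+/- {self.estimate.half_width:.0f}) -- {self.remark.replace('_', ' ')} "
            f"[mean CMY gray {self.mean_gray_cmy:.1f}, "
            f"{self.n_pixels_total} px, {self.n_outliers_removed} outliers removed]"
        )


def eliminate_outliers(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Single-pass Tukey-fence screen of a gray-value vector.

    Computes Q1 and Q3 with linear-interpolation quantiles and removes
    values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Applied once, not
    iterated, so the rule is idempotent only through its fences being
    recomputed on cleaner data (tested as a property).
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 5:
        raise InputError("too few pixels for outlier screening (need >= 5)")
    q1, q3 = np.quantile(vals, [0.25, 0.75])
    iqr = q3 - q1
    keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
    return vals[keep], int(vals.size - keep.sum())


def mean_gray(values: np.ndarray) -> float:
    """Arithmetic mean of a non-empty gray-value vector."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size == 0:
        raise InputError("cannot take the mean of an empty vector")
    return float(vals.mean())


def estimate_concentration(
    mean_gray_cmy: float,
    curve: CalibrationCurve,
    dilution_factor: float = 2.0,
    temperature_c: float = 25.0,
    temp_model: TemperatureModel | None = None,
) -> ConcentrationEstimate:
    """Invert the calibration curve for a mean CMY gray value.

    If a temperature model is supplied and the measurement temperature
    differs from the curve's reference, the gray value is first corrected
    for the linear thermal drift.  The inverted concentration is multiplied
    by ``dilution_factor`` so the result refers to the undiluted sample.
    The interval half-width comes from the delta method:
    z(0.95) * residual_sd / |dG/dC| at the estimate.
    """
    if curve is None:
        raise InputError("missing calibration curve")
    if dilution_factor < 1.0:
        raise InputError("dilution factor must be >= 1")

    gray = float(mean_gray_cmy)
    if temp_model is not None and temperature_c != curve.temperature_ref:
        corrected = correct_temperature(gray, temperature_c, temp_model)
        logger.info(
            "temperature correction: gray %.2f @ %.1f degC -> %.2f @ %.1f degC",
            gray, temperature_c, corrected, curve.temperature_ref,
        )
        gray = corrected

    conc_diluted, censored = invert_calibration(curve, gray)
    # |dG/dC| of the saturating model at the (diluted-scale) estimate
    dgdc = curve.span / curve.tau * np.exp(-conc_diluted / curve.tau)
    half_width = _Z95 * curve.residual_sd / dgdc * dilution_factor
    return ConcentrationEstimate(
        ppm=conc_diluted * dilution_factor,
        half_width=float(half_width),
        censored=censored,
        dilution_factor=dilution_factor,
        temperature_c=temperature_c,
    )


def make_remark(ppm: float) -> Remark:
    """Classify a ppm estimate against the 300-700 ppm acceptable range.

    Boundary values belong to the acceptable range.  Censored estimates
    should pass their lower bound.
    """
    if ppm < 0:
        raise InputError("concentration must be >= 0 ppm")
    low, high = ACCEPTABLE_RANGE_PPM
    if ppm < low:
        return "below_range"
    if ppm <= high:
        return "within_acceptable_limit"
    return "above_acceptable_limit"


def quantify_image(
    path: str | Path,
    curve: CalibrationCurve,
    roi: RoiSpec | None = None,
    dilution_factor: float = 2.0,
    temperature_c: float = 25.0,
    temp_model: TemperatureModel | None = None,
) -> QuantResult:
    """Run the full readout pipeline on one spot image.

    ``roi=None`` auto-detects the spot; pass an explicit
    :class:`~uripad.colorimg.RoiSpec` to override.
    """
    stage = "load_image"
    try:
        image = load_image(path)
        stage = "gray conversion"
        cmy = to_cmy(rgb_to_gray(image))
        stage = "ROI detection"
        if roi is None:
            roi = detect_spot_roi(cmy)
            logger.info(
                "auto ROI: center (%.1f, %.1f), radius %.1f px",
                roi.center[0], roi.center[1], roi.radius,
            )
        stage = "ROI extraction"
        pixels = extract_roi(cmy, roi)
        stage = "outlier elimination"
        filtered, n_removed = eliminate_outliers(pixels)
        logger.info("ROI %d px, removed %d outliers", pixels.size, n_removed)
        stage = "concentration estimation"
        gray = mean_gray(filtered)
        estimate = estimate_concentration(
            gray, curve, dilution_factor, temperature_c, temp_model
        )
    except InputError as exc:
        raise InputError(f"{stage}: {exc}") from exc
    remark = make_remark(estimate.ppm)
    result = QuantResult(
        mean_gray_cmy=gray,
        n_pixels_total=int(pixels.size),
        n_outliers_removed=n_removed,
        estimate=estimate,
        remark=remark,
    )
    logger.info("%s", result.report_line())
    return result
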