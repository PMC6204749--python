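"""Saturating concentration-gray calibration and temperature correction.

The colorimetric signal of the assay rises with uric acid concentration and
saturates; above the saturation point the color no longer discriminates
between concentrations.  The calibration model used here is an exponential
saturation,

    G(C) = G0 + (Gmax - G0) * (1 - exp(-C / tau)),

with baseline gray ``G0`` at 0 ppm, asymptote ``Gmax``, and concentration
scale ``tau`` (ppm).  The operational saturation concentration is where the
curve reaches 95% of its span, C_sat95 = tau * ln(20).  The model is
monotone and analytically invertible; inversion censors at C_sat95 (the
estimate becomes a lower bound) and clamps small sub-baseline signals to
0 ppm.

Gray value also drifts linearly with ambient temperature (the paper
substrate yellows when warm).  A straight-line temperature model fitted to
gray-vs-temperature data provides an additive correction back to the
curve's reference temperature.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._exceptions import AnalysisError, InputError

__all__ = [
    "Standard",
    "CalibrationCurve",
    "TemperatureModel",
    "predict_gray",
    "fit_calibration",
    "invert_calibration",
    "fit_temperature_model",
    "correct_temperature",
    "read_standards_csv",
    "write_standards_csv",
]

logger = logging.getLogger(__name__)

#: C_sat95 = tau * ln(20): the concentration at 95% of the curve's span.
LN20 = math.log(20.0)

CensorFlag = Literal["none", "above_saturation"]


@dataclasses.dataclass(frozen=True)
class Standard:
    """One calibration standard: a known concentration with replicate grays."""

    concentration: float  # ppm, on the applied (diluted) sample scale
    gray_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InputError("standard concentration must be >= 0 ppm")
        grays = tuple(float(g) for g in self.gray_replicates)
        if len(grays) < 1:
            raise InputError("standard needs at least one gray replicate")
        if min(grays) < 0 or max(grays) > 255:
            raise InputError("gray replicates must lie in [0, 255]")
        object.__setattr__(self, "gray_replicates", grays)

    @property
    def mean_gray(self) -> float:
        return float(np.mean(self.gray_replicates))


@dataclasses.dataclass(frozen=True)
class CalibrationCurve:
    """Fitted exponential-saturation calibration curve (CMY gray vs ppm)."""

    G0: float
    Gmax: float
    tau: float
    r_squared: float
    residual_sd: float
    n_standards: int
    temperature_ref: float = 25.0
    model_id: str = "expsat"

    def __post_init__(self) -> None:
        if self.Gmax <= self.G0:
            raise InputError("calibration requires Gmax > G0")
        if self.tau <= 0:
            raise InputError("calibration requires tau > 0")

    @property
    def C_sat95(self) -> float:
        return self.tau * LN20

    @property
    def span(self) -> float:
        return self.Gmax - self.G0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "G0": self.G0,
            "Gmax": self.Gmax,
            "tau": self.tau,
            "C_sat95": self.C_sat95,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n_standards": self.n_standards,
            "temperature_ref": self.temperature_ref,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        if d.get("model_id", "expsat") != "expsat":
            raise InputError(f"unsupported calibration model {d.get('model_id')!r}")
        return cls(
            G0=float(d["G0"]),
            Gmax=float(d["Gmax"]),
            tau=float(d["tau"]),
            r_squared=float(d["r_squared"]),
            residual_sd=float(d["residual_sd"]),
            n_standards=int(d["n_standards"]),
            temperature_ref=float(d.get("temperature_ref", 25.0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        path = Path(path)
        if not path.exists():
            raise InputError(f"calibration file '{path}' not found")
        try:
            return cls.from_dict(json.loads(path.read_text()))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise InputError(f"invalid calibration file '{path}': {exc}") from exc


@dataclasses.dataclass(frozen=True)
class TemperatureModel:
    """Linear gray-vs-temperature drift model: gray = intercept + slope * T."""

    slope: float  # gray units per degree C
    intercept: float
    reference_temp: float
    r_squared: float

    def predict(self, temperature_c: float) -> float:
        return self.intercept + self.slope * temperature_c

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "reference_temp": self.reference_temp,
            "r_squared": self.r_squared,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TemperatureModel":
        path = Path(path)
        if not path.exists():
            raise InputError(f"temperature model file '{path}' not found")
        try:
            d = json.loads(path.read_text())
            return cls(
                slope=float(d["slope"]),
                intercept=float(d["intercept"]),
                reference_temp=float(d["reference_temp"]),
                r_squared=float(d["r_squared"]),
            )
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise InputError(f"invalid temperature model file '{path}': {exc}") from exc


def _expsat(c: np.ndarray, g0: float, gmax: float, tau: float) -> np.ndarray:
    return g0 + (gmax - g0) * (1.0 - np.exp(-c / tau))


def predict_gray(curve: CalibrationCurve, concentration: float | np.ndarray) -> float | np.ndarray:
    """Forward calibration model: gray at a given concentration (ppm)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise InputError("concentration must be >= 0 ppm")
    out = _expsat(c, curve.G0, curve.Gmax, curve.tau)
    return float(out) if np.isscalar(concentration) else out


def fit_calibration(
    standards: Sequence[Standard],
    temperature_ref: float = 25.0,
) -> CalibrationCurve:
    """Fit the exponential-saturation curve to replicate calibration points.

    Requires >= 4 distinct concentrations, anchored at both ends (one
    standard <= 50 ppm and one >= 400 ppm) so that baseline and plateau are
    both identifiable.  Nonlinear least squares over all replicate points;
    initialization G0 = mean gray at the lowest concentration, Gmax = max
    mean gray, tau = half the largest concentration.
    """
    if len(standards) == 0:
        raise InputError("no calibration standards supplied")
    concs = np.array([s.concentration for s in standards], dtype=float)
    distinct = np.unique(concs)
    if distinct.size < 4:
        raise InputError("need at least 4 distinct standard concentrations")
    if distinct.min() > 50.0:
        raise InputError("need a low anchor standard (<= 50 ppm)")
    if distinct.max() < 400.0:
        raise InputError("need a high anchor standard (>= 400 ppm)")

    order = np.argsort([s.concentration for s in standards])
    means = np.array([standards[i].mean_gray for i in order])
    sorted_concs = concs[order]
    # gross inversion guard: grays falling with concentration over the
    # (identifiable) lower half of the range cannot come from this chemistry
    lower = means[sorted_concs <= np.median(distinct)]
    if lower.size >= 2 and np.all(np.diff(lower) <= 0) and np.any(np.diff(lower) < 0):
        raise InputError("non-monotone standards")

    c_all = np.concatenate([[s.concentration] * len(s.gray_replicates) for s in standards])
    g_all = np.concatenate([s.gray_replicates for s in standards])

    p0 = [means[0], float(means.max()), float(distinct.max()) / 2.0]
    try:
        popt, _ = optimize.curve_fit(
            _expsat, c_all, g_all, p0=p0, xtol=1e-8, ftol=1e-8, maxfev=20000
        )
    except RuntimeError as exc:
        raise AnalysisError(f"calibration fit did not converge: {exc}") from exc
    g0, gmax, tau = (float(v) for v in popt)
    if not (gmax > g0 and tau > 0):
        raise AnalysisError(
            f"calibration fit produced a non-increasing curve "
            f"(G0={g0:.3g}, Gmax={gmax:.3g}, tau={tau:.3g})"
        )

    resid = g_all - _expsat(c_all, g0, gmax, tau)
    ssr = float(resid @ resid)
    sst = float(np.sum((g_all - g_all.mean()) ** 2))
    r_squared = 1.0 - ssr / sst if sst > 0 else 1.0
    dof = max(g_all.size - 3, 1)
    curve = CalibrationCurve(
        G0=g0,
        Gmax=gmax,
        tau=tau,
        r_squared=r_squared,
        residual_sd=math.sqrt(ssr / dof),
        n_standards=int(distinct.size),
        temperature_ref=temperature_ref,
    )
    logger.info(
        "fitted calibration: G0=%.2f Gmax=%.2f tau=%.1f C_sat95=%.1f ppm r2=%.4f",
        g0, gmax, tau, curve.C_sat95, r_squared,
    )
    return curve


def invert_calibration(curve: CalibrationCurve, gray: float) -> tuple[float, CensorFlag]:
    """Invert the calibration curve: gray value -> (ppm, censoring flag).

    Grays at or above 95% of the fitted span return (C_sat95,
    "above_saturation"): the concentration is reported as a lower bound
    because the signal no longer discriminates.  Grays slightly below
    baseline (within 2 residual SD) clamp to 0 ppm; anything lower is
    rejected as signal below blank.
    """
    if gray >= curve.G0 + 0.95 * curve.span:
        return curve.C_sat95, "above_saturation"
    if gray >= curve.G0:
        conc = -curve.tau * math.log(1.0 - (gray - curve.G0) / curve.span)
        return conc, "none"
    if gray > curve.G0 - 2.0 * curve.residual_sd:
        return 0.0, "none"
    raise InputError(
        f"signal below blank: gray {gray:.2f} is more than 2 residual SD "
        f"below baseline G0={curve.G0:.2f}"
    )


def fit_temperature_model(
    pairs: Sequence[tuple[float, float]],
    reference_temp: float = 25.0,
) -> TemperatureModel:
    """Ordinary least-squares line of gray value on temperature (deg C)."""
    temps = np.array([p[0] for p in pairs], dtype=float)
    grays = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(temps).size < 3:
        raise InputError("need at least 3 distinct temperatures")
    if not temps.min() <= reference_temp <= temps.max():
        raise InputError(
            f"reference temperature {reference_temp} degC outside fitted range "
            f"[{temps.min()}, {temps.max()}]"
        )
    fit = stats.linregress(temps, grays)
    return TemperatureModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        reference_temp=reference_temp,
        r_squared=float(fit.rvalue) ** 2,
    )


def correct_temperature(gray: float, temperature_c: float, model: TemperatureModel) -> float:
    """Shift a gray value measured at ``temperature_c`` back to the reference.

    gray_corrected = gray - slope * (T - T_ref), clamped to [0, 255].
    """
    corrected = gray - model.slope * (temperature_c - model.reference_temp)
    if corrected < 0.0 or corrected > 255.0:
        logger.warning(
            "temperature-corrected gray %.2f outside [0, 255]; clamping", corrected
        )
        corrected = min(max(corrected, 0.0), 255.0)
    return corrected


def read_standards_csv(path: str | Path) -> list[Standard]:
    """Read standards from CSV (columns concentration_ppm, gray; one row per replicate)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"standards file '{path}' not found")
    df = pd.read_csv(path)
    missing = {"concentration_ppm", "gray"} - set(df.columns)
    if missing:
        raise InputError(f"standards CSV '{path}' missing columns: {sorted(missing)}")
    return [
        Standard(concentration=float(conc), gray_replicates=tuple(group["gray"]))
        for conc, group in df.groupby("concentration_ppm", sort=True)
    ]


def write_standards_csv(standards: Sequence[Standard], path: str | Path) -> None:
    rows = [
        {"concentration_ppm": s.concentration, "gray": g}
        for s in standards
        for g in s.gray_replicates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
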