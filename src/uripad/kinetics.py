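"""Reaction-order selection and rate-constant estimation for color formation.

Prussian blue forms on the activated paper over a few seconds; a video of
the spot, converted to frames at a known rate, gives a time series x(t) of
CMY gray intensity (a proxy for product formed).  With ``a`` the limiting
intensity at completion (proxy for the initial reactant amount), the three
classical integrated rate laws linearize as

    zero order:    x = K t
    first order:   2.303 * log10(a - x) = -K t + c
    second order:  1 / (a - x) = K t + c

Each candidate order is fitted by ordinary least squares on its linearized
axis; the order whose straight line fits best (highest r^2) is selected and
its slope converted to the rate constant K (first order: K = -2.303 x the
log10 slope, in s^-1).  The asymptote ``a`` is not directly observable in a
finite recording; it is estimated by a grid search that maximizes the
first-order linearity.

Fits use only the pre-completion window x <= 0.95 a (roughly the first
three half-lives).  Past that point the remaining signal a - x has decayed
below typical measurement noise, and least squares on log10(a - x) would be
dominated by noise with an asymmetric (downward) bias on K; the straight
portion of the log plot is what carries the rate information.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import AnalysisError, InputError

__all__ = [
    "KineticsSeries",
    "OrderFit",
    "KineticsResult",
    "frames_to_series",
    "estimate_asymptote",
    "linearize",
    "fit_order",
    "analyze_kinetics",
    "read_series_csv",
    "write_series_csv",
]

logger = logging.getLogger(__name__)

#: Conversion between natural-log and log10 slopes: the classical "2.303 x
#: log" factor is the rounded ln 10; full precision keeps noiseless fits exact.
LN10 = math.log(10.0)

_MIN_SAMPLES = 10


@dataclasses.dataclass(frozen=True)
class KineticsSeries:
    """A color-formation time series: times (s, from 0) and CMY intensities."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        if t.size != x.size:
            raise InputError("times and intensities must have equal length")
        if t.size < _MIN_SAMPLES:
            raise InputError(f"kinetics series needs >= {_MIN_SAMPLES} samples")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise InputError("times must be non-negative and strictly increasing")
        if x.min() < 0 or x.max() > 255:
            raise InputError("intensities must lie in [0, 255]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", x)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclasses.dataclass(frozen=True)
class OrderFit:
    """Linearized least-squares fit for one candidate reaction order."""

    order: int
    a_used: float
    slope: float
    intercept: float
    r_squared: float
    K: float  # s^-1 for order 1; gray/s for order 0; gray^-1 s^-1 for order 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class KineticsResult:
    """All three order fits plus the selected (best-r^2) order."""

    fits: dict[int, OrderFit]
    best_order: int
    a_estimate: float

    @property
    def K_best(self) -> float:
        return self.fits[self.best_order].K

    def to_dict(self) -> dict:
        return {
            "a_estimate": self.a_estimate,
            "best_order": self.best_order,
            "K_best": self.K_best,
            "fits": {str(o): f.to_dict() for o, f in sorted(self.fits.items())},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def frames_to_series(frame_grays: Sequence[float], fps: float = 30.0) -> KineticsSeries:
    """Build a series from per-frame mean spot grays captured at ``fps``."""
    if fps <= 0:
        raise InputError("fps must be positive")
    grays = np.asarray(frame_grays, dtype=float)
    times = np.arange(grays.size, dtype=float) / fps
    return KineticsSeries(times=times, intensities=grays)


def _fit_window(x: np.ndarray, a: float) -> np.ndarray:
    """Pre-completion window: keep points with x <= 0.95 a.

    Beyond 95% of completion a - x is typically smaller than measurement
    noise and the linearized axes carry no rate information.  Falls back to
    all points if fewer than 5 survive.
    """
    mask = x <= 0.95 * a
    if mask.sum() < 5:
        return np.ones_like(mask)
    return mask


def estimate_asymptote(series: KineticsSeries, n_grid: int = 200, order: int = 1) -> float:
    """Estimate the asymptote ``a`` by maximizing linearized-fit quality.

    Grid search over a in (max(x), 1.5 * max(x)] in ``n_grid`` equal steps;
    returns the candidate maximizing r^2 of the ``order`` linearization
    (first order by default, over its pre-completion window), ties broken
    toward smaller a.
    """
    if order not in (1, 2):
        raise InputError("asymptote estimation applies to orders 1 and 2 only")
    x = series.intensities
    xmax = float(x.max())
    if xmax <= 0:
        raise InputError("no product formation (all intensities are zero)")

    cands = xmax * (1.0 + np.arange(1, n_grid + 1) * (0.5 / n_grid))
    best_a, best_r2 = None, -np.inf
    for a in cands:
        t_w, y_w = linearize(series, order, float(a))
        if np.ptp(t_w) == 0.0 or np.ptp(y_w) == 0.0:
            continue
        tc = t_w - t_w.mean()
        yc = y_w - y_w.mean()
        r2 = float(tc @ yc) ** 2 / (float(tc @ tc) * float(yc @ yc))
        if r2 > best_r2:  # strict: ties keep the earlier (smaller) a
            best_a, best_r2 = float(a), r2
    if best_a is None:
        raise AnalysisError(
            "degenerate kinetics series: intensities carry no curvature to fit"
        )
    return best_a


def linearize(
    series: KineticsSeries, order: int, a: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Transform intensities onto the straight-line axis of a candidate order.

    When ``a`` is supplied the returned points are restricted to the
    pre-completion window x <= 0.95 a (same window for every order, so the
    r^2 values compete on the same data).
    """
    x = series.intensities
    t = series.times
    if order not in (0, 1, 2):
        raise InputError(f"reaction order must be 0, 1 or 2, got {order}")
    if order == 0:
        if a is not None:
            w = _fit_window(x, a)
            return t[w], x[w].copy()
        return t, x.copy()
    if a is None or a <= float(x.max()):
        raise InputError(f"order {order} linearization requires a > max(x)")
    w = _fit_window(x, a)
    if order == 1:
        return t[w], np.log10(a - x[w])
    return t[w], 1.0 / (a - x[w])


def fit_order(series: KineticsSeries, order: int, a: float | None = None) -> OrderFit:
    """OLS fit of the linearized series; extract the rate constant K.

    order 0: K = slope (gray/s); order 1: K = -2.303 x slope of the log10
    fit (s^-1); order 2: K = slope (gray^-1 s^-1).
    """
    t, y = linearize(series, order, a)
    if np.ptp(t) == 0:
        raise AnalysisError("degenerate series: zero time variance")
    fit = stats.linregress(t, y)
    slope = float(fit.slope)
    k = -LN10 * slope if order == 1 else slope
    r_squared = float(fit.rvalue) ** 2 if np.ptp(y) > 0 else 0.0
    return OrderFit(
        order=order,
        a_used=float(a) if a is not None else float(series.intensities.max()),
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=r_squared,
        K=k,
    )


def analyze_kinetics(series: KineticsSeries) -> KineticsResult:
    """Estimate ``a``, fit all three candidate orders, select the best.

    best_order maximizes r^2 of the linearized fit; all three fits are
    reported so a borderline selection is visible to the user.  Orders 1
    and 2 each get the asymptote that best linearizes their own axis:
    comparing both against a single first-order-tuned ``a`` would handicap
    the second-order fit on genuinely second-order data.
    """
    a = estimate_asymptote(series, order=1)
    try:
        a2 = estimate_asymptote(series, order=2)
    except AnalysisError:
        a2 = a
    fits = {
        0: fit_order(series, 0, a),
        1: fit_order(series, 1, a),
        2: fit_order(series, 2, a2),
    }
    best_order = max(fits, key=lambda o: fits[o].r_squared)
    logger.info(
        "kinetics: a=%.2f, r2 by order %s, best order %d, K=%.4g",
        a,
        {o: round(f.r_squared, 4) for o, f in fits.items()},
        best_order,
        fits[best_order].K,
    )
    return KineticsResult(fits=fits, best_order=best_order, a_estimate=a)


def read_series_csv(path: str | Path, fps: float | None = None) -> KineticsSeries:
    """Read a kinetics CSV: columns (time_s, intensity) or (frame_index, intensity).

    Frame-indexed files require ``fps`` to convert indices to seconds.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"kinetics file '{path}' not found")
    df = pd.read_csv(path)
    if "intensity" not in df.columns:
        raise InputError(f"kinetics CSV '{path}' missing 'intensity' column")
    if "time_s" in df.columns:
        return KineticsSeries(
            times=df["time_s"].to_numpy(float),
            intensities=df["intensity"].to_numpy(float),
        )
    if "frame_index" in df.columns:
        if fps is None:
            raise InputError("frame-indexed kinetics CSV requires an fps value")
        order = np.argsort(df["frame_index"].to_numpy())
        return frames_to_series(df["intensity"].to_numpy(float)[order], fps=fps)
    raise InputError(f"kinetics CSV '{path}' needs a 'time_s' or 'frame_index' column")


def write_series_csv(series: KineticsSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times, "intensity": series.intensities}).to_csv(
        path, index=False
    )
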