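"""Synthetic fixtures with known ground truth for every pipeline stage.

No public image dataset exists for this assay, so testing relies on a
generator whose defaults emulate the study conditions end to end:

* calibration truth G0 = 20, Gmax = 170, tau = 500/ln 20 gray/ppm, so the
  signal reaches 95% of its span (operational saturation) at exactly
  500 ppm;
* first-order color formation x(t) = a (1 - e^(-K t)) with K = 0.64 s^-1
  and a = 150 gray, sampled at 30 frames/s for 10 s;
* linear thermal drift through (25 degC, 82 gray) and (50 degC, 96 gray),
  i.e. slope 0.56 gray/degC;
* noise defaults: pixel SD 2 gray, series SD 1 gray, and a 2% fraction of
  outlier pixels shifted +60 CMY gray (dust / coffee-ring artifacts).

Every generator is a pure function of its parameters and an explicit seed;
there is no global random state.  Spot images are neutral gray (R = G = B);
the hue of the real pigment is cosmetic and never enters the gray value.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from ._exceptions import InputError
from .calibrate import CalibrationCurve, Standard, write_standards_csv
from .kinetics import KineticsSeries, write_series_csv

__all__ = [
    "TruthBundle",
    "truth_curve",
    "gen_spot_image",
    "gen_standards",
    "gen_kinetics",
    "gen_temperature",
    "write_temperature_csv",
    "write_fixture_set",
]

DEFAULT_TEMPS = (25.0, 30.0, 35.0, 40.0, 45.0, 50.0)


@dataclasses.dataclass(frozen=True)
class TruthBundle:
    """Ground-truth parameters the generators draw from.

    Calibration truth (g0, gmax, tau), kinetics truth (k_rate, a_asymptote),
    temperature anchors, and noise levels.  Defaults reproduce the study
    conditions: saturation at 500 ppm, K = 0.64 s^-1, gray 82 at 25 degC and
    96 at 50 degC.
    """

    g0: float = 20.0
    gmax: float = 170.0
    tau: float = 500.0 / math.log(20.0)
    k_rate: float = 0.64  # s^-1
    a_asymptote: float = 150.0  # gray
    temp_anchor_low: tuple[float, float] = (25.0, 82.0)  # (degC, gray)
    temp_anchor_high: tuple[float, float] = (50.0, 96.0)
    pixel_sd: float = 2.0  # gray, per-pixel noise in spot images
    series_sd: float = 1.0  # gray, per-sample noise in time/temperature series
    outlier_fraction: float = 0.02
    outlier_shift: float = 60.0  # CMY gray added to outlier pixels

    def __post_init__(self) -> None:
        if not (self.gmax > self.g0 and self.tau > 0):
            raise InputError("truth curve requires gmax > g0 and tau > 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise InputError("outlier_fraction must lie in [0, 1)")

    @property
    def temp_slope(self) -> float:
        (t0, g0), (t1, g1) = self.temp_anchor_low, self.temp_anchor_high
        return (g1 - g0) / (t1 - t0)

    def predict_gray(self, concentration: float) -> float:
        return self.g0 + (self.gmax - self.g0) * (1.0 - math.exp(-concentration / self.tau))

    def predict_temperature_gray(self, temperature_c: float) -> float:
        t0, g0 = self.temp_anchor_low
        return g0 + self.temp_slope * (temperature_c - t0)

    def noiseless(self) -> "TruthBundle":
        """Copy with all noise sources switched off."""
        return dataclasses.replace(
            self, pixel_sd=0.0, series_sd=0.0, outlier_fraction=0.0
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def truth_curve(truth: TruthBundle) -> CalibrationCurve:
    """The generator's truth as a CalibrationCurve (for noiseless round trips)."""
    return CalibrationCurve(
        G0=truth.g0,
        Gmax=truth.gmax,
        tau=truth.tau,
        r_squared=1.0,
        residual_sd=0.0,
        n_standards=0,
    )


def gen_spot_image(
    concentration: float,
    truth: TruthBundle,
    size: int = 200,
    spot_radius: float = 60.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a circular reagent spot on white paper as an RGB uint8 array.

    Disc pixels carry CMY gray = truth curve value + N(0, pixel_sd); a
    fraction of them is shifted +outlier_shift to mimic dark artifacts.
    Channels are identical (R = G = B = 255 - CMY), clamped and rounded.
    """
    if concentration < 0:
        raise InputError("concentration must be >= 0 ppm")
    if spot_radius >= size / 2:
        raise InputError("spot_radius must be smaller than half the image size")

    rng = np.random.default_rng(seed)
    rows, cols = np.indices((size, size))
    center = (size - 1) / 2.0
    disc = np.hypot(rows - center, cols - center) <= spot_radius
    n_disc = int(disc.sum())

    cmy = np.full((size, size), 0.0)  # white background: CMY gray 0
    spot_vals = truth.predict_gray(concentration) + rng.normal(0.0, truth.pixel_sd, n_disc)
    n_out = int(round(truth.outlier_fraction * n_disc))
    if n_out > 0:
        idx = rng.choice(n_disc, size=n_out, replace=False)
        spot_vals[idx] += truth.outlier_shift
    cmy[disc] = spot_vals

    rgb = np.clip(np.rint(255.0 - cmy), 0, 255).astype(np.uint8)
    return np.stack([rgb] * 3, axis=-1)


def gen_standards(
    concentrations: Sequence[float],
    truth: TruthBundle,
    replicates: int = 4,
    seed: int = 0,
) -> list[Standard]:
    """Simulate a calibration experiment: replicate mean grays per standard.

    Each replicate is the truth-curve gray plus N(0, pixel_sd / sqrt(1000)),
    the noise left after averaging a ~1000-pixel spot.
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rep_sd = truth.pixel_sd / math.sqrt(1000.0)
    out = []
    for conc in concentrations:
        grays = truth.predict_gray(conc) + rng.normal(0.0, rep_sd, replicates)
        out.append(Standard(concentration=float(conc), gray_replicates=tuple(grays)))
    return out


def gen_kinetics(
    truth: TruthBundle,
    fps: float = 30.0,
    duration_s: float = 10.0,
    seed: int = 0,
) -> KineticsSeries:
    """Simulate first-order color formation sampled at ``fps`` for ``duration_s``.

    x(t) = a (1 - e^(-K t)) + N(0, series_sd), clamped to [0, a - 0.01] so
    the observed intensity never reaches the asymptote.
    """
    if fps <= 0 or duration_s <= 0:
        raise InputError("fps and duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    times = np.arange(n) / fps
    x = truth.a_asymptote * (1.0 - np.exp(-truth.k_rate * times))
    x = x + rng.normal(0.0, truth.series_sd, n)
    x = np.clip(x, 0.0, truth.a_asymptote - 0.01)
    return KineticsSeries(times=times, intensities=x)


def gen_temperature(
    temps: Sequence[float] = DEFAULT_TEMPS,
    truth: TruthBundle = TruthBundle(),
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Simulate gray value vs temperature along the linear truth drift."""
    rng = np.random.default_rng(seed)
    return [
        (float(t), truth.predict_temperature_gray(t) + rng.normal(0.0, truth.series_sd))
        for t in temps
    ]


def write_temperature_csv(pairs: Sequence[tuple[float, float]], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(pairs, columns=["temperature_c", "gray"]).to_csv(path, index=False)


def write_fixture_set(
    out_dir: str | Path,
    kind: str,
    truth: TruthBundle,
    seed: int = 0,
    **params,
) -> dict:
    """Write one fixture set (spot | standards | kinetics | temperature) + manifest.

    Returns the manifest dict; files land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"kind": kind, "seed": seed, "truth": truth.to_dict(), "params": params}

    if kind == "spot":
        conc = params.get("concentration", 200.0)
        image = gen_spot_image(
            conc,
            truth,
            size=params.get("size", 200),
            spot_radius=params.get("spot_radius", 60.0),
            seed=seed,
        )
        fname = f"spot_{conc:g}ppm_seed{seed}.png"
        Image.fromarray(image).save(out_dir / fname)
        manifest["files"] = [fname]
    elif kind == "standards":
        concs = params.get("concentrations", list(np.arange(0.0, 1001.0, 50.0)))
        standards = gen_standards(
            concs, truth, replicates=params.get("replicates", 4), seed=seed
        )
        fname = f"standards_seed{seed}.csv"
        write_standards_csv(standards, out_dir / fname)
        manifest["files"] = [fname]
        manifest["params"]["concentrations"] = [float(c) for c in concs]
    elif kind == "kinetics":
        series = gen_kinetics(
            truth,
            fps=params.get("fps", 30.0),
            duration_s=params.get("duration_s", 10.0),
            seed=seed,
        )
        fname = f"kinetics_seed{seed}.csv"
        write_series_csv(series, out_dir / fname)
        manifest["files"] = [fname]
    elif kind == "temperature":
        pairs = gen_temperature(params.get("temps", DEFAULT_TEMPS), truth, seed=seed)
        fname = f"temperature_seed{seed}.csv"
        write_temperature_csv(pairs, out_dir / fname)
        manifest["files"] = [fname]
        manifest["params"]["temps"] = [float(t) for t in params.get("temps", DEFAULT_TEMPS)]
    else:
        raise InputError(f"unknown fixture kind {kind!r}")

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
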