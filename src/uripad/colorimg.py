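"""Image loading, color-scheme conversion, and spot ROI extraction.

A photographed or scanned reagent spot enters the pipeline as an 8-bit RGB
raster.  Per-pixel gray values are the channel mean, gray = (R + G + B) / 3,
on the usual 0 (black) .. 255 (white) scale.  Because the assay product
(Prussian blue) darkens with analyte concentration, quantification uses the
complementary CMY gray value, CMY = 255 - RGB, on which darker = higher =
more analyte.

The region of interest (ROI) is the set of pixels inside the reagent spot.
Spots can be addressed explicitly (full image, or an explicit circle) or
detected automatically by thresholding against the white paper background.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import measure

from ._exceptions import InputError

__all__ = [
    "RGB_GRAY",
    "CMY_GRAY",
    "GrayMatrix",
    "RoiSpec",
    "load_image",
    "rgb_to_gray",
    "to_cmy",
    "detect_spot_roi",
    "extract_roi",
]

RGB_GRAY = "rgb_gray"
CMY_GRAY = "cmy_gray"

#: Minimum image side length that still leaves a usable border + spot.
_MIN_SIDE = 16


def _as_pixel_array(image: np.ndarray) -> np.ndarray:
    """Validate an H x W x 3 array of 8-bit RGB intensities."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise InputError("channel values must lie in [0, 255]")
    return arr


@dataclasses.dataclass(frozen=True)
class GrayMatrix:
    """Per-pixel gray values tagged with their color scheme.

    Values may be fractional (the channel mean is kept exact; rounding to
    integers happens only at display).  ``scheme`` is ``rgb_gray`` (255 =
    white) or ``cmy_gray`` (255 = black); the tag exists so a conversion is
    never applied twice.
    """

    values: np.ndarray
    scheme: Literal["rgb_gray", "cmy_gray"]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.scheme not in (RGB_GRAY, CMY_GRAY):
            raise InputError(f"unknown gray scheme {self.scheme!r}")
        if vals.size == 0:
            raise InputError("empty gray matrix")
        if vals.min() < 0 or vals.max() > 255:
            raise InputError("gray values must lie in [0, 255]")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class RoiSpec:
    """Region-of-interest specification.

    mode ``full`` uses every pixel; ``circle`` and ``auto`` use the disc of
    ``radius`` pixels around ``center`` (row, col; 0-based pixel centers).
    ``margin_fraction`` records the radial shrink already applied by
    auto-detection to exclude edge / coffee-ring pixels.
    """

    mode: Literal["full", "circle", "auto"]
    center: tuple[float, float] | None = None
    radius: float | None = None
    margin_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("full", "circle", "auto"):
            raise InputError(f"unknown ROI mode {self.mode!r}")
        if not 0.0 <= self.margin_fraction < 0.5:
            raise InputError("margin_fraction must lie in [0, 0.5)")
        if self.mode in ("circle", "auto"):
            if self.center is None or self.radius is None:
                raise InputError(f"mode {self.mode!r} requires center and radius")
            if self.radius <= 0:
                raise InputError("ROI radius must be positive")


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG/TIFF raster as an H x W x 3 uint8 RGB array.

    Grayscale images are promoted to three identical channels, alpha
    channels are dropped, and 16-bit rasters are rescaled to 8 bits by
    integer division by 257 (so 65535 maps to 255 exactly).
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise InputError(f"cannot read image file '{path}': {exc}") from exc

    if arr.dtype == np.uint16 or (arr.dtype.kind == "i" and arr.max(initial=0) > 255):
        arr = (arr.astype(np.uint32) // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)

    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"cannot interpret '{path}' as an RGB raster (shape {arr.shape})")

    if arr.shape[0] < _MIN_SIDE or arr.shape[1] < _MIN_SIDE:
        raise InputError("image too small for ROI analysis")
    return arr


def rgb_to_gray(image: np.ndarray) -> GrayMatrix:
    """Convert an RGB pixel array to gray values: gray = (R + G + B) / 3.

    The mean is kept as an exact fraction (float), not rounded.
    """
    arr = _as_pixel_array(image)
    gray = arr.astype(float).mean(axis=2)
    return GrayMatrix(values=gray, scheme=RGB_GRAY)


def to_cmy(gray: GrayMatrix) -> GrayMatrix:
    """Convert an rgb_gray matrix to the CMY scheme: CMY = 255 - RGB.

    On the CMY scale the darker the color, the higher the gray value, so
    intensity increases with analyte concentration.
    """
    if gray.scheme == CMY_GRAY:
        raise InputError("double conversion: gray matrix is already cmy_gray")
    return GrayMatrix(values=255.0 - gray.values, scheme=CMY_GRAY)


def detect_spot_roi(gray: GrayMatrix, margin_fraction: float = 0.15) -> RoiSpec:
    """Auto-detect a single dark spot on a lighter background.

    Thresholds at (border median + 3 x border MAD) where the background
    sample is the outer 10% frame of the image, keeps the largest connected
    component above threshold, fits the enclosing circle centred on the
    component centroid, and shrinks the radius by ``margin_fraction`` to
    exclude edge / coffee-ring pixels.
    """
    if gray.scheme != CMY_GRAY:
        raise InputError("spot detection expects a cmy_gray matrix (dark spot = high value)")
    vals = gray.values
    h, w = vals.shape

    border = max(1, round(0.1 * min(h, w)))
    border_mask = np.ones((h, w), dtype=bool)
    border_mask[border:-border, border:-border] = False
    bg = vals[border_mask]
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    threshold = med + 3.0 * mad

    mask = vals > threshold
    if not mask.any():
        raise InputError("no spot detected")

    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    component = labels == sizes.argmax()

    edge = np.zeros((h, w), dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if component[edge].sum() > 0.5 * edge.sum():
        raise InputError("spot not separable from background")

    rows, cols = np.nonzero(component)
    center = (float(rows.mean()), float(cols.mean()))
    radius = float(np.hypot(rows - center[0], cols - center[1]).max())
    return RoiSpec(
        mode="auto",
        center=center,
        radius=radius * (1.0 - margin_fraction),
        margin_fraction=margin_fraction,
    )


def extract_roi(gray: GrayMatrix, roi: RoiSpec) -> np.ndarray:
    """Return the gray values of the pixels inside the ROI as a 1-D vector.

    Circle membership is decided by pixel-center distance (row-major,
    0-based indices).  The pixel count is ``result.size``.
    """
    vals = gray.values
    if roi.mode == "full":
        return vals.ravel().copy()

    h, w = vals.shape
    cr, cc = roi.center  # type: ignore[misc]
    if not (-0.5 <= cr - roi.radius and cr + roi.radius <= h - 0.5
            and -0.5 <= cc - roi.radius and cc + roi.radius <= w - 0.5):
        raise InputError("ROI extends outside the image")
    rows, cols = np.indices((h, w))
    inside = np.hypot(rows - cr, cols - cc) <= roi.radius
    if not inside.any():
        raise InputError("empty ROI")
    return vals[inside]
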