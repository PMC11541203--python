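"""Reading and writing brightfield images, manifests, and overlays.

All images are normalised to a single canonical in-memory form: a 2-D
float array of intensities on the 0-255 scale (:class:`GrayImage`), with
an optional physical pixel size in mm attached.  The 0-255 scale matters
because the segmentation chain's background threshold (default 90) is
defined on it.

Supported inputs are single-frame grayscale or RGB(A) PNG and TIFF:

* 8-bit data passes through unchanged;
* 16-bit data is rescaled linearly by 255/65535 (full-range, never
  percentile-based, so the threshold stays interpretable);
* RGB is collapsed with the ITU-R 601 luma weights (0.299, 0.587,
  0.114); an alpha channel, if present, is dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage

from .errors import (
    ImageReadError,
    ManifestParseError,
    SchemaError,
    UnsupportedFormatError,
    ValidationError,
)

#: ITU-R 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Smallest accepted image edge, in pixels.
MIN_IMAGE_SIDE = 8

#: RGB colour used to draw mask boundaries in overlays.
OVERLAY_COLOR = (255, 0, 0)


@dataclass
class GrayImage:
    """A 2-D intensity raster on the 0-255 scale.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with values in [0, 255].
    pixel_size_mm : float, optional
        Physical edge length of one pixel in mm. ``None`` means the
        image is only calibrated in pixel units.
    """

    pixels: np.ndarray
    pixel_size_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"GrayImage requires a 2-D array, got ndim={self.pixels.ndim}"
            )
        h, w = self.pixels.shape
        if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image of {h}x{w} px is below the minimum of "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 255.0:
            raise ValidationError(
                f"intensities must lie in [0, 255], got range [{lo}, {hi}]"
            )
        if self.pixel_size_mm is not None and not self.pixel_size_mm > 0:
            raise ValidationError("pixel_size_mm must be > 0 when given")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImageRecord:
    """One manifest row: an image file with its grouping keys."""

    file_path: str
    cell_line: str
    day: int

    def __post_init__(self) -> None:
        if not self.cell_line:
            raise ValidationError("cell_line must be non-empty")
        if not isinstance(self.day, (int, np.integer)) or self.day < 0:
            raise ValidationError(f"day must be a non-negative integer, got {self.day!r}")
        self.day = int(self.day)


def _to_gray(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        arr2 = (
            LUMA_WEIGHTS[0] * rgb[..., 0]
            + LUMA_WEIGHTS[1] * rgb[..., 1]
            + LUMA_WEIGHTS[2] * rgb[..., 2]
        )
    elif arr.ndim == 2:
        arr2 = arr.astype(np.float64)
    else:
        raise UnsupportedFormatError(
            f"{path}: multi-frame stacks or unsupported layouts are not "
            f"supported (got array of shape {arr.shape})"
        )
    return arr2


def load_image(path: str | Path, pixel_size_mm: float | None = None) -> GrayImage:
    """Load a single-frame PNG/TIFF and normalise it to the 0-255 scale.

    8-bit values pass through unchanged, 16-bit values are rescaled by
    255/65535, and RGB images are converted with the ITU-R 601 luma
    weights then clipped to [0, 255].
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError, RuntimeError, TypeError) as exc:
        raise ImageReadError(f"could not read image file {path}: {exc}") from exc

    dtype = arr.dtype
    gray = _to_gray(arr, str(path))
    if dtype == np.uint16:
        gray = gray * (255.0 / 65535.0)
    elif dtype == np.bool_:
        gray = gray * 255.0
    gray = np.clip(gray, 0.0, 255.0)
    return GrayImage(gray, pixel_size_mm=pixel_size_mm)


def save_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as an 8-bit grayscale PNG.

    Intensities are rounded to the nearest integer; an 8-bit round trip
    through :func:`load_image` reproduces integer-valued images exactly.
    """
    data = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Read a batch manifest CSV with columns file_path, cell_line, day.

    Row numbers in error messages count the header line as row 1, so the
    first data row is row 2.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty manifest")
        missing = [c for c in ("file_path", "cell_line", "day") if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
        records: list[ImageRecord] = []
        for i, row in enumerate(reader):
            rownum = i + 2
            raw_day = (row["day"] or "").strip()
            try:
                day = int(raw_day)
            except ValueError:
                raise ManifestParseError(
                    f"{path}: row {rownum}: day={raw_day!r} is not an integer",
                    row=rownum,
                ) from None
            if day < 0:
                raise ManifestParseError(
                    f"{path}: row {rownum}: day must be >= 0, got {day}", row=rownum
                )
            cell_line = (row["cell_line"] or "").strip()
            if not cell_line:
                raise ManifestParseError(
                    f"{path}: row {rownum}: empty cell_line", row=rownum
                )
            records.append(ImageRecord(row["file_path"].strip(), cell_line, day))
    return records


def write_overlay(image: GrayImage, mask, path: str | Path) -> None:
    """Write a PNG with the mask boundary drawn over the grayscale image.

    The boundary is the set of foreground pixels with at least one
    non-foreground 8-neighbour, drawn in a fixed highlight colour. An
    all-false mask produces a plain RGB rendering of the input.
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if mask_arr.shape != image.pixels.shape:
        raise ValidationError(
            f"mask shape {mask_arr.shape} does not match image shape "
            f"{image.pixels.shape}"
        )
    gray8 = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    rgb = np.stack([gray8, gray8, gray8], axis=-1)
    if mask_arr.any():
        eroded = ndimage.binary_erosion(mask_arr, structure=np.ones((3, 3), bool))
        boundary = mask_arr & ~eroded
        rgb[boundary] = OVERLAY_COLOR
    iio.imwrite(Path(path), rgb)
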