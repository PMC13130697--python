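"""Raster I/O for micrographs, annotation masks and overlay renderings.

Images are held internally as floating-point RGB arrays in [0, 1], decoupling
the pipeline from the acquisition bit depth (8-bit PNG or 8/16-bit TIFF on
disk).  Masks are boolean arrays stored as 0/255 PNG.  The coordinate
convention is row-major, origin top-left, half-open ranges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "RgbImage",
    "AnnotationMask",
    "FormatError",
    "GeometryError",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_overlay",
]

MIN_SIDE_PX = 64


class FormatError(ValueError):
    """Raised when a raster file is not a supported 3-channel image."""


class GeometryError(ValueError):
    """Raised when two rasters that must be congruent differ in shape."""


@dataclass
class RgbImage:
    """A bright-field RGB micrograph with intensities in [0, 1].

    Parameters
    ----------
    pixels : (H, W, 3) float array
        Channel order R, G, B; every value finite and within [0, 1].
    pixel_size_um : float
        Physical pixel pitch in micrometres (0.6 at the nominal 20x setup).
        Taken from configuration, never from file metadata.
    image_id : str
        Identifier used for provenance and as the histogram-alignment
        reference key.
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.6
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(
                f"expected an H x W x 3 array, got shape {self.pixels.shape}"
            )
        h, w = self.pixels.shape[:2]
        if h < MIN_SIDE_PX or w < MIN_SIDE_PX:
            raise FormatError(
                f"image {w}x{h} smaller than the supported minimum "
                f"{MIN_SIDE_PX}x{MIN_SIDE_PX}"
            )
        if not np.isfinite(self.pixels).all():
            raise FormatError("image contains non-finite intensities")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise FormatError("image intensities must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class AnnotationMask:
    """A boolean pixel mask congruent with its companion image.

    ``kind`` records provenance: a pathologist's coarse region sweep
    (``rough_annotation``), exact simulated ground truth (``ground_truth``)
    or a pipeline output (``prediction``).
    """

    pixels: np.ndarray
    kind: str = "rough_annotation"

    KINDS = ("rough_annotation", "ground_truth", "prediction")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise GeometryError(f"mask must be 2-D, got shape {self.pixels.shape}")
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    @property
    def is_full(self) -> bool:
        return bool(self.pixels.all())


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(np.float64)
    raise FormatError(f"unsupported sample format {arr.dtype}")


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    if suffix == ".png":
        return np.asarray(Image.open(path))
    raise FormatError(f"unsupported raster format {suffix!r} for {path}")


def read_image(
    path: str | os.PathLike,
    pixel_size_um: float = 0.6,
    image_id: str | None = None,
) -> RgbImage:
    """Read a PNG or TIFF micrograph, rescaling intensities by bit depth.

    Greyscale or alpha-carrying rasters are rejected rather than silently
    coerced; the pixel size comes from configuration, not file tags.
    """
    arr = _read_raster(path)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path}: expected 3 channels, got shape {arr.shape}"
        )
    pixels = np.clip(_to_unit_float(arr), 0.0, 1.0)
    name = image_id if image_id is not None else Path(path).stem
    return RgbImage(pixels=pixels, pixel_size_um=pixel_size_um, image_id=name)


def read_mask(
    path: str | os.PathLike,
    image: RgbImage,
    kind: str = "rough_annotation",
) -> AnnotationMask:
    """Read a 0/255 raster mask and validate its geometry against ``image``."""
    arr = _read_raster(path)
    if arr.ndim == 3:  # tolerate RGB-encoded masks, any positive channel is true
        arr = arr.max(axis=2)
    if arr.shape != image.shape:
        raise GeometryError(
            f"mask shape {arr.shape} does not match image shape {image.shape}"
        )
    return AnnotationMask(pixels=arr > 0, kind=kind)


def write_image(image: RgbImage, path: str | os.PathLike) -> None:
    """Write an image as 8-bit PNG (or TIFF by extension)."""
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def write_mask(mask: AnnotationMask, path: str | os.PathLike) -> None:
    """Write a boolean mask as 0/255 single-channel PNG."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of ``mask`` with at least one 4-neighbour outside it."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)  # out-of-frame counts as outside
    interior = (
        padded[1:-1, 1:-1]
        & padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return m & ~interior


def write_overlay(
    image: RgbImage,
    result_mask: AnnotationMask,
    path: str | os.PathLike,
    colour: tuple[float, float, float] = (0.0, 0.85, 0.1),
) -> None:
    """Render the detected-region outline over the micrograph as PNG.

    The outline is the mask's inner boundary; an empty mask reproduces the
    input image (up to 8-bit encoding).  Deterministic for fixed inputs.
    """
    if result_mask.shape != image.shape:
        raise GeometryError(
            f"mask shape {result_mask.shape} does not match image "
            f"shape {image.shape}"
        )
    rgb = image.pixels.copy()
    edge = mask_boundary(result_mask.pixels)
    rgb[edge] = colour
    write_image(RgbImage(rgb, image.pixel_size_um, image.image_id), path)
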