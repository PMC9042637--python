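"""Grayscale image container and raster I/O.

The toolkit works on single-channel 8-bit images: intensities are integers
in ``[0, G_max]`` with ``G_max = 255``.  All filtering and morphology happen
in this integer space; quality metrics convert to floating point.  Pixels
are indexed ``(row, column)``, 0-based, row 0 at the top.

Supported on-disk formats are the lossless raster formats a scanner export
or a screenshot pipeline typically produces: binary PGM (P5), 8-bit
grayscale PNG, and 8-bit grayscale TIFF.  Multi-channel inputs are folded
to luminance on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = ["GrayImage", "read_image", "write_image"]

#: Pillow format names keyed by the extensions/format flags we accept.
_FORMATS = {
    "pgm": "PPM",
    "png": "PNG",
    "tif": "TIFF",
    "tiff": "TIFF",
}


@dataclass(frozen=True, eq=False)
class GrayImage:
    """A validated 2-D grid of 8-bit intensities.

    Attributes
    ----------
    pixels : numpy.ndarray
        Read-only ``uint8`` array of shape ``(height, width)``.
    g_max : int
        Maximum representable intensity (255 for 8-bit data).
    """

    pixels: np.ndarray
    g_max: int = 255

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"GrayImage requires a 2-D array, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"GrayImage requires height >= 1 and width >= 1, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"GrayImage intensities must be integers, got dtype {arr.dtype}")
        if self.g_max < 1:
            raise ValueError("g_max must be >= 1")
        lo, hi = int(arr.min()), int(arr.max())
        if lo < 0 or hi > self.g_max:
            raise ValueError(f"intensities out of range [0, {self.g_max}]: min={lo}, max={hi}")
        arr = np.ascontiguousarray(arr.astype(np.uint8, copy=True))
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def g(self) -> int:
        """Total pixel count ``height * width``."""
        return self.pixels.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, g_max: int = 255) -> "GrayImage":
        return cls(np.asarray(arr), g_max=g_max)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.g_max == other.g_max and np.array_equal(self.pixels, other.pixels)


def _to_gray_array(im: Image.Image) -> np.ndarray:
    """Collapse a Pillow image to an 8-bit luminance array."""
    if im.mode == "L":
        return np.asarray(im, dtype=np.uint8)
    if im.mode in ("I", "I;16", "I;16B", "I;16L"):
        # 16/32-bit grayscale: rescale full range onto [0, 255].
        arr = np.asarray(im, dtype=np.float64)
        scale = 65535.0 if "16" in im.mode else max(float(arr.max()), 1.0)
        return np.rint(arr / scale * 255.0).clip(0, 255).astype(np.uint8)
    # RGB(A), palette, 1-bit ... : Pillow's ITU-R 601 luma conversion.
    return np.asarray(im.convert("L"), dtype=np.uint8)


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a PGM/PNG/TIFF file as an 8-bit grayscale image.

    Color inputs are converted to luminance; higher bit depths are rescaled
    onto ``[0, 255]``.  Raises ``IOError`` naming the path when the file
    cannot be read, and ``ValueError`` for zero-sized images.
    """
    try:
        with Image.open(path) as im:
            arr = _to_gray_array(im)
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image in {os.fspath(path)!r}")
    return GrayImage(arr)


def write_image(img: GrayImage, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``img`` losslessly; ``read_image`` round-trips bit-exactly.

    The format is sniffed from the extension unless ``format`` (one of
    ``pgm``/``png``/``tif``/``tiff``) overrides it.
    """
    if format is None:
        ext = os.path.splitext(os.fspath(path))[1].lstrip(".").lower()
    else:
        ext = format.lower()
    if ext not in _FORMATS:
        raise ValueError(
            f"unsupported image format {ext!r}; expected one of {sorted(_FORMATS)}"
        )
    pil = Image.fromarray(img.pixels, mode="L")
    try:
        pil.save(path, format=_FORMATS[ext])
    except (FileNotFoundError, OSError) as exc:
        raise IOError(f"cannot write image file {os.fspath(path)!r}: {exc}") from exc
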