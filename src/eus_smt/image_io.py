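"""Image and mask I/O for the endosonogram pipelines.

Everything downstream works on two in-memory representations:

* a *gray image* — a 2-D ``uint8`` array of brightness values in [0, 255],
  row-major, origin at the top-left, indexed ``(row, col)``;
* a *binary mask* — a 2-D ``bool`` array of the same shape as the image it
  was derived from.

Clinical endosonograms are stored as Windows bitmaps; BMP and PNG are read,
masks are written as single-channel PNG with foreground = 255.  Color inputs
are collapsed to luminance with the Rec. 601 weights (0.299, 0.587, 0.114),
rounded half-up — the clinical frames are grayscale already, so the exact
convention only matters for incidental RGB screenshots.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

#: Smallest accepted image side; the morphological and frequency-domain
#: stages are meaningless below a few structuring-element widths.
MIN_SIZE = 8

_REC601 = np.array([0.299, 0.587, 0.114], dtype=np.float64)


class ImageDecodeError(ValueError):
    """Raised when a file cannot be decoded as a BMP/PNG image."""


class ImageSizeError(ValueError):
    """Raised when an image is smaller than the pipeline minimum."""


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and return ``arr`` as a uint8 gray image.

    Accepts any integer or float array with values already in [0, 255];
    raises ``ValueError`` on shape, range or size violations.
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {a.shape}")
    if a.shape[0] < MIN_SIZE or a.shape[1] < MIN_SIZE:
        raise ImageSizeError(
            f"image is {a.shape[1]}x{a.shape[0]} px; "
            f"the pipeline requires at least {MIN_SIZE}x{MIN_SIZE}"
        )
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)):
            raise ValueError("gray image values must lie in [0, 255]")
        a = np.floor(np.asarray(a, dtype=np.float64) + 0.5).astype(np.uint8)
    return a.copy()


def _luminance(rgb: np.ndarray) -> np.ndarray:
    y = rgb[..., :3].astype(np.float64) @ _REC601
    return np.floor(y + 0.5).astype(np.uint8)  # round half-up


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a BMP or PNG file as a gray image (uint8, [0, 255])."""
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise ImageDecodeError(f"cannot decode image file {os.fspath(path)!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = _luminance(arr)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    return as_gray_image(arr)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a gray image as an 8-bit single-channel PNG (or BMP by suffix)."""
    Image.fromarray(as_gray_image(img), mode="L").save(path)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a single-channel PNG, foreground = 255.

    The write/read round trip is exact: ``read_mask(write_mask(m)) == m``.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    Image.fromarray(m.astype(np.uint8) * 255, mode="L").save(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 0/255 PNG mask back as a boolean array."""
    return read_image(path) >= 128
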