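"""Loading and geometric preparation of gel photographs.

A gel photograph shows bright sample lanes on a dark background (ethidium
bromide under UV). The image is held as a 2-D float grid in [0, 255] with
row 0 at the top, where the wells are assumed to sit: migration distance of
a DNA fragment is then simply its row index.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import BoundsError, FormatError

SUPPORTED_EXTENSIONS = {".gif", ".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

# ITU-R BT.601 luminance weights; any convex weighting is acceptable for
# gel imagery since lanes are near-gray, and R=G=B pixels are fixed points.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GelImage:
    """A grayscale gel image.

    Intensities are floats in [0, 255]; row index increases downward
    (away from the wells).
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise FormatError("GelImage requires a non-empty 2-D intensity grid")
        if not np.all(np.isfinite(px)):
            raise FormatError("GelImage intensities must be finite")
        if px.min() < 0 or px.max() > 255:
            raise FormatError("GelImage intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_grayscale(rgb: np.ndarray) -> GelImage:
    """Convert a height x width x 3 RGB array to a grayscale :class:`GelImage`.

    Uses the standard luminance weights (0.299, 0.587, 0.114); the weights
    sum to 1, so achromatic pixels are unchanged.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected a 3-channel image, got shape {arr.shape}")
    return GelImage(arr @ _LUMA)


def load_image(path: str | os.PathLike) -> GelImage:
    """Load a gel photograph (gif/png/jpg/tiff/bmp) as grayscale.

    Paletted and RGBA inputs are expanded to RGB first; RGB is reduced with
    :func:`to_grayscale`; single-channel images pass through unchanged.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported image format '{ext}'; "
                          f"accepted: gif, png, jpg, tiff, bmp")
    try:
        with Image.open(path) as im:
            if im.mode in ("P", "RGBA", "LA", "PA", "CMYK"):
                im = im.convert("RGB")
            if im.mode == "RGB":
                return to_grayscale(np.asarray(im))
            if im.mode in ("L", "I", "I;16", "F"):
                arr = np.asarray(im, dtype=float)
                if arr.max(initial=0.0) > 255:  # 16-bit grays rescale to 8-bit range
                    arr = arr * (255.0 / arr.max())
                return GelImage(arr)
            return to_grayscale(np.asarray(im.convert("RGB")))
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot read image file '{path}': {exc}") from exc


def save_image(img: GelImage, path: str | os.PathLike) -> None:
    """Write the image as 8-bit grayscale; intensities are rounded and clamped."""
    data = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(os.fspath(path))


def crop(img: GelImage, top: int, bottom: int, left: int, right: int) -> GelImage:
    """Crop to rows [top, bottom) and columns [left, right) (half-open)."""
    if not (0 <= top < bottom <= img.height and 0 <= left < right <= img.width):
        raise BoundsError(
            f"crop rectangle rows [{top},{bottom}) cols [{left},{right}) "
            f"invalid for a {img.height}x{img.width} image")
    return GelImage(img.pixels[top:bottom, left:right].copy())


def rotate_quarter(img: GelImage, turns: int) -> GelImage:
    """Rotate by ``turns`` 90-degree counter-clockwise quarter turns.

    Negative values rotate clockwise; four turns is the identity. Quarter
    turns are exact (no resampling), which is all that is needed to place
    the wells at the top.
    """
    return GelImage(np.rot90(img.pixels, k=turns % 4).copy())
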