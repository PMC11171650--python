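"""Image ingestion and mask extraction.

The preprocessing chain mirrors common dermoscopy practice: the photograph is
reduced to an 8-bit grayscale raster at a fixed working resolution (512 px by
default), thresholded into lesion/background, and cleaned so that a single
connected lesion component remains.  Lesions are assumed darker than the
surrounding skin; pass ``invert=True`` for light-on-dark inputs.

Coordinates are row-major with the origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import DegenerateImageError, EmptyMaskError, IngestError

DEFAULT_SIDE = 512


@dataclass
class GrayImage:
    """An 8-bit grayscale raster plus an opaque source identifier."""

    pixels: np.ndarray  # uint8, shape (H, W)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A foreground/background raster; foreground is the lesion.

    ``meta`` carries run metadata recorded by the operations that produced
    the mask (threshold used, binarization method, ...).
    """

    pixels: np.ndarray  # bool, shape (H, W)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D pixel array")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def load_image(path: str | Path, target_side: int = DEFAULT_SIDE) -> GrayImage:
    """Read a raster image (PNG/JPEG/BMP), convert to 8-bit grayscale and
    resize to ``target_side`` x ``target_side``.

    Color inputs are converted by luminance weighting; non-square inputs are
    resized without aspect preservation (bilinear interpolation).  Re-ingesting
    a conforming output reproduces it bit-exactly.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            gray = im.convert("L")
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise IngestError(f"cannot read image {path}: {exc}") from exc
    if gray.size != (target_side, target_side):
        gray = gray.resize((target_side, target_side), Image.BILINEAR)
    return GrayImage(np.asarray(gray, dtype=np.uint8), source_id=path.stem)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 1-bit PNG for audit."""
    Image.fromarray(mask.pixels).convert("1").save(Path(path))


def binarize(
    img: GrayImage,
    method: str = "otsu",
    fixed_threshold: int | None = None,
    invert: bool = False,
) -> BinaryMask:
    """Threshold a grayscale image into a lesion mask.

    With ``method="otsu"`` the threshold maximizes Otsu's between-class
    variance; with ``method="fixed"`` the caller supplies ``fixed_threshold``
    in [0, 255].  The lesion is taken as the *darker* class (foreground =
    intensities <= threshold) unless ``invert`` is set.  The threshold used is
    recorded in the mask's ``meta``.
    """
    pixels = img.pixels
    if pixels.min() == pixels.max():
        raise DegenerateImageError(
            f"{img.source_id or 'image'}: constant intensity "
            f"{int(pixels.flat[0])}, no separable classes"
        )
    if method == "otsu":
        thr = int(threshold_otsu(pixels))
    elif method == "fixed":
        if fixed_threshold is None or not 0 <= fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be given in [0, 255]")
        thr = int(fixed_threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    fg = pixels > thr if invert else pixels <= thr
    return BinaryMask(
        fg, meta={"threshold": thr, "method": method, "invert": invert}
    )


def remove_background(
    mask: BinaryMask, min_component_px: int = 1, fill_holes: bool = True
) -> BinaryMask:
    """Retain only the largest 8-connected foreground component.

    Ties on component area break toward the component whose first foreground
    pixel comes earlier in row-major scan order.  Interior holes are filled by
    default so that area-style box counting is stable.  Isolated specks
    (hair/bubble artifacts) are removed as a side effect.
    """
    if mask.foreground_count == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    labels = cc_label(mask.pixels, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    best = int(np.argmax(sizes))  # first max -> earliest row-major component
    if sizes[best] < min_component_px:
        raise EmptyMaskError(
            f"largest component ({sizes[best]} px) below min_component_px"
        )
    kept = labels == best
    if fill_holes:
        kept = ndimage.binary_fill_holes(kept)
    meta = dict(mask.meta)
    meta.update(
        {"largest_component_px": int(sizes[best]), "holes_filled": fill_holes}
    )
    return BinaryMask(kept, meta=meta)
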