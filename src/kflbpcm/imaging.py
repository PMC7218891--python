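"""Vegetation segmentation and morphological operations.

This module holds everything that touches raw pixels before texture
features are computed: the ExG−ExR color-index segmentation that separates
green plant material from soil, grayscale conversion, opening/closing
smoothing, and the contour-band masks that carry the leaf-margin shape
signal.

Conventions
-----------
* Rasters are numpy arrays, row-major, 0-based ``(row, col)`` indexing.
* RGB images are ``H×W×3`` uint8; masks are ``H×W`` bool.
* All morphology pads by edge replication so that image borders do not
  produce spurious contour bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from ._exceptions import ConfigError, InvalidInputError

__all__ = [
    "PlantImage",
    "BinaryMask",
    "MorphologyConfig",
    "segment_vegetation",
    "to_grayscale",
    "open_close",
    "open_close_rgb",
    "contour_mask",
    "read_image",
    "write_mask",
    "read_mask",
]

#: BT.601 luminance weights used for every grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

MIN_IMAGE_SIDE = 16


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PlantImage:
    """A labeled RGB plant image with growth-stage and rotation metadata.

    Parameters
    ----------
    pixels : ndarray
        ``H×W×3`` uint8 raster, ``H, W >= 16``.
    label : str
        Class identifier (e.g. ``"canola_like"`` or ``"background"``).
    stage : int
        Growth-stage tag, ``>= 1``.  Larger stages mean larger plants.
    rotation_deg : float
        In-plane rotation in ``[0, 360)``.
    """

    pixels: np.ndarray
    label: str
    stage: int = 1
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidInputError(
                f"PlantImage requires an H×W×3 raster, got shape {px.shape}"
            )
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise InvalidInputError(
                f"image sides must be >= {MIN_IMAGE_SIDE}, got {px.shape[:2]}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InvalidInputError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.stage < 1:
            raise InvalidInputError(f"stage must be >= 1, got {self.stage}")
        self.rotation_deg = float(self.rotation_deg) % 360.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """A per-pixel indicator aligned with a source image.

    ``kind`` records provenance: ``"vegetation"`` for ExG−ExR output,
    ``"contour_band"`` for a boundary band derived from a vegetation mask.
    """

    values: np.ndarray
    kind: str = "vegetation"

    _KINDS = ("vegetation", "contour_band")

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got shape {v.shape}")
        self.values = v.astype(bool)
        if self.kind not in self._KINDS:
            raise InvalidInputError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class MorphologyConfig:
    """Structuring-element geometry for smoothing and band extraction.

    ``se_size`` is the side of the square element used by :func:`open_close`
    (default 5).  ``thickness`` is the contour-band width in pixels
    (default 2).  ``band_style`` selects whether the band sits just inside
    the vegetation boundary (``"inner"``, the default) or just outside
    (``"outer"``).
    """

    se_size: int = 5
    thickness: int = 2
    band_style: str = "inner"

    def __post_init__(self) -> None:
        if self.se_size < 3 or self.se_size % 2 == 0:
            raise ConfigError(f"se_size must be odd and >= 3, got {self.se_size}")
        if self.thickness < 1:
            raise ConfigError(f"thickness must be >= 1, got {self.thickness}")
        if self.band_style not in ("inner", "outer"):
            raise ConfigError(f"band_style must be 'inner' or 'outer', got {self.band_style!r}")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_vegetation(image: PlantImage | np.ndarray) -> BinaryMask:
    """Segment green vegetation with the excess-green minus excess-red index.

    Chromatic coordinates ``r = R/(R+G+B)`` (and likewise g, b) make the
    index invariant to uniform brightness changes.  A pixel is vegetation
    when ``ExG − ExR > 0`` with ``ExG = 2g − r − b`` and ``ExR = 1.4r − g``.
    Pixels with ``R+G+B = 0`` (pure black) are background.

    Returns a :class:`BinaryMask` of kind ``"vegetation"``.
    """
    px = image.pixels if isinstance(image, PlantImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InvalidInputError(f"expected an H×W×3 raster, got shape {px.shape}")
    rgb = px.astype(np.float64)
    total = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, rgb[..., 0] / total, 0.0)
        g = np.where(total > 0, rgb[..., 1] / total, 0.0)
        b = np.where(total > 0, rgb[..., 2] / total, 0.0)
    exg = 2.0 * g - r - b
    exr = 1.4 * r - g
    veg = (exg - exr > 0.0) & (total > 0)
    return BinaryMask(veg, kind="vegetation")


def to_grayscale(image: PlantImage | np.ndarray) -> np.ndarray:
    """BT.601 luminance (0.299 R + 0.587 G + 0.114 B), rounded to uint8."""
    px = image.pixels if isinstance(image, PlantImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InvalidInputError(f"expected an H×W×3 raster, got shape {px.shape}")
    return np.rint(px.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _check_cfg(cfg: MorphologyConfig) -> MorphologyConfig:
    if not isinstance(cfg, MorphologyConfig):
        raise ConfigError(f"expected MorphologyConfig, got {type(cfg).__name__}")
    return cfg


def open_close(raster: np.ndarray, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Morphological opening followed by closing with a square element.

    Removes bright speckle smaller than the element (opening) and fills
    dark pits (closing), smoothing leaf texture before contour extraction.
    The border is padded by replication, so the operation is exact in the
    interior and free of edge artifacts.
    """
    cfg = _check_cfg(cfg) if cfg is not None else MorphologyConfig()
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise InvalidInputError(f"open_close expects a 2-D raster, got shape {arr.shape}")
    size = (cfg.se_size, cfg.se_size)
    opened = ndimage.grey_opening(arr, size=size, mode="nearest")
    return ndimage.grey_closing(opened, size=size, mode="nearest")


def open_close_rgb(pixels: np.ndarray, cfg: MorphologyConfig | None = None) -> np.ndarray:
    """Channelwise :func:`open_close` of an RGB raster."""
    px = np.asarray(pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise InvalidInputError(f"expected an H×W×3 raster, got shape {px.shape}")
    return np.stack([open_close(px[..., c], cfg) for c in range(3)], axis=2)


def _erode(mask: np.ndarray, iterations: int) -> np.ndarray:
    # edge-replicated erosion with the 3×3 square element
    padded = np.pad(mask, iterations, mode="edge")
    eroded = ndimage.binary_erosion(
        padded, structure=np.ones((3, 3), bool), iterations=iterations
    )
    return eroded[iterations:-iterations, iterations:-iterations]


def _dilate(mask: np.ndarray, iterations: int) -> np.ndarray:
    padded = np.pad(mask, iterations, mode="edge")
    dilated = ndimage.binary_dilation(
        padded, structure=np.ones((3, 3), bool), iterations=iterations
    )
    return dilated[iterations:-iterations, iterations:-iterations]


def contour_mask(veg: BinaryMask, cfg: MorphologyConfig | None = None) -> BinaryMask:
    """Extract a boundary band of width ``cfg.thickness`` from a vegetation mask.

    The default inner band is ``veg AND NOT erode^t(veg)`` where the erosion
    uses a 3×3 square element applied ``t`` times; along a straight edge the
    band is exactly ``t`` pixels wide, and for a solid ``a×b`` rectangle with
    ``2t < min(a, b)`` the band has ``a·b − (a−2t)(b−2t)`` pixels.  The inner
    band is always a subset of the vegetation mask.  ``band_style="outer"``
    instead returns ``dilate^t(veg) AND NOT veg``.
    """
    cfg = _check_cfg(cfg) if cfg is not None else MorphologyConfig()
    if veg.kind != "vegetation":
        raise InvalidInputError(f"contour_mask requires a vegetation mask, got kind {veg.kind!r}")
    t = cfg.thickness
    if cfg.band_style == "inner":
        band = veg.values & ~_erode(veg.values, t)
    else:
        band = _dilate(veg.values, t) & ~veg.values
    return BinaryMask(band, kind="contour_band")


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path, label: str = "", stage: int = 1,
               rotation_deg: float = 0.0) -> PlantImage:
    """Load a PNG/JPEG file as a :class:`PlantImage`."""
    with Image.open(path) as im:
        px = np.asarray(im.convert("RGB"))
    return PlantImage(px, label=label, stage=stage, rotation_deg=rotation_deg)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a single-channel PNG with values 0/255."""
    Image.fromarray(np.where(mask.values, 255, 0).astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path, kind: str = "vegetation") -> BinaryMask:
    """Read a 0/255 single-channel PNG back into a :class:`BinaryMask`."""
    with Image.open(path) as im:
        values = np.asarray(im.convert("L")) > 127
    return BinaryMask(values, kind=kind)
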