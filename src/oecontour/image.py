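"""Image containers, I/O and grid tiling.

All downstream stages operate on a single-channel raster with intensities
on a fixed [0, 255] float scale, independent of the bit depth of the file
it was read from.  Masks are strictly binary ({0, 1}) arrays paired with an
image of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Image2D",
    "BinaryMask",
    "GridTiling",
    "read_image",
    "read_mask",
    "write_mask",
    "tile_grid",
]

#: minimum admissible image side, in pixels
MIN_SIDE = 16

# ITU-R BT.601 luma weights used to collapse RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Image2D:
    """A 2-D grayscale image with float intensities in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 255.0:
            raise ValueError("intensities must lie within [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} mask with the same shape as its paired image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


@dataclass(frozen=True)
class GridTiling:
    """Row-major square tiling of an image, edge-padded to full coverage.

    ``tiles`` holds ``(row_offset, col_offset, tile_pixels)`` triples whose
    offsets refer to the padded frame; ``image_shape`` records the original
    (un-padded) shape so the tiling can be reassembled exactly.
    """

    tile_side: int
    tiles: tuple[tuple[int, int, np.ndarray], ...]
    covers: bool
    image_shape: tuple[int, int]
    padded_shape: tuple[int, int]

    def __iter__(self) -> Iterator[tuple[int, int, np.ndarray]]:
        return iter(self.tiles)

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            self.padded_shape[0] // self.tile_side,
            self.padded_shape[1] // self.tile_side,
        )

    def reassemble(self) -> np.ndarray:
        """Stitch the tiles back together and crop the padding."""
        out = np.empty(self.padded_shape, dtype=np.float64)
        s = self.tile_side
        for r0, c0, tile in self.tiles:
            out[r0 : r0 + s, c0 : c0 + s] = tile
        h, w = self.image_shape
        return out[:h, :w]


def _rescale_to_255(raw: np.ndarray) -> np.ndarray:
    """Linearly map the dtype's full range to [0, 255] floats."""
    if raw.dtype == np.uint8:
        return raw.astype(np.float64)
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) * (255.0 / 65535.0)
    if raw.dtype == np.int16:  # some TIFF writers store signed data
        shifted = raw.astype(np.float64) - np.iinfo(np.int16).min
        return shifted * (255.0 / (2**16 - 1))
    if np.issubdtype(raw.dtype, np.floating):
        # Assume [0, 1] floats unless the data plainly exceeds it.
        arr = raw.astype(np.float64)
        if arr.size and arr.max() > 1.0 + 1e-9:
            return np.clip(arr, 0.0, 255.0)
        return arr * 255.0
    raise IOError(f"unsupported pixel dtype {raw.dtype}")


def read_image(path: str | Path) -> Image2D:
    """Read a PNG/TIFF/PGM image as a [0, 255]-scaled grayscale raster.

    RGB(A) inputs are collapsed to BT.601 luma after per-channel rescaling;
    8-bit values pass through unchanged and 16-bit full scale maps to 255.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError(f"zero-area image: {path}")
    if raw.ndim == 3:
        px = _rescale_to_255(raw[..., :3])
        px = px @ _LUMA
    elif raw.ndim == 2:
        px = _rescale_to_255(raw)
    else:
        raise ValueError(f"unsupported image dimensionality {raw.ndim}")
    return Image2D(np.clip(px, 0.0, 255.0))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    path = Path(path)
    try:
        iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    except Exception as exc:
        raise IOError(f"cannot write mask {path}: {exc}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask PNG; values above half scale count as foreground."""
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return BinaryMask((raw > raw.dtype.type(127)).astype(np.uint8))


def tile_grid(img: Image2D, tile_side: int) -> GridTiling:
    """Split an image into non-overlapping ``tile_side`` squares.

    Dimensions that are not multiples of ``tile_side`` are edge-padded by
    replication up to the next multiple, so the grid always covers the
    image; replication keeps the padded border's local statistics close to
    the true border instead of injecting artificial step edges.
    """
    if tile_side % 2 != 0:
        raise ValueError(f"tile_side must be even, got {tile_side}")
    if tile_side < 8:
        raise ValueError(f"tile_side must be >= 8, got {tile_side}")
    if tile_side > min(img.height, img.width):
        raise ValueError(
            f"tile_side {tile_side} exceeds image extent {img.shape}"
        )
    h, w = img.shape
    ph = -(-h // tile_side) * tile_side
    pw = -(-w // tile_side) * tile_side
    padded = np.pad(img.pixels, ((0, ph - h), (0, pw - w)), mode="edge")
    tiles = []
    for r0 in range(0, ph, tile_side):
        for c0 in range(0, pw, tile_side):
            tiles.append(
                (r0, c0, padded[r0 : r0 + tile_side, c0 : c0 + tile_side].copy())
            )
    return GridTiling(
        tile_side=tile_side,
        tiles=tuple(tiles),
        covers=True,
        image_shape=(h, w),
        padded_shape=(ph, pw),
    )
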