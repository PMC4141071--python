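"""Orientation entropy of directional subbands and the parameter maps.

The orientation entropy (OE) of a subband is the Shannon entropy of the
probability function derived from its coefficient magnitudes.  Tiles whose
subbands carry coherent, single-orientation structure concentrate their
coefficient mass and score low; tiles filled with multi-oriented clutter
spread their mass across positions and directions and score high.  The
tile-level OE grid, rescaled to (0, 1], becomes the data-fidelity weight
map w_df, and the regularization weight map is its element-wise reciprocal
w_reg = 1 / w_df.  Both maps are computed once, before contour evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .dfb import DirectionalSubbands, decompose_image
from .image import Image2D, tile_grid

__all__ = [
    "EntropyGrid",
    "ParameterMaps",
    "subband_probability",
    "orientation_entropy",
    "tile_entropy",
    "default_grid_side",
    "compute_entropy_grid",
    "build_parameter_maps",
]

Normalization = Literal["denoised", "band"]

#: default estimator for the tile-level OE grid (see compute_entropy_grid)
DEFAULT_NORMALIZATION: Normalization = "denoised"

#: noise-floor height in multiples of the global median |coefficient|
DENOISE_FACTOR = 3.0
#: local saliency floor as a fraction of the tile's peak |coefficient|
LOCAL_FRACTION = 0.25


def subband_probability(band: np.ndarray) -> np.ndarray:
    """L1-normalized coefficient magnitudes of one subband.

    p(m, n) = |c(m, n)| / sum |c|; a band with zero total magnitude maps to
    the uniform distribution (no position is privileged).
    """
    band = np.asarray(band, dtype=np.float64)
    if not np.all(np.isfinite(band)):
        raise ValueError("non-finite subband coefficients")
    mag = np.abs(band)
    total = mag.sum()
    if total == 0.0:
        return np.full(band.shape, 1.0 / band.size)
    return mag / total


def _entropy(p: np.ndarray, base: float) -> float:
    """Shannon entropy with the 0 log 0 := 0 convention."""
    nz = p[p > 0.0]
    return float(-np.sum(nz * np.log(nz)) / np.log(base))


def orientation_entropy(band: np.ndarray, base: float = 2.0) -> float:
    """Orientation entropy of one subband (bits by default).

    OE = -sum p log p over ``subband_probability(band)``; bounded by
    log(M * N) for an M x N band, attained by the uniform distribution.
    """
    return _entropy(subband_probability(band), base)


def tile_entropy(subs: DirectionalSubbands, base: float = 2.0) -> float:
    """Sum of the orientation entropies of the four directional bands.

    Invariant to band ordering; for a tile of side s the value lies in
    [0, 4 * log(s/2 * s/2)].
    """
    return float(sum(orientation_entropy(b, base) for b in subs.bands))


def default_grid_side(height: int, width: int, divisor: int = 8) -> int:
    """Automatic grid-tile side for an image of the given extent.

    The side is the smaller image dimension divided by ``divisor`` (a
    power of two, default 8), floored to an even integer and clamped below
    at 8 so a tile still spans a meaningful edge region: 256 -> 32 and
    320 -> 40.
    """
    if height < 16 or width < 16:
        raise ValueError(
            f"image must be at least 16x16, got ({height}, {width})"
        )
    if divisor < 1:
        raise ValueError("divisor must be positive")
    side = min(height, width) // divisor
    side -= side % 2
    return max(side, 8)


@dataclass(frozen=True)
class EntropyGrid:
    """Per-tile orientation entropies over the image grid."""

    tile_side: int
    oe: np.ndarray  # (grid_h, grid_w) tile-level OE
    per_band_oe: np.ndarray  # (grid_h, grid_w, 4)

    def __post_init__(self) -> None:
        if self.per_band_oe.shape != self.oe.shape + (4,):
            raise ValueError("per_band_oe must hold 4 values per tile")


@dataclass(frozen=True)
class ParameterMaps:
    """Pixel-wise regularization and data-fidelity weight maps.

    ``w_df`` lies in [eps, 1] and ``w_reg`` is its element-wise reciprocal,
    so w_reg * w_df = 1 everywhere; both are piecewise constant on tiles
    (unless a smoothing sigma was requested).
    """

    w_reg: np.ndarray
    w_df: np.ndarray
    tile_side: int
    entropy_grid: EntropyGrid | None = None

    def __post_init__(self) -> None:
        if self.w_reg.shape != self.w_df.shape:
            raise ValueError("map shapes differ")
        if np.any(self.w_df <= 0.0) or np.any(self.w_reg <= 0.0):
            raise ValueError("weight maps must be strictly positive")


def compute_entropy_grid(
    img: Image2D,
    tile_side: int,
    base: float = 2.0,
    normalization: Normalization = DEFAULT_NORMALIZATION,
) -> EntropyGrid:
    """Orientation entropy of every grid tile of an image.

    Two estimators of the per-band probability function are available:

    - ``"denoised"`` (default): coefficient magnitudes are soft-thresholded
      before L1 normalization at the larger of ``DENOISE_FACTOR`` times
      the global median |coefficient| (the image's noise floor) and
      ``LOCAL_FRACTION`` times the tile's peak |coefficient| (local
      saliency — filter sidelobes of one strong edge are not counted as
      spread); a band left with zero mass scores zero entropy.  Both
      floors scale with the image, so OE stays invariant under positive
      intensity scaling.  Featureless tiles then score near zero, a
      coherent edge scores through its one concentrated band, and
      multi-oriented clutter — spread over positions and directions —
      scores highest.
    - ``"band"``: each band L1-normalized on its own with no thresholding,
      the plain per-subband OE.  Scale-invariant per tile, which makes a
      tile of faint pure noise score near-maximal (noise is the most
      spread-out signal there is); kept for diagnostics.

    Either way the value is summed over the four directions.
    """
    subbands = decompose_image(img, tile_side)
    tiling = tile_grid(img, tile_side)
    gh, gw = tiling.grid_shape
    per_band = np.zeros((gh, gw, 4))
    noise_floor = 0.0
    if normalization == "denoised":
        all_mags = np.concatenate(
            [np.abs(b).ravel() for subs in subbands.values() for b in subs.bands]
        )
        noise_floor = DENOISE_FACTOR * float(np.median(all_mags))
    for (r0, c0), subs in subbands.items():
        gi, gj = r0 // tile_side, c0 // tile_side
        if normalization == "denoised":
            peak = max(float(np.abs(b).max()) for b in subs.bands)
            threshold = max(noise_floor, LOCAL_FRACTION * peak)
        for k, band in enumerate(subs.bands):
            if normalization == "band":
                per_band[gi, gj, k] = orientation_entropy(band, base)
            else:
                mag = np.maximum(np.abs(band) - threshold, 0.0)
                total = mag.sum()
                if total > 0.0:
                    per_band[gi, gj, k] = _entropy(mag / total, base)
    return EntropyGrid(
        tile_side=tile_side, oe=per_band.sum(axis=2), per_band_oe=per_band
    )


def build_parameter_maps(
    img: Image2D,
    tile_side: int,
    eps: float = 0.01,
    base: float = 2.0,
    normalization: Normalization = DEFAULT_NORMALIZATION,
    smooth_sigma: float = 0.0,
) -> ParameterMaps:
    """Build the reciprocal weight-map pair from the tile OE grid.

    The tile-level OE grid is rescaled linearly so its maximum maps to 1
    and its minimum to ``eps`` (all tiles equal -> all ones), each tile's
    value is broadcast to its pixels to form w_df, and w_reg = 1 / w_df.
    ``eps`` bounds the dynamic range of the reciprocal pair at eps : 1;
    ranges much wider than ~100 : 1 make the curvature term stiffer than
    one evolution step can resolve.
    High-entropy (cluttered) tiles therefore amplify the data-fidelity
    force while low-entropy (coherently structured) tiles amplify
    regularization — the trade-off the contour needs, obtained from image
    content alone.  The linear rescale makes the result independent of the
    entropy log base and of any positive intensity scaling.

    ``smooth_sigma`` > 0 optionally blurs the piecewise-constant w_df with
    a Gaussian (in pixels) before the reciprocal is taken; off by default.
    """
    if not 0.0 < eps <= 1.0:
        raise ValueError(f"eps must lie in (0, 1], got {eps}")
    grid = compute_entropy_grid(img, tile_side, base, normalization)
    oe = grid.oe
    lo, hi = float(oe.min()), float(oe.max())
    if hi - lo <= 0.0:
        scaled = np.ones_like(oe)
    else:
        scaled = eps + (1.0 - eps) * (oe - lo) / (hi - lo)
    # broadcast each tile's value to its pixels, crop padding to image shape
    w_df = np.kron(scaled, np.ones((tile_side, tile_side)))
    w_df = w_df[: img.height, : img.width]
    if smooth_sigma > 0.0:
        w_df = np.clip(gaussian_filter(w_df, smooth_sigma), eps, 1.0)
    w_reg = 1.0 / w_df
    return ParameterMaps(
        w_reg=w_reg, w_df=w_df, tile_side=tile_side, entropy_grid=grid
    )
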