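"""Segmentation evaluation: Tanimoto overlap and Hausdorff distance.

The Tanimoto coefficient TC(A, B) = N(A and B) / N(A or B) measures region
overlap in [0, 1]; the Hausdorff distance is the larger of the two
directed maximal nearest-point distances between the 8-connected boundary
contours of the two masks, optionally scaled from pixels to physical
units.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial.distance import directed_hausdorff

from .image import BinaryMask

__all__ = [
    "tanimoto",
    "hausdorff_directed",
    "hausdorff",
    "mask_boundary",
]


def tanimoto(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection-over-union of two masks; two empty masks give 1."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    pa = a.pixels.astype(bool)
    pb = b.pixels.astype(bool)
    union = np.count_nonzero(pa | pb)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(pa & pb) / union)


def hausdorff_directed(a: np.ndarray, b: np.ndarray) -> float:
    """Directed Hausdorff distance h(A, B) = max_a min_b ||a - b||.

    Point sets are (n, 2) arrays of (row, col) coordinates.  Matches the
    brute-force definition exactly (the early-break algorithm underneath
    is exact, only faster).
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    return float(directed_hausdorff(a, b)[0])


def mask_boundary(mask: BinaryMask) -> np.ndarray:
    """8-connected boundary pixels of a mask as an (n, 2) coordinate array.

    A foreground pixel is on the boundary if any of its 4-neighbors (or
    the image edge) is background; the resulting pixel chain is
    8-connected.
    """
    m = mask.pixels.astype(bool)
    interior = binary_erosion(
        m, structure=generate_binary_structure(2, 1), border_value=0
    )
    return np.argwhere(m & ~interior)


def hausdorff(a: BinaryMask, b: BinaryMask, spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between two mask boundaries.

    spacing converts pixel units to physical units (e.g. mm/pixel);
    identical masks give 0.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    pa = mask_boundary(a)
    pb = mask_boundary(b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("hausdorff distance requires non-empty masks")
    return spacing * max(hausdorff_directed(pa, pb), hausdorff_directed(pb, pa))
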