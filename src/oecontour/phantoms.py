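"""Synthetic phantoms: a coherent-boundary target in oriented clutter.

Each phantom realizes the statistical dichotomy the segmentation method
relies on: the target's boundary is a smooth, anti-aliased curve (a
structured edge region, locally one orientation), while the background
carries short strokes at random orientations (unstructured edge regions)
plus additive Gaussian noise.  Pure noise alone would not exercise the
directional filter bank, hence the strokes.  Every phantom comes with its
ground-truth mask, so the whole pipeline is testable without external
data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .image import BinaryMask, Image2D

__all__ = ["PhantomSpec", "make_phantom", "phantom_suite"]

_SHAPES = ("disk", "ellipse", "blob")
#: side of the lattice used to place background clutter, in pixels
_CLUTTER_TILE = 16


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom; identical specs render identical pixels."""

    size: tuple[int, int] = (256, 256)
    target_shape: str = "disk"
    target_intensity: float = 150.0
    background_intensity: float = 100.0
    clutter_density: float = 0.5
    clutter_contrast: float = 30.0
    noise_sigma: float = 5.0
    seed: int = 0
    target_radius_frac: float = 0.23  # base radius as fraction of min side

    def __post_init__(self) -> None:
        if self.target_shape not in _SHAPES:
            raise ValueError(f"unknown target shape {self.target_shape!r}")
        if abs(self.target_intensity - self.background_intensity) < 10:
            raise ValueError(
                "target and background intensities must differ by >= 10"
            )
        if not 0.0 <= self.clutter_density <= 1.0:
            raise ValueError("clutter_density must lie in [0, 1]")
        if self.noise_sigma < 0 or self.clutter_contrast < 0:
            raise ValueError("noise_sigma and clutter_contrast must be >= 0")
        if min(self.size) < 32:
            raise ValueError("phantom must be at least 32x32")
        # the blob's radial perturbation can reach ~1.2x the base radius
        if self.target_radius_frac * 1.3 >= 0.5:
            raise ValueError("target does not fit inside the image")


def _signed_distance(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Approximate signed distance to the target boundary (positive inside)."""
    h, w = spec.size
    r0 = spec.target_radius_frac * min(h, w)
    jitter = 0.03 * min(h, w)
    cr = h / 2 + rng.uniform(-jitter, jitter)
    cc = w / 2 + rng.uniform(-jitter, jitter)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    dr, dc = rr - cr, cc_grid - cc
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    if spec.target_shape == "disk":
        return r0 - rho
    if spec.target_shape == "ellipse":
        ax_a, ax_b = 1.25 * r0, 0.8 * r0
        rot = rng.uniform(0, np.pi)
        x = dc * np.cos(rot) + dr * np.sin(rot)
        y = -dc * np.sin(rot) + dr * np.cos(rot)
        rho_n = np.sqrt((x / ax_a) ** 2 + (y / ax_b) ** 2)
        return (1.0 - rho_n) * min(ax_a, ax_b)
    # blob: low-order harmonic perturbation of the disk radius
    amps = rng.uniform(-0.06, 0.06, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    radius = r0 * (
        1.0
        + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, (2, 3, 4), phases))
    )
    return radius - rho


def _stroke_alpha(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length: float,
    half_width: float,
) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased coverage of one line segment, on its bounding patch."""
    h, w = shape
    cr, cc = center
    dr, dc = np.sin(angle), np.cos(angle)
    pad = length / 2 + half_width + 2
    r_lo, r_hi = int(max(0, cr - pad)), int(min(h, cr + pad + 1))
    c_lo, c_hi = int(max(0, cc - pad)), int(min(w, cc + pad + 1))
    rr, cc_grid = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    # distance to the segment of half-length length/2 through center
    pr, pc = rr - cr, cc_grid - cc
    t = np.clip(pr * dr + pc * dc, -length / 2, length / 2)
    dist = np.hypot(pr - t * dr, pc - t * dc)
    alpha = np.clip(half_width + 0.5 - dist, 0.0, 1.0)
    return slice(r_lo, r_hi), slice(c_lo, c_hi), alpha


def make_phantom(spec: PhantomSpec) -> tuple[Image2D, BinaryMask]:
    """Render a phantom and its ground-truth mask.

    The target boundary is anti-aliased over one pixel; strokes are drawn
    only on background lattice cells selected at ``clutter_density`` and
    are masked away from the target; Gaussian noise is added last and the
    result clipped to [0, 255].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    d = _signed_distance(spec, rng)
    target_alpha = np.clip(d + 0.5, 0.0, 1.0)
    truth = (d > 0).astype(np.uint8)
    img = spec.background_intensity + (
        spec.target_intensity - spec.background_intensity
    ) * target_alpha
    # clutter strokes on background lattice cells
    keep_out = target_alpha > 0
    for r0 in range(0, h, _CLUTTER_TILE):
        for c0 in range(0, w, _CLUTTER_TILE):
            cell = keep_out[r0 : r0 + _CLUTTER_TILE, c0 : c0 + _CLUTTER_TILE]
            is_background = not cell.any()
            fill = rng.uniform() < spec.clutter_density
            if not (is_background and fill):
                continue
            for _ in range(int(rng.integers(6, 13))):
                center = (
                    r0 + rng.uniform(0, _CLUTTER_TILE),
                    c0 + rng.uniform(0, _CLUTTER_TILE),
                )
                angle = rng.uniform(0, np.pi)
                length = rng.uniform(5, 11)
                sign = 1.0 if rng.uniform() < 0.5 else -1.0
                rs, cs, alpha = _stroke_alpha((h, w), center, angle, length, 0.7)
                patch = alpha * (1.0 - target_alpha[rs, cs])
                img[rs, cs] += sign * spec.clutter_contrast * patch
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return Image2D(np.clip(img, 0.0, 255.0)), BinaryMask(truth)


def phantom_suite(
    n: int, base_seed: int
) -> list[tuple[Image2D, BinaryMask, PhantomSpec]]:
    """A reproducible suite spanning the study grid.

    Phantoms cycle through the full cross of clutter densities
    {0.2, 0.5, 0.8}, noise sigmas {2, 5, 10} and the three target shapes
    (27 combinations); per-phantom seeds are spawned deterministically
    from ``base_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    combos = list(itertools.product((0.2, 0.5, 0.8), (2.0, 5.0, 10.0), _SHAPES))
    out = []
    for i in range(n):
        density, sigma, shape = combos[i % len(combos)]
        seed = int(
            np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % 2**31
        )
        spec = PhantomSpec(
            target_shape=shape,
            clutter_density=density,
            noise_sigma=sigma,
            seed=seed,
        )
        img, truth = make_phantom(spec)
        out.append((img, truth, spec))
    return out
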