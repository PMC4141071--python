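"""Structure-tensor field, eigenvalues and orientation-coherence diagnostics.

The structure tensor J = G_rho * (grad I grad I^T) summarizes, per pixel,
how intensity varies in a Gaussian neighborhood of scale rho.  Its
eigenvalues (lambda1 >= lambda2 >= 0) measure intensity variation along
the principal and minor axes; a single coherent edge is rank-one
(lambda2 ~ 0) while multi-oriented clutter has comparable eigenvalues.
This module is diagnostic: the segmentation path derives its weights from
orientation entropy, not from the eigenvalues, but the tensor field makes
the structured/unstructured dichotomy visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image import Image2D

__all__ = ["TensorField", "tensor_field", "coherence_map", "export_tensor_quiver"]


@dataclass(frozen=True)
class TensorField:
    """Per-pixel smoothed gradient products and their eigensystem.

    v1/v2 are unit eigenvector fields stored as (..., 2) arrays in
    (row, col) components; lambda1 >= lambda2 >= 0 everywhere and
    lambda1 + lambda2 equals the tensor trace j11 + j22.
    """

    j11: np.ndarray
    j12: np.ndarray
    j22: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    smoothing_scale: float


def tensor_field(img: Image2D, smoothing_scale: float = 2.0) -> TensorField:
    """Compute the structure-tensor field of an image.

    Gradients are central differences with replicated borders; the outer
    products are smoothed by an isotropic Gaussian of scale
    ``smoothing_scale`` (pixels, 0 disables smoothing).  Eigenvalues use
    the closed form for a symmetric 2x2 matrix,

        lambda_{1,2} = (j11 + j22)/2 +- sqrt(((j11 - j22)/2)^2 + j12^2),

    the + sign belonging to lambda1.
    """
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    gr, gc = np.gradient(img.pixels)  # central differences, replicate edges
    j11 = gr * gr
    j12 = gr * gc
    j22 = gc * gc
    if smoothing_scale > 0:
        j11 = gaussian_filter(j11, smoothing_scale)
        j12 = gaussian_filter(j12, smoothing_scale)
        j22 = gaussian_filter(j22, smoothing_scale)
    mean = 0.5 * (j11 + j22)
    disc = np.sqrt((0.5 * (j11 - j22)) ** 2 + j12**2)
    lambda1 = mean + disc
    lambda2 = np.maximum(mean - disc, 0.0)  # clip tiny negative round-off
    theta = 0.5 * np.arctan2(2.0 * j12, j11 - j22)
    v1 = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    v2 = np.stack([-np.sin(theta), np.cos(theta)], axis=-1)
    return TensorField(
        j11=j11,
        j12=j12,
        j22=j22,
        lambda1=lambda1,
        lambda2=lambda2,
        v1=v1,
        v2=v2,
        smoothing_scale=float(smoothing_scale),
    )


def coherence_map(tf: TensorField) -> np.ndarray:
    """Orientation coherence (lambda1 - lambda2) / (lambda1 + lambda2).

    1 on a perfectly coherent (rank-one) edge, 0 for isotropic content;
    0/0 is defined as 0 (no structure at all).
    """
    num = tf.lambda1 - tf.lambda2
    den = tf.lambda1 + tf.lambda2
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return np.clip(out, 0.0, 1.0)


def export_tensor_quiver(
    tf: TensorField, stride: int, path: str | Path, background: Image2D | None = None
) -> None:
    """Write a glyph overlay of the principal directions, subsampled by stride.

    Glyph length is proportional to sqrt(lambda1) so flat regions draw
    zero-length glyphs.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = tf.lambda1.shape
    rr, cc = np.mgrid[stride // 2 : h : stride, stride // 2 : w : stride]
    amp = np.sqrt(tf.lambda1[rr, cc])
    peak = amp.max()
    if peak > 0:
        amp = amp / peak
    # v1 is (row, col); quiver wants (x, y) = (col, row) with y flipped
    u = tf.v1[rr, cc, 1] * amp
    v = -tf.v1[rr, cc, 0] * amp
    fig, ax = plt.subplots(figsize=(6, 6 * h / max(w, 1)))
    if background is not None:
        ax.imshow(background.pixels, cmap="gray", vmin=0, vmax=255)
    ax.quiver(cc, rr, u, v, color="red", angles="xy", pivot="middle")
    ax.set_xlim(-0.5, w - 0.5)
    ax.set_ylim(h - 0.5, -0.5)
    ax.set_axis_off()
    try:
        fig.savefig(path, bbox_inches="tight", dpi=150)
    finally:
        plt.close(fig)
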