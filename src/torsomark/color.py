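"""sRGB linearization, chromaticity decomposition and gray-pixel selection.

These primitives are shared by white balancing, exposure control, marker
classification and color calibration.  Images are ``(H, W, 3)`` arrays:
8-bit gamma-compressed on the sensor side, float linear RGB in ``[0, 1]``
internally.  A pixel's *chromaticity* ``(r, g, b)`` is its color normalized
by the total linear intensity ``I = R + G + B`` (``I`` ranges up to 3), so
brightness and hue are handled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    MAX_INTENSITY,
    SRGB_GAMMA,
    SRGB_LINEAR_SLOPE,
    SRGB_LINEAR_THRESHOLD,
    SRGB_OFFSET,
    GamutTarget,
)

__all__ = [
    "srgb_to_linear",
    "linear_to_srgb",
    "linearize",
    "compress",
    "ChromaticityImage",
    "to_chromaticity",
    "select_gray_pixels",
]


def srgb_to_linear(v: np.ndarray | float) -> np.ndarray | float:
    """Gamma-decompress sRGB values in [0, 1] to linear light."""
    v = np.asarray(v, dtype=np.float64)
    lo = v <= SRGB_LINEAR_THRESHOLD
    out = np.where(
        lo,
        v / SRGB_LINEAR_SLOPE,
        ((v + SRGB_OFFSET) / (1.0 + SRGB_OFFSET)) ** SRGB_GAMMA,
    )
    return out


def linear_to_srgb(v: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`srgb_to_linear` (gamma compression)."""
    v = np.asarray(v, dtype=np.float64)
    lo = v <= SRGB_LINEAR_THRESHOLD / SRGB_LINEAR_SLOPE
    with np.errstate(invalid="ignore"):
        out = np.where(
            lo,
            v * SRGB_LINEAR_SLOPE,
            (1.0 + SRGB_OFFSET) * np.maximum(v, 0.0) ** (1.0 / SRGB_GAMMA) - SRGB_OFFSET,
        )
    return out


# 256-entry lookup table: 8-bit gamma value -> linear channel in [0, 1].
LINEARIZE_LUT: np.ndarray = srgb_to_linear(np.arange(256) / 255.0)


def linearize(raw: np.ndarray) -> np.ndarray:
    """Gamma-decompress an 8-bit RGB image via the 256-entry lookup table.

    Parameters
    ----------
    raw:
        ``(..., 3)`` integer array with channels in [0, 255].

    Returns
    -------
    Linear RGB float image in [0, 1].
    """
    raw = np.asarray(raw)
    if raw.dtype.kind not in "ui":
        raise TypeError("linearize expects an integer 8-bit image")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return LINEARIZE_LUT[raw]


def compress(linear: np.ndarray) -> np.ndarray:
    """Map a linear RGB float image back to 8-bit gamma values.

    Implemented as a left-bisection search over the linearized lookup-table
    bin boundaries (midpoints between consecutive table entries), mirroring
    how the recording pipeline avoids evaluating the power law per pixel.
    """
    boundaries = (LINEARIZE_LUT[:-1] + LINEARIZE_LUT[1:]) / 2.0
    idx = np.searchsorted(boundaries, np.asarray(linear, dtype=np.float64))
    return idx.astype(np.uint8)


@dataclass
class ChromaticityImage:
    """Per-pixel chromaticity plus intensity with an explicit validity mask.

    ``chromaticity[..., k]`` are (r, g, b) fractions summing to one wherever
    ``defined`` is set; ``intensity`` is R+G+B in [0, 3].  Zero-intensity
    (black) pixels are masked out rather than carrying sentinel values.
    """

    chromaticity: np.ndarray
    intensity: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.defined is None:
            self.defined = self.intensity > 0


def to_chromaticity(linear: np.ndarray) -> ChromaticityImage:
    """Split a linear RGB image into chromaticity and intensity.

    ``I = R+G+B``; ``(r, g, b) = (R, G, B)/I``.  Pixels with ``I = 0`` are
    flagged undefined and their chromaticity entries are zero.
    """
    linear = np.asarray(linear, dtype=np.float64)
    intensity = linear.sum(axis=-1)
    defined = intensity > 0
    safe = np.where(defined, intensity, 1.0)
    chrom = linear / safe[..., None]
    chrom[~defined] = 0.0
    return ChromaticityImage(chromaticity=chrom, intensity=intensity, defined=defined)


def select_gray_pixels(chrom: ChromaticityImage, target: GamutTarget) -> np.ndarray:
    """Boolean mask of pixels that plausibly image a neutral gray surface.

    A pixel qualifies when it falls inside both axis-aligned chromaticity
    ellipses around the neutral gamut point — the red/green ellipse and the
    blue/green one — and its intensity lies strictly inside the
    properly-exposed band ``(i_min·maxI, i_max·maxI)``.  An all-false result
    is legitimate (no gray reference in view).
    """
    c = chrom.chromaticity
    r, g, b = c[..., 0], c[..., 1], c[..., 2]
    ell_rg = (r - target.r) ** 2 / target.sigma_r**2 + (g - target.g) ** 2 / target.sigma_g**2
    ell_bg = (b - target.b) ** 2 / target.sigma_b**2 + (g - target.g) ** 2 / target.sigma_g**2
    exposed = (chrom.intensity > target.i_min * MAX_INTENSITY) & (
        chrom.intensity < target.i_max * MAX_INTENSITY
    )
    return chrom.defined & exposed & (ell_rg <= 1.0) & (ell_bg <= 1.0)
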