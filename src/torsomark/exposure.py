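"""Patient-locked, histogram-skewness-driven auto-exposure control.

Only pixels belonging to the patient (via the depth segmentation mask
mapped into the color image) contribute to the exposure histogram, so the
skin brightness stays constant no matter how bright the background is.
The controller drives the skewness of the gamma-domain gray-value
histogram about mid-gray (128) toward zero: a dark-skewed histogram
lengthens the exposure, a bright-skewed one shortens it.  The histogram is
built directly from linear intensities by bisecting a table of linearized
bin boundaries, never gamma-compressing per pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import color
from .config import MAX_INTENSITY, ExposureConfig
from .white_balance import CameraState

log = logging.getLogger(__name__)

__all__ = ["ExposureState", "masked_histogram", "skewness", "update_exposure"]

#: Linearized boundaries between the 256 gamma-domain gray bins, scaled to
#: total intensity I in [0, 3].  Bin v collects I in (edges[v], edges[v+1]].
_BIN_BOUNDARIES = color.srgb_to_linear(
    (np.arange(255) + 0.5) / 255.0
) * MAX_INTENSITY


@dataclass
class ExposureState:
    """Controller state: virtual overall exposure and its reference."""

    tau_star: float = 100.0   # ms, virtual overall exposure parameter
    cfg: ExposureConfig = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.cfg is None:
            self.cfg = ExposureConfig()

    @property
    def tau_ref(self) -> float:
        """Gain-crossover reference exposure (clamped optimal frame time)."""
        c = self.cfg
        return max(min(c.tau_frame, c.tau_max), c.tau_min)


def masked_histogram(
    chrom: color.ChromaticityImage,
    mask: np.ndarray,
    target=None,
) -> np.ndarray:
    """256-bin gamma-domain gray-value histogram of the masked region.

    Counts only masked pixels whose intensity lies in the properly-exposed
    band; the bin index is found by left bisection over the precomputed
    linearized boundaries.  An empty selection yields an all-zero histogram
    (flagged by a warning).
    """
    from .config import GamutTarget

    target = target or GamutTarget()
    sel = mask & chrom.defined
    sel &= (chrom.intensity > target.i_min * MAX_INTENSITY) & (
        chrom.intensity < target.i_max * MAX_INTENSITY
    )
    values = chrom.intensity[sel]
    if values.size == 0:
        log.warning("masked_histogram: no properly exposed masked pixels")
        return np.zeros(256, dtype=np.int64)
    bins = np.searchsorted(_BIN_BOUNDARIES, values)
    return np.bincount(bins, minlength=256).astype(np.int64)


def skewness(hist: np.ndarray) -> float:
    """Standardized third central moment of the histogram about gray 128.

    ``S = m3 / m2^{3/2}`` with ``m_k = Σ H(v)(v−128)^k / Σ H(v)``; the
    per-bin powers are precomputed.  ``S = 0`` for a degenerate histogram
    (all mass at 128 or empty).
    """
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total == 0:
        return 0.0
    dev = np.arange(256, dtype=np.float64) - 128.0
    m2 = float((hist * dev**2).sum() / total)
    m3 = float((hist * dev**3).sum() / total)
    if m2 == 0:
        return 0.0
    return m3 / m2**1.5


def update_exposure(
    state: ExposureState, cam: CameraState, s: float
) -> tuple[ExposureState, CameraState]:
    """One exposure-controller step from the measured skewness ``s``.

    The virtual overall exposure moves opposite to the skewness,
    ``τ*_{n+1} = τ*_n − S·τΔ·Nτ·Γex,n``; the physical gain follows as the
    clamped ratio to the reference exposure and the physical exposure time
    as the clamped ratio ``τ*/Γex``.
    """
    c = state.cfg
    tau_star = state.tau_star - s * c.tau_delta * c.n_tau * cam.gain
    tau_star = max(tau_star, c.tau_min)
    gain = max(min(tau_star / state.tau_ref, c.gain_max), c.gain_min)
    tau = max(min(tau_star / gain, c.tau_max), c.tau_min)
    return replace(state, tau_star=tau_star), replace(cam, tau=tau, gain=gain)
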