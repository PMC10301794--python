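"""Marker-color calibration from masked chromaticity images.

The red/blue classification ellipses are derived from manually masked
clip-head pixels of a few recordings: a 256x256 heat map over (r, g)
chromaticity is built and median-filtered, Gaussian-shaped peaks are
located by thresholding, and a Gaussian mixture initialized at the peak
centroids is fitted to the pixel samples.  The component with the largest
mean red chromaticity becomes the red ellipse, the one maximizing
1 − r − g the blue ellipse; any further components (highlights, raw
conversion artifacts) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.mixture import GaussianMixture

from . import color
from .config import MAX_INTENSITY, GamutTarget, MarkerColorCalibration

log = logging.getLogger(__name__)

__all__ = ["CalibrationError", "build_heatmap", "find_peaks", "extract_components", "calibrate"]

HEATMAP_BINS = 256


class CalibrationError(RuntimeError):
    pass


def masked_samples(
    chrom: color.ChromaticityImage,
    mask: np.ndarray,
    target: GamutTarget | None = None,
) -> np.ndarray:
    """(r, g) samples of masked, properly exposed, defined pixels."""
    target = target or GamutTarget()
    sel = mask & chrom.defined
    sel &= (chrom.intensity > target.i_min * MAX_INTENSITY) & (
        chrom.intensity < target.i_max * MAX_INTENSITY
    )
    return chrom.chromaticity[sel][:, :2]


def build_heatmap(samples_list: list[np.ndarray]) -> np.ndarray:
    """Median-filtered 2D histogram of (r, g) chromaticities.

    256 bins per axis over [0, 1); the 7x7 median filter suppresses
    isolated single-bin spikes while preserving the Gaussian-shaped marker
    peaks.  Raises on empty input.
    """
    nonempty = [s for s in samples_list if len(s)]
    if not nonempty:
        raise CalibrationError("no masked pixels to build the heat map from")
    samples = np.concatenate(nonempty)
    idx = np.clip((samples * HEATMAP_BINS).astype(np.int64), 0, HEATMAP_BINS - 1)
    heat = np.zeros((HEATMAP_BINS, HEATMAP_BINS), dtype=np.float64)
    np.add.at(heat, (idx[:, 0], idx[:, 1]), 1.0)
    return ndimage.median_filter(heat, size=7, mode="constant")


def find_peaks(heatmap: np.ndarray, min_bins: int = 5, sigma_factor: float = 1.9):
    """Peak regions of the heat map.

    Bins above ``mean + 1.9 sd`` of the nonzero bins are labeled
    (4-connectivity); regions of at least 5 bins count as peaks.  Returns
    ``(labels, centroids)`` with centroids in (r, g) chromaticity units.
    """
    nz = heatmap[heatmap > 0]
    if nz.size == 0:
        raise CalibrationError("heat map is empty")
    thresh = nz.mean() + sigma_factor * nz.std()
    binary = heatmap > thresh
    lab, n = ndimage.label(binary)  # default structure = 4-connectivity
    peaks = []
    for k in range(1, n + 1):
        if (lab == k).sum() >= min_bins:
            peaks.append(k)
    if not peaks:
        raise CalibrationError("no peaks found on the heat map")
    centroids = np.array(
        [ndimage.center_of_mass(heatmap, lab, k) for k in peaks]
    )
    centroids = (centroids + 0.5) / HEATMAP_BINS
    return lab, centroids


def _ellipse_from_covariance(mean: np.ndarray, cov: np.ndarray):
    """Center, spreads and rotation angle of a Gaussian component.

    The spreads are the square roots of the covariance eigenvalues (major
    first); the angle is the rotation that maps the major axis onto the
    red axis, matching the rotated-ellipse classification form.  An
    isotropic component reports angle 0.
    """
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    sig1, sig2 = np.sqrt(np.maximum(vals, 0.0))
    if np.isclose(vals[0], vals[1]):
        phi = 0.0
    else:
        u1 = vecs[:, 0]
        phi = -np.arctan2(u1[1], u1[0])
        # fold into (-pi/2, pi/2]: the ellipse has period pi
        if phi <= -np.pi / 2:
            phi += np.pi
        elif phi > np.pi / 2:
            phi -= np.pi
    # report in the minimal-rotation convention (|phi| <= 45°): an ellipse
    # whose major axis lies along g is the g-spread ellipse, not an r-spread
    # one rotated a quarter turn
    if phi > np.pi / 4:
        phi -= np.pi / 2
        sig1, sig2 = sig2, sig1
    elif phi <= -np.pi / 4:
        phi += np.pi / 2
        sig1, sig2 = sig2, sig1
    return float(mean[0]), float(mean[1]), float(sig1), float(sig2), float(phi)


def extract_components(
    samples: np.ndarray,
    peak_centroids: np.ndarray,
    random_state: int = 0,
) -> MarkerColorCalibration:
    """Fit a Gaussian mixture at the peak centroids and pick red/blue.

    Red is the component with the largest mean r, blue the one maximizing
    ``1 − r − g``; their eigen-decomposed covariances give the spreads and
    rotation angles of the classification ellipses.  Fewer than two peaks
    is an error.
    """
    if len(peak_centroids) < 2:
        raise CalibrationError("need at least two peaks for red and blue")
    gm = GaussianMixture(
        n_components=len(peak_centroids),
        means_init=peak_centroids,
        covariance_type="full",
        random_state=random_state,
    ).fit(samples)
    means = gm.means_
    red_i = int(np.argmax(means[:, 0]))
    blue_i = int(np.argmax(1.0 - means[:, 0] - means[:, 1]))
    if red_i == blue_i:
        raise CalibrationError("red and blue selection collapsed onto one component")
    rr, rg, rs1, rs2, rphi = _ellipse_from_covariance(means[red_i], gm.covariances_[red_i])
    br, bg, bs1, bs2, bphi = _ellipse_from_covariance(means[blue_i], gm.covariances_[blue_i])
    return MarkerColorCalibration(
        red_r=rr, red_g=rg, red_sigma_r=rs1, red_sigma_g=rs2, red_phi=rphi,
        blue_r=br, blue_g=bg, blue_sigma_r=bs1, blue_sigma_g=bs2, blue_phi=bphi,
    )


def calibrate(
    chrom_images: list[color.ChromaticityImage],
    masks: list[np.ndarray],
    random_state: int = 0,
) -> MarkerColorCalibration:
    """Full calibration: heat map, peak detection, component extraction."""
    samples_list = [masked_samples(ci, m) for ci, m in zip(chrom_images, masks)]
    heat = build_heatmap(samples_list)
    _, centroids = find_peaks(heat)
    samples = np.concatenate([s for s in samples_list if len(s)])
    return extract_components(samples, centroids, random_state)
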