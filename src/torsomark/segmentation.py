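"""Foreground/background segmentation of 16-bit depth images.

Depth rasters are integer millimetres with 0 encoding "no valid depth".
The patient is separated from walls and furniture by (i) edge-preserving
Gaussian smoothing with a precomputed gradient-weight table, (ii) an
octagonal-Laplacian zero-crossing edge detector with a two-threshold
acceptance rule in the spirit of Canny hysteresis, (iii) selection of the
dominant connected component seeded in the central ninth of the image, and
(iv) a row-statistics depth band that strips outliers merged into the
patient component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import SegmentationConfig

log = logging.getLogger(__name__)

__all__ = [
    "SegmentationAbort",
    "SegmentationMask",
    "smooth_depth",
    "detect_edges",
    "depth_band",
    "select_patient",
]


class SegmentationAbort(RuntimeError):
    """No component qualifies as the patient; the frame should be skipped."""


@dataclass
class SegmentationMask:
    """Patient mask plus the edge sets it was derived from.

    ``mask`` never contains an edge or undefined-depth pixel; the edge
    pixels adjacent to the patient component are kept separately in
    ``boundary`` (they outline the contour but carry unreliable depth).
    """

    mask: np.ndarray                 # bool, patient pixels
    edges: np.ndarray                # bool, all accepted edge pixels
    primary: np.ndarray              # bool, primary edge subset
    boundary: np.ndarray             # bool, edge pixels adjacent to the mask
    d_close: float = 0.0             # mm, accepted depth band
    d_far: float = 0.0


# The octagonal Laplacian: 4-connected neighbours weighted 1, diagonal
# neighbours 1/sqrt(2) so every neighbour acts at unit distance; the centre
# balances the sum at -(4 + 2*sqrt(2)).
_SQ2 = 1.0 / np.sqrt(2.0)
OCTAGONAL_LAPLACIAN = np.array(
    [
        [_SQ2, 1.0, _SQ2],
        [1.0, -(4.0 + 2.0 * np.sqrt(2.0)), 1.0],
        [_SQ2, 1.0, _SQ2],
    ]
)


def _gradient_sq(depth: np.ndarray) -> np.ndarray:
    """Squared central-difference gradient magnitude, invalid pixels excluded."""
    d = depth.astype(np.float64)
    valid = depth > 0
    dpad = np.pad(d, 1, mode="edge")
    vpad = np.pad(valid, 1, mode="edge")

    def diff(axis):
        if axis == 0:
            plus, minus = dpad[2:, 1:-1], dpad[:-2, 1:-1]
            vp, vm = vpad[2:, 1:-1], vpad[:-2, 1:-1]
        else:
            plus, minus = dpad[1:-1, 2:], dpad[1:-1, :-2]
            vp, vm = vpad[1:-1, 2:], vpad[1:-1, :-2]
        both = vp & vm
        one_sided_p = vp & ~vm
        one_sided_m = vm & ~vp
        g = np.zeros_like(d)
        g[both] = (plus[both] - minus[both]) / 2.0
        g[one_sided_p] = plus[one_sided_p] - d[one_sided_p]
        g[one_sided_m] = d[one_sided_m] - minus[one_sided_m]
        return g

    return diff(0) ** 2 + diff(1) ** 2


def gradient_weight_table(cfg: SegmentationConfig, max_grad: int = 4096):
    """Precomputed weights w16 for integer gradient magnitudes.

    Returns ``(squared_boundaries, weights)``: the weight for a pixel with
    squared gradient ``g2`` is ``weights[searchsorted(squared_boundaries,
    g2)]`` — a left bisection over the squared midpoints between
    consecutive integer gradient values, so neither square roots nor
    exponentials are evaluated per pixel.
    """
    grads = np.arange(max_grad, dtype=np.float64)
    weights = np.exp(-(grads**2) / (2.0 * cfg.sigma_depth**2))
    boundaries_sq = (grads[:-1] + 0.5) ** 2
    return boundaries_sq, weights


def smooth_depth(depth: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Edge-preserving Gaussian smoothing of a depth raster.

    Each neighbour contributes with a spatial Gaussian weight times a
    gradient-magnitude weight fetched from the precomputed table, so pixels
    sitting on strong depth steps barely bleed across them.  Undefined
    pixels (0) are excluded from every average and copied through
    unchanged.  Returns float millimetres.
    """
    cfg = cfg or SegmentationConfig()
    valid = depth > 0
    d = depth.astype(np.float64)

    boundaries_sq, weights = gradient_weight_table(cfg)
    g2 = _gradient_sq(depth)
    w = weights[np.minimum(np.searchsorted(boundaries_sq, g2), len(weights) - 1)]
    w = w * valid

    half = cfg.support // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    kern1 = np.exp(-(ax**2) / (2.0 * cfg.sigma_spatial**2))

    def blur(img):
        tmp = ndimage.correlate1d(img, kern1, axis=0, mode="constant")
        return ndimage.correlate1d(tmp, kern1, axis=1, mode="constant")

    num = blur(w * d)
    den = blur(w)
    out = np.where(valid & (den > 0), num / np.where(den > 0, den, 1.0), d)
    out[~valid] = 0.0
    return out


def _shifted(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    return np.pad(img, 1, mode="edge")[1 + dy : img.shape[0] + 1 + dy,
                                       1 + dx : img.shape[1] + 1 + dx]


#: Opposing 8-neighbour direction pairs (N/S, E/W, NE/SW, NW/SE).
_DIRECTIONS = [(-1, 0), (0, 1), (-1, 1), (-1, -1)]


def detect_edges(
    smoothed: np.ndarray, cfg: SegmentationConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Primary and minor edge pixels of a smoothed depth image.

    Candidates are zero crossings of the octagonal Laplacian (a sign change
    between opposing 8-neighbours).  The edge strength is the largest
    opposing-neighbour depth difference, doubled when only a one-sided
    neighbour carries valid depth.  Candidates stronger than the primary
    limit, or bordering undefined depth, are primary edges; the remaining
    candidates are accepted as minor edges when the modified two-threshold
    rule holds and they connect (8-connectivity) to a primary edge.
    """
    cfg = cfg or SegmentationConfig()
    d = np.asarray(smoothed, dtype=np.float64)
    valid = d > 0

    lap = ndimage.correlate(d, OCTAGONAL_LAPLACIAN, mode="nearest")
    candidate = np.zeros(d.shape, dtype=bool)
    for dy, dx in _DIRECTIONS:
        lp = _shifted(lap, dy, dx)
        lm = _shifted(lap, -dy, -dx)
        candidate |= lp * lm < 0
    candidate &= valid

    # Edge strength per Eq-16-style neighbour cases.
    strength = np.zeros(d.shape)
    for dy, dx in _DIRECTIONS:
        dp, dm = _shifted(d, dy, dx), _shifted(d, -dy, -dx)
        vp, vm = dp > 0, dm > 0
        s = np.zeros(d.shape)
        both = vp & vm
        s[both] = np.abs(dp[both] - dm[both])
        only_m = vm & ~vp
        s[only_m] = 2.0 * np.abs(dm[only_m] - d[only_m])
        only_p = vp & ~vm
        s[only_p] = 2.0 * np.abs(dp[only_p] - d[only_p])
        strength = np.maximum(strength, s)

    has_undefined_neighbor = np.zeros(d.shape, dtype=bool)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            has_undefined_neighbor |= ~(_shifted(valid, dy, dx))

    primary = candidate & ((strength > cfg.edge_primary) | has_undefined_neighbor)

    p, m = cfg.edge_primary, cfg.edge_minor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(strength < p, (strength - m) / (p - strength), np.inf)
    minor_ok = candidate & (strength > m) & ((strength > p) | (ratio > 1.0))

    # Hysteresis: keep minor candidates connected to a primary edge.
    lab, n = ndimage.label(minor_ok | primary, structure=np.ones((3, 3)))
    keep = np.zeros(n + 1, dtype=bool)
    if n:
        keep[np.unique(lab[primary])] = True
        keep[0] = False
    minor = minor_ok & keep[lab] & ~primary
    return primary, minor


def depth_band(
    row_close: np.ndarray, row_far: np.ndarray, d_near: float = 200.0
) -> tuple[float, float]:
    """Accepted depth interval from per-row close/far statistics.

    ``row_close``/``row_far`` are the smallest and largest depths of the
    patient component in each occupied row.  The far bound caps the row
    maxima at one third of the overall depth spread past the farthest row
    (or mean + 3 sd, whichever is tighter); the close bound mirrors this
    and never drops below the sensor's near limit.
    """
    row_close = np.asarray(row_close, dtype=np.float64)
    row_far = np.asarray(row_far, dtype=np.float64)
    spread = row_far.max() - row_close.min()
    d_far = min(
        row_far.max() + spread / 3.0,
        row_far.mean() + 3.0 * row_far.std(),
    )
    close_spread = row_close.max() - row_close.min()
    d_close = max(
        row_close.min() - close_spread / 3.0,
        row_close.mean() - 3.0 * row_far.std(),
        d_near,
    )
    return d_close, d_far


def select_patient(
    depth: np.ndarray,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
    cfg: SegmentationConfig | None = None,
) -> SegmentationMask:
    """Segment the patient component out of a depth frame.

    Edge and undefined pixels are removed, the image is split into a 3x3
    grid, and the largest 4-connected component inside the central segment
    that reaches the segment border is flood-filled across the whole frame.
    A per-row depth band strips background bleeding; components smaller
    than 200 px (or without a valid band) are rejected and the next-largest
    tried.  Raises :class:`SegmentationAbort` when nothing qualifies.
    """
    cfg = cfg or SegmentationConfig()
    if edges is None:
        primary, minor = detect_edges(smooth_depth(depth, cfg), cfg)
    else:
        primary, minor = edges
    edge = primary | minor
    base = (depth > 0) & ~edge

    h, w = depth.shape
    r0, r1 = h // 3, 2 * h // 3
    c0, c1 = w // 3, 2 * w // 3
    central = np.zeros_like(base)
    central[r0:r1, c0:c1] = True

    lab_c, n_c = ndimage.label(base & central)
    if n_c == 0:
        raise SegmentationAbort("no components in the central segment")
    sizes = ndimage.sum_labels(np.ones_like(lab_c), lab_c, index=np.arange(1, n_c + 1))
    border = np.zeros_like(central)
    border[r0, c0:c1] = border[r1 - 1, c0:c1] = True
    border[r0:r1, c0] = border[r0:r1, c1 - 1] = True
    touches = np.unique(lab_c[border & (lab_c > 0)])

    # Candidate central components, largest first; equal sizes break toward
    # the component whose centroid is nearest the image centre.
    centroids = ndimage.center_of_mass(base & central, lab_c, index=np.arange(1, n_c + 1))
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    dist = [float(np.hypot(*(np.asarray(cm) - center))) for cm in centroids]
    order = sorted(
        (i + 1 for i in range(n_c) if (i + 1) in set(touches)),
        key=lambda lbl: (-sizes[lbl - 1], dist[lbl - 1]),
    )

    lab_full, _ = ndimage.label(base)
    for lbl in order:
        seed_pixels = np.argwhere(lab_c == lbl)
        seed = tuple(seed_pixels[0])
        full_lbl = lab_full[seed]
        comp = lab_full == full_lbl

        rows_any = comp.any(axis=1)
        if not rows_any.any():
            continue
        dmat = np.where(comp, depth.astype(np.float64), np.nan)
        with np.errstate(all="ignore"):
            row_close = np.nanmin(dmat[rows_any], axis=1)
            row_far = np.nanmax(dmat[rows_any], axis=1)
        d_close, d_far = depth_band(row_close, row_far, cfg.d_near)
        if not d_close <= d_far:
            continue
        # inclusive bounds: a perfectly flat component would otherwise
        # produce an empty band (close == far)
        final = comp & (depth >= d_close) & (depth <= d_far)
        if final.sum() < cfg.min_component:
            continue
        boundary = edge & ndimage.binary_dilation(final, np.ones((3, 3)))
        return SegmentationMask(
            mask=final,
            edges=edge,
            primary=primary,
            boundary=boundary,
            d_close=float(d_close),
            d_far=float(d_far),
        )
    raise SegmentationAbort("no component qualifies as the patient")
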