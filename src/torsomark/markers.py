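"""Colored electrode-marker extraction from corrected textures.

Each electrode clip head is a red epoxy disk inside a blue painted rim.
Pixels are classified in (r, g) chromaticity space by two rotated
ellipses, lifted onto the 3D surface through the texture mapping
(barycentric interpolation inside the containing uv triangle), filtered by
requiring a nearby neighbour of the opposite color (isolated red or blue
blobs are reflections and cables, not markers), and finally clustered into
per-electrode point sets with HDBSCAN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import HDBSCAN

from . import color
from .config import MarkerColorCalibration, MarkerConfig
from .meshing import TexturedSurface

log = logging.getLogger(__name__)

__all__ = [
    "MarkerPointCloud",
    "classify_pixels",
    "lift_to_surface",
    "opposite_color_filter",
    "cluster_markers",
    "realign_frontal",
]


@dataclass
class MarkerPointCloud:
    """3D marker points tagged by color, with surface normals and view ids."""

    points: np.ndarray            # (N, 3) mm
    is_blue: np.ndarray           # (N,) bool; False = red
    normals: np.ndarray           # (N, 3)
    view_ids: np.ndarray          # (N,) int

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def empty(cls) -> "MarkerPointCloud":
        return cls(
            points=np.empty((0, 3)),
            is_blue=np.empty(0, dtype=bool),
            normals=np.empty((0, 3)),
            view_ids=np.empty(0, dtype=np.int64),
        )

    def select(self, idx) -> "MarkerPointCloud":
        return MarkerPointCloud(
            self.points[idx], self.is_blue[idx], self.normals[idx], self.view_ids[idx]
        )

    @classmethod
    def concatenate(cls, clouds) -> "MarkerPointCloud":
        clouds = [c for c in clouds if len(c)]
        if not clouds:
            return cls.empty()
        return cls(
            np.concatenate([c.points for c in clouds]),
            np.concatenate([c.is_blue for c in clouds]),
            np.concatenate([c.normals for c in clouds]),
            np.concatenate([c.view_ids for c in clouds]),
        )


def _ellipse_inside(r, g, cr, cg, sr, sg, phi):
    dr = r - cr
    dg = g - cg
    u = dr * np.cos(phi) - dg * np.sin(phi)
    w = dr * np.sin(phi) + dg * np.cos(phi)
    return u**2 / sr**2 + w**2 / sg**2 <= 1.0


def classify_pixels(
    chrom: color.ChromaticityImage, calib: MarkerColorCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Red and blue marker pixel masks from the calibrated chromaticity ellipses.

    Membership uses the standard rotated-ellipse form with squared spreads;
    a pixel matching both ellipses counts as red.
    """
    c = chrom.chromaticity
    r, g = c[..., 0], c[..., 1]
    red = chrom.defined & _ellipse_inside(
        r, g, calib.red_r, calib.red_g, calib.red_sigma_r, calib.red_sigma_g, calib.red_phi
    )
    blue = chrom.defined & _ellipse_inside(
        r, g, calib.blue_r, calib.blue_g, calib.blue_sigma_r, calib.blue_sigma_g, calib.blue_phi
    )
    blue &= ~red
    return red, blue


def lift_to_surface(
    pixels: np.ndarray,
    is_blue: np.ndarray,
    surface: TexturedSurface,
    max_candidates: int = 12,
) -> MarkerPointCloud:
    """Map texture pixels to 3D surface points via barycentric coordinates.

    ``pixels`` is an ``(N, 2)`` array of (column, row) texture coordinates.
    For each pixel the uv triangle containing it is located (nearest
    triangle centroids first); the 3D point and normal are the barycentric
    combinations of the triangle's vertices.  Pixels outside every triangle
    are dropped.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if len(pixels) == 0:
        return MarkerPointCloud.empty()
    uv = surface.uv
    tris = surface.triangles
    if len(tris) == 0:
        return MarkerPointCloud.empty()
    centroids = uv[tris].mean(axis=1)
    tree = cKDTree(centroids)
    _, cand = tree.query(pixels, k=min(max_candidates, len(tris)))
    cand = np.atleast_2d(cand.reshape(len(pixels), -1))

    vnormals = surface.vertex_normals()
    found = np.full(len(pixels), -1, dtype=np.int64)
    bary = np.zeros((len(pixels), 3))
    tol = 1e-9
    for k in range(cand.shape[1]):
        todo = found < 0
        if not todo.any():
            break
        t_idx = cand[todo, k]
        a = uv[tris[t_idx, 0]]
        b = uv[tris[t_idx, 1]]
        c_ = uv[tris[t_idx, 2]]
        p = pixels[todo]
        v0 = b - a
        v1 = c_ - a
        v2 = p - a
        den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
        ok_den = np.abs(den) > 1e-12
        den = np.where(ok_den, den, 1.0)
        l1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
        l2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
        l0 = 1.0 - l1 - l2
        inside = ok_den & (l0 >= -tol) & (l1 >= -tol) & (l2 >= -tol)
        todo_idx = np.flatnonzero(todo)
        hit = todo_idx[inside]
        found[hit] = t_idx[inside]
        bary[hit, 0] = l0[inside]
        bary[hit, 1] = l1[inside]
        bary[hit, 2] = l2[inside]

    ok = found >= 0
    t = tris[found[ok]]
    w = bary[ok][:, :, None]
    pts = (surface.vertices[t] * w).sum(axis=1)
    nrm = (vnormals[t] * w).sum(axis=1)
    norm = np.linalg.norm(nrm, axis=1)
    nrm /= np.where(norm > 0, norm, 1.0)[:, None]
    return MarkerPointCloud(
        points=pts,
        is_blue=np.asarray(is_blue)[ok],
        normals=nrm,
        view_ids=np.full(ok.sum(), surface.view_id, dtype=np.int64),
    )


def opposite_color_filter(
    cloud: MarkerPointCloud, rho_red: float, rho_blue: float
) -> MarkerPointCloud:
    """Keep points with at least one opposite-color neighbour nearby.

    Red points need a blue neighbour within the clip-head radius
    ``rho_red``; blue points need a red neighbour within the ring width
    ``rho_blue``.  Isolated single-color blobs (cable reflections, shaded
    skin) disappear entirely.
    """
    red_pts = cloud.points[~cloud.is_blue]
    blue_pts = cloud.points[cloud.is_blue]
    keep = np.zeros(len(cloud), dtype=bool)
    if len(red_pts) and len(blue_pts):
        tree_b = cKDTree(blue_pts)
        tree_r = cKDTree(red_pts)
        d_r, _ = tree_b.query(red_pts, k=1)
        d_b, _ = tree_r.query(blue_pts, k=1)
        keep[~cloud.is_blue] = d_r <= rho_red
        keep[cloud.is_blue] = d_b <= rho_blue
    return cloud.select(keep)


def cluster_markers(
    cloud: MarkerPointCloud, cfg: MarkerConfig | None = None
) -> list[MarkerPointCloud]:
    """Split the filtered marker cloud into per-electrode clusters.

    Hierarchical density clustering with minimum cluster size
    ``max(count(red)/(4·Nclip), 20)``, minimum samples 20, and a
    split-stopping distance equal to the clip-head radius so a single
    marker is never divided while adjacent markers stay apart.  Noise
    points are discarded.
    """
    cfg = cfg or MarkerConfig()
    if len(cloud) == 0:
        log.warning("cluster_markers: empty marker cloud")
        return []
    n_red = int((~cloud.is_blue).sum())
    min_cluster = int(max(n_red / (4.0 * cfg.n_electrodes), cfg.min_samples))
    if len(cloud) <= max(min_cluster, cfg.min_samples):
        log.warning("cluster_markers: too few points (%d)", len(cloud))
        return []
    labels = HDBSCAN(
        min_cluster_size=min_cluster,
        min_samples=cfg.min_samples,
        cluster_selection_epsilon=cfg.head_radius,
    ).fit_predict(cloud.points)
    out = []
    for lbl in np.unique(labels):
        if lbl < 0:
            continue
        out.append(cloud.select(labels == lbl))
    if not out:
        log.warning("cluster_markers: no clusters found")
    return out


def _shoulder_yaw(points: np.ndarray) -> float | None:
    """Yaw (rad) of the shoulder axis relative to +x, or None if degenerate."""
    z = points[:, 2]
    z_lo = z.min() + 2.0 * (z.max() - z.min()) / 3.0
    chest = points[z >= z_lo]
    if len(chest) < 3:
        return None
    x = chest[:, 0]
    edges = np.linspace(x.min(), x.max() + 1e-9, 4)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 2)
    right_sel = chest[idx == 0]
    left_sel = chest[idx == 2]
    if len(right_sel) == 0 or len(left_sel) == 0:
        return None
    v = np.median(left_sel, axis=0) - np.median(right_sel, axis=0)
    if np.hypot(v[0], v[1]) < 1e-9:
        return None
    return float(np.arctan2(v[1], v[0]))


def realign_frontal(points: np.ndarray, max_iter: int = 5) -> np.ndarray:
    """Transform aligning the shoulder axis with the frontal plane's x-axis.

    The torso cloud is split into chest/belly/hip thirds along z; the chest
    third is split 3-way along x, and the right→left vector between the
    median points of the outer sections is rotated (about z) onto +x.  The
    x-band medians underestimate large yaws on an elliptic cross-section,
    so the estimate is iterated until it settles below one degree.  Returns
    a 4x4 transform; degenerate shoulder sections yield identity.
    """
    t = np.eye(4)
    pts = points
    for _ in range(max_iter):
        yaw = _shoulder_yaw(pts)
        if yaw is None:
            log.warning("realign_frontal: degenerate shoulder sections")
            break
        if abs(yaw) < np.radians(1.0):
            break
        step = np.eye(4)
        c, s = np.cos(-yaw), np.sin(-yaw)
        step[:2, :2] = [[c, -s], [s, c]]
        t = step @ t
        pts = points @ t[:3, :3].T
    return t
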