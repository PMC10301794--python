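"""Textured surface meshes from masked depth frames.

A depth frame is backprojected through the pinhole intrinsics of the depth
sensor and triangulated on the pixel grid; texture coordinates come from
projecting each vertex into the laterally offset color sensor.  Because
the two sensors view the scene from slightly different angles, triangles
bridging depth discontinuities show up with a *flipped* winding in texture
space — the color sensor would be seeing their back side, which is
impossible for a real surface patch — and are removed, along with
degenerate and skinny triangles.  Finally the mesh is placed in the
canonical patient frame (+z toward the head, +x from the patient's right
to their left, origin on the camera's central viewing axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .config import MeshConfig

log = logging.getLogger(__name__)

__all__ = [
    "CameraIntrinsics",
    "TexturedSurface",
    "depth_to_mesh",
    "remove_occluded",
    "remove_degenerate_and_skinny",
    "canonicalize",
    "clean_surface",
]


@dataclass
class CameraIntrinsics:
    """Pinhole model: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def project(self, points: np.ndarray) -> np.ndarray:
        """3D camera-frame points (mm) to pixel coordinates (x, y)."""
        z = points[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            x = self.fx * points[..., 0] / z + self.cx
            y = self.fy * points[..., 1] / z + self.cy
        return np.stack([x, y], axis=-1)

    def backproject(self, px: np.ndarray, py: np.ndarray, depth: np.ndarray) -> np.ndarray:
        """Pixel coordinates plus depth (mm along the optical axis) to 3D."""
        x = (px - self.cx) / self.fx * depth
        y = (py - self.cy) / self.fy * depth
        return np.stack([x, y, depth], axis=-1)


@dataclass
class TexturedSurface:
    """Triangle mesh with texture coordinates into an RGB image.

    ``uv`` is in texture *pixel* coordinates (column, row) so the
    degenerate-triangle thresholds (area in px², edges in px) apply
    directly.  ``frame`` records whether vertices are still in the depth
    camera frame or already in the canonical patient frame.
    """

    vertices: np.ndarray                  # (N, 3) mm
    triangles: np.ndarray                 # (M, 3) int vertex indices
    uv: np.ndarray                        # (N, 2) texture pixels
    texture: np.ndarray                   # (H, W, 3) image
    kw: float = 5500.0                    # color temperature it was recorded at
    frame: str = "camera"
    view_id: int = 0

    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    def vertex_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        out = np.zeros_like(v)
        for k in range(3):
            np.add.at(out, t[:, k], fn)
        norm = np.linalg.norm(out, axis=1)
        norm[norm == 0] = 1.0
        return out / norm[:, None]

    def compact(self) -> "TexturedSurface":
        """Drop vertices not referenced by any triangle and reindex."""
        used = np.zeros(len(self.vertices), dtype=bool)
        used[self.triangles.ravel()] = True
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(used.sum())
        return replace(
            self,
            vertices=self.vertices[used],
            uv=self.uv[used],
            triangles=remap[self.triangles],
        )


def depth_to_mesh(
    depth: np.ndarray,
    mask: np.ndarray,
    intrinsics: CameraIntrinsics,
    texture: np.ndarray,
    color_intrinsics: CameraIntrinsics,
    color_offset: np.ndarray | None = None,
    kw: float = 5500.0,
    view_id: int = 0,
) -> TexturedSurface:
    """Backproject a masked depth frame and map a pre-triangulated grid onto it.

    Pixels outside the mask (or without valid depth) map to the origin and
    every grid triangle touching such a vertex is dropped.  Each quad is
    split along its top-left→bottom-right diagonal; the winding is chosen
    so triangle normals face the depth camera (⟨n, Z⟩ < 0).
    """
    if not mask.any():
        raise ValueError("empty segmentation mask")
    h, w = depth.shape
    py, px = np.mgrid[0:h, 0:w].astype(np.float64)
    pts = intrinsics.backproject(px, py, depth.astype(np.float64))
    ok = mask & (depth > 0)
    pts[~ok] = 0.0

    idx = np.arange(h * w).reshape(h, w)
    q00 = idx[:-1, :-1].ravel()
    q10 = idx[1:, :-1].ravel()
    q11 = idx[1:, 1:].ravel()
    q01 = idx[:-1, 1:].ravel()
    tris = np.concatenate(
        [np.stack([q00, q10, q11], axis=1), np.stack([q00, q11, q01], axis=1)]
    )
    flat_ok = ok.ravel()
    keep = flat_ok[tris].all(axis=1)
    tris = tris[keep]

    verts = pts.reshape(-1, 3)
    offset = np.zeros(3) if color_offset is None else np.asarray(color_offset, dtype=np.float64)
    uv = color_intrinsics.project(verts - offset[None, :])

    surf = TexturedSurface(
        vertices=verts,
        triangles=tris,
        uv=uv,
        texture=texture,
        kw=kw,
        view_id=view_id,
    )
    return surf.compact()


def _uv_signed_area(surface: TexturedSurface) -> np.ndarray:
    uv = surface.uv
    t = surface.triangles
    a = uv[t[:, 1]] - uv[t[:, 0]]
    b = uv[t[:, 2]] - uv[t[:, 0]]
    return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])


def remove_occluded(surface: TexturedSurface) -> TexturedSurface:
    """Remove triangles whose winding flips between depth and texture space.

    Valid grid triangles project with negative signed area into both the
    depth image and the texture (image y grows downward); a non-negative
    texture-space area while the 3D normal faces the depth camera marks a
    bridging triangle that no real surface patch can produce.
    """
    area = _uv_signed_area(surface)
    normals = surface.triangle_normals()
    centroids = surface.vertices[surface.triangles].mean(axis=1)
    facing = (normals * centroids).sum(axis=1) < 0  # camera at the origin
    drop = facing & (area >= 0)
    return replace(surface, triangles=surface.triangles[~drop]).compact()


def _edge_key(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lo = np.minimum(a, b).astype(np.int64)
    hi = np.maximum(a, b).astype(np.int64)
    return lo << 32 | hi


def remove_degenerate_and_skinny(
    surface: TexturedSurface, cfg: MeshConfig | None = None
) -> TexturedSurface:
    """Strip degenerate, out-of-texture and skinny triangles, then tidy up.

    Removal criteria: texture area below 0.25 px²; shortest texture edge
    below 0.5 px; texture coordinates beyond the top/bottom texture rows;
    skinny triangles (smallest angle < 13°) whose two longest edges are
    outliers (mean + 4 sd) against the edge lengths of the triangles found
    within ``max(0.9|eb|, |ea|)`` of the needle tip and the short-edge
    midpoint, with removal cascading along their long edges.  Afterwards
    duplicate vertices are merged, unreferenced vertices dropped and small
    disconnected patches discarded.
    """
    cfg = cfg or MeshConfig()
    v, t, uv = surface.vertices, surface.triangles, surface.uv

    area = np.abs(_uv_signed_area(surface))
    drop = area < cfg.min_uv_area

    uv_edges = np.stack(
        [
            np.linalg.norm(uv[t[:, 1]] - uv[t[:, 0]], axis=1),
            np.linalg.norm(uv[t[:, 2]] - uv[t[:, 1]], axis=1),
            np.linalg.norm(uv[t[:, 0]] - uv[t[:, 2]], axis=1),
        ],
        axis=1,
    )
    drop |= uv_edges.min(axis=1) < cfg.min_uv_edge

    th = surface.texture.shape[0]
    uv_y = uv[t][:, :, 1]
    drop |= (uv_y < 0).any(axis=1) | (uv_y > th - 1).any(axis=1)

    drop |= _skinny_outliers(surface, cfg)

    out = replace(surface, triangles=t[~drop]).compact()
    out = _merge_duplicate_vertices(out)
    out = _drop_small_patches(out, cfg.min_patch_triangles)
    return out


def _triangle_geometry(v: np.ndarray, t: np.ndarray):
    """Edge lengths sorted ascending, min angle, apex vertex index per triangle."""
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    # edge k is opposite vertex k
    e = np.stack(
        [
            np.linalg.norm(p2 - p1, axis=1),
            np.linalg.norm(p0 - p2, axis=1),
            np.linalg.norm(p1 - p0, axis=1),
        ],
        axis=1,
    )
    e_safe = np.where(e == 0, 1e-12, e)
    # angle at vertex k via the law of cosines
    angles = np.empty_like(e)
    for k in range(3):
        a, b, c = e_safe[:, k], e_safe[:, (k + 1) % 3], e_safe[:, (k + 2) % 3]
        cosang = np.clip((b**2 + c**2 - a**2) / (2 * b * c), -1.0, 1.0)
        angles[:, k] = np.degrees(np.arccos(cosang))
    return e, angles


def _skinny_outliers(surface: TexturedSurface, cfg: MeshConfig) -> np.ndarray:
    v, t = surface.vertices, surface.triangles
    if len(t) == 0:
        return np.zeros(0, dtype=bool)
    e, angles = _triangle_geometry(v, t)
    min_angle = angles.min(axis=1)
    skinny = np.flatnonzero(min_angle < cfg.skinny_angle_deg)
    drop = np.zeros(len(t), dtype=bool)
    if skinny.size == 0:
        return drop

    centroids = v[t].mean(axis=1)
    tree = cKDTree(centroids)
    order = np.argsort(e, axis=1)  # ea <= eb <= ec per triangle

    # Adjacency over shared undirected edges, for cascade removal.
    edge_keys = np.stack(
        [
            _edge_key(t[:, 1], t[:, 2]),
            _edge_key(t[:, 2], t[:, 0]),
            _edge_key(t[:, 0], t[:, 1]),
        ],
        axis=1,
    )
    key_to_tris: dict[int, list[int]] = {}
    for ti in range(len(t)):
        for k in range(3):
            key_to_tris.setdefault(int(edge_keys[ti, k]), []).append(ti)

    queue = list(skinny)
    visited: set[int] = set()
    while queue:
        ti = queue.pop()
        if ti in visited or drop[ti]:
            continue
        visited.add(ti)
        ia, ib, ic = order[ti]
        ea_len, eb_len, ec_len = e[ti, ia], e[ti, ib], e[ti, ic]
        # apex = small-angle vertex = vertex opposite the shortest edge
        apex = v[t[ti, ia]]
        short_mid = (v[t[ti, (ia + 1) % 3]] + v[t[ti, (ia + 2) % 3]]) / 2.0
        radius = max(0.9 * eb_len, ea_len)
        near = set(tree.query_ball_point(apex, radius)) | set(
            tree.query_ball_point(short_mid, radius)
        )
        near.discard(ti)
        if not near:
            continue
        lens = e[np.fromiter(near, dtype=np.int64)].ravel()
        limit = lens.mean() + cfg.knn_sigma_factor * lens.std()
        n_small = int((angles[ti] < cfg.skinny_angle_deg).sum())
        if ec_len > limit and eb_len > limit:
            drop[ti] = True
            # cascade along the two longest edges to adjacent skinny triangles
            for edge_idx in (ib, ic):
                for tj in key_to_tris.get(int(edge_keys[ti, edge_idx]), []):
                    if tj != ti and angles[tj].min() < cfg.skinny_angle_deg:
                        drop[tj] = True
                        queue.append(tj)
        elif ec_len > limit and n_small == 2:
            for tj in key_to_tris.get(int(edge_keys[ti, ic]), []):
                if tj != ti and angles[tj].min() < cfg.skinny_angle_deg:
                    drop[tj] = True
    return drop


def _merge_duplicate_vertices(surface: TexturedSurface) -> TexturedSurface:
    v = surface.vertices
    _, first, inverse = np.unique(
        v, axis=0, return_index=True, return_inverse=True
    )
    if len(first) == len(v):
        return surface
    tris = inverse[surface.triangles]
    # drop triangles collapsed by the merge
    ok = (
        (tris[:, 0] != tris[:, 1])
        & (tris[:, 1] != tris[:, 2])
        & (tris[:, 0] != tris[:, 2])
    )
    return replace(
        surface,
        vertices=v[first],
        uv=surface.uv[first],
        triangles=tris[ok],
    ).compact()


def _drop_small_patches(surface: TexturedSurface, min_triangles: int) -> TexturedSurface:
    t = surface.triangles
    if len(t) == 0:
        return surface
    # union-find over vertices
    parent = np.arange(len(surface.vertices))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for tri in t:
        r0 = find(tri[0])
        for other in tri[1:]:
            r = find(other)
            if r != r0:
                parent[r] = r0
    roots = np.array([find(a) for a in t[:, 0]])
    uniq, counts = np.unique(roots, return_counts=True)
    small = set(uniq[counts < min_triangles])
    if not small:
        return surface
    keep = np.array([r not in small for r in roots])
    return replace(surface, triangles=t[keep]).compact()


def clean_surface(surface: TexturedSurface, cfg: MeshConfig | None = None) -> TexturedSurface:
    """Occlusion + degeneracy cleanup in recording order."""
    return remove_degenerate_and_skinny(remove_occluded(surface), cfg)


#: Proper rotation taking depth-camera axes (X right, Y down, Z forward)
#: to the canonical patient frame (x right→left, y toward the back, z up).
CANONICAL_ROTATION = np.array(
    [
        [1.0, 0.0, 0.0],   # x = X
        [0.0, 0.0, 1.0],   # y = Z (depth)
        [0.0, -1.0, 0.0],  # z = -Y (up)
    ]
)


def shoulder_medians(
    points: np.ndarray, groups: int = 5
) -> tuple[np.ndarray, np.ndarray] | None:
    """Median points of the outer x-subgroups within the top vertical third.

    Points must be in the canonical axis orientation (z up).  Returns
    ``(right_median, left_median)`` or ``None`` when fewer than ``groups``
    subgroups are populated.
    """
    z = points[:, 2]
    z_lo = z.min() + 2.0 * (z.max() - z.min()) / 3.0
    top = points[z >= z_lo]
    if len(top) == 0:
        return None
    x = top[:, 0]
    edges = np.linspace(x.min(), x.max() + 1e-9, groups + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, groups - 1)
    if len(np.unique(idx)) < groups:
        return None
    right = np.median(top[idx == 0], axis=0)
    left = np.median(top[idx == groups - 1], axis=0)
    return right, left


def canonicalize(surface: TexturedSurface) -> TexturedSurface:
    """Place the surface in the canonical patient frame.

    Axes are permuted so +z points toward the head and +x from the
    patient's right to their left; the origin stays on the camera's central
    viewing axis, with its y-component set to the mean of the median
    y-values of the outer shoulder subgroups (5-way x-split of the top
    vertical third).  Already-canonical surfaces only refresh the origin,
    so the operation is idempotent.
    """
    if surface.frame == "camera":
        verts = surface.vertices @ CANONICAL_ROTATION.T
    else:
        verts = np.array(surface.vertices, copy=True)
    med = shoulder_medians(verts)
    if med is None:
        log.warning("canonicalize: shoulder subgroups degenerate; using bbox centre")
        y0 = (verts[:, 1].min() + verts[:, 1].max()) / 2.0
    else:
        y0 = (med[0][1] + med[1][1]) / 2.0
    verts[:, 1] -= y0
    return replace(surface, vertices=verts, frame="canonical")
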