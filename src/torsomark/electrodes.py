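"""Planar disk/ring model fitting, electrode-grid construction and labeling.

Each marker cluster is projected onto the plane of its dominant surface
normal and a circular model (red disk of radius ρ_disc inside a blue rim)
is fitted for the electrode centre.  The fitted centres are triangulated
with a two-radius ball-pivoting scheme; the two largest connected meshes
are the frontal and dorsal patches of the body-surface-mapping layout,
everything else is a single electrode (Einthoven and auxiliary leads).
Channel numbers run bottom-right to top-left on the chest and continue
top-right to bottom-left on the back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .config import GridConfig, MarkerConfig
from .markers import MarkerPointCloud

log = logging.getLogger(__name__)

__all__ = [
    "ElectrodeCluster",
    "ElectrodeMap",
    "dominant_normal",
    "fit_marker",
    "merge_split_clusters",
    "build_grid",
    "assign_labels",
]

SINGLE_LABELS = ("RA", "LA", "LL", "AUX_R_FRONT", "AUX_R_BACK")


@dataclass
class ElectrodeCluster:
    """A per-electrode marker point set with its fitted centre."""

    cloud: MarkerPointCloud
    normal: np.ndarray | None = None        # dominant surface normal
    center: np.ndarray | None = None        # fitted electrode centre X (mm)
    residual: float = float("nan")
    merged: bool = False
    fit_cloud: MarkerPointCloud | None = None  # piece used for fitting

    @property
    def n_red(self) -> int:
        return int((~self.cloud.is_blue).sum())

    @property
    def n_blue(self) -> int:
        return int(self.cloud.is_blue.sum())


@dataclass
class ElectrodeMap:
    """Labeled electrode positions in the canonical patient frame."""

    labels: list[str]
    positions: np.ndarray                 # (N, 3) mm
    normals: np.ndarray                   # (N, 3)
    patches: list[str]                    # 'frontal' | 'dorsal' | 'single'
    grid_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    unlabeled: int = 0

    def __len__(self) -> int:
        return len(self.labels)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {lbl: pos for lbl, pos in zip(self.labels, self.positions)}


def dominant_normal(normals: np.ndarray) -> np.ndarray:
    """Predominant direction of a bundle of unit normals.

    Computed as the first right singular vector of the bundle, sign-fixed
    toward the mean normal.  The singular spectrum is checked with a
    3-decade cutoff; a bundle whose mean direction nearly vanishes (two
    opposing sub-bundles) is ambiguous and raises ``ValueError``.
    """
    normals = np.asarray(normals, dtype=np.float64)
    if len(normals) < 3:
        raise ValueError("need at least 3 normals")
    norms = np.linalg.norm(normals, axis=1)
    if np.all(norms == 0):
        raise ValueError("all-zero normal bundle")
    _, s, vt = np.linalg.svd(normals, full_matrices=False)
    mean = normals.mean(axis=0)
    if np.linalg.norm(mean) < 0.1:
        raise ValueError("ambiguous normal bundle (opposing directions)")
    rank = int((s > s[0] * 1e-3).sum())  # directions within 3 decades
    n = vt[0]
    if rank > 1 and s[1] / s[0] > 0.99:
        log.debug("dominant_normal: nearly isotropic bundle")
    if np.dot(n, mean) < 0:
        n = -n
    return n / np.linalg.norm(n)


def fit_marker(
    cluster: ElectrodeCluster, cfg: MarkerConfig | None = None
) -> ElectrodeCluster | None:
    """Fit the planar disk/ring model to one cluster.

    Points are projected onto the plane through the cluster centroid with
    the dominant normal; the objective penalizes blue points for deviating
    from the disk radius, red points for lying outside the disk, and the
    centre for leaving the plane.  Minimized over X with L-BFGS-B from the
    centroid.  Returns ``None`` when the cluster lacks one color, is
    degenerate, or the optimizer fails (such clusters are dropped).
    """
    cfg = cfg or MarkerConfig()
    cloud = cluster.fit_cloud if cluster.fit_cloud is not None else cluster.cloud
    if not (len(cloud) >= 3 and cloud.is_blue.any() and (~cloud.is_blue).any()):
        return None
    try:
        n = dominant_normal(cloud.normals)
    except ValueError:
        return None
    pts = cloud.points
    centroid = pts.mean(axis=0)
    if np.allclose(pts, pts[0]):
        return None
    proj = pts - ((pts - centroid) @ n)[:, None] * n[None, :]
    blue = cloud.is_blue
    p_blue = proj[blue]
    p_red = proj[~blue]
    rho = cfg.disk_radius

    def objective(x):
        db = np.linalg.norm(p_blue - x, axis=1) - rho
        dr = np.linalg.norm(p_red - x, axis=1) - rho
        dr = np.maximum(dr, 0.0)
        off = float(np.dot(x - centroid, n))
        return float((db**2).sum() + (dr**2).sum() + off**2)

    span = 4.0 * cfg.head_radius
    bounds = [(c - span, c + span) for c in centroid]
    res = minimize(objective, centroid, method="L-BFGS-B", bounds=bounds)
    if not res.success or not np.isfinite(res.fun):
        return None
    cluster.normal = n
    cluster.center = np.asarray(res.x)
    cluster.residual = float(res.fun)
    return cluster


def merge_split_clusters(
    clusters: list[ElectrodeCluster], cfg: GridConfig | None = None
) -> list[ElectrodeCluster]:
    """Rejoin markers that were split (e.g. by a cable shadow) into two clusters.

    Clusters whose red/blue count ratio leaves (1/3, 3) are split
    candidates.  Two candidates are pieces of the same marker when at
    least 10 points of each have their nearest out-of-cluster neighbour in
    the other (mutually).  The merged cluster keeps all points but the
    model is fitted to the largest piece only.
    """
    cfg = cfg or GridConfig()
    if len(clusters) < 2:
        return clusters

    def is_candidate(cl: ElectrodeCluster) -> bool:
        if cl.n_blue == 0 or cl.n_red == 0:
            return True
        ratio = cl.n_red / cl.n_blue
        return not (1.0 / 3.0 < ratio < 3.0)

    cand = {i for i, cl in enumerate(clusters) if is_candidate(cl)}
    if not cand:
        return clusters

    all_pts = np.concatenate([clusters[i].cloud.points for i in range(len(clusters))])
    owner = np.concatenate(
        [np.full(len(clusters[i].cloud), i) for i in range(len(clusters))]
    )
    tree = cKDTree(all_pts)

    def votes(i: int, j: int) -> int:
        pts = clusters[i].cloud.points
        # nearest neighbour outside cluster i for every point of i
        k = min(len(all_pts), 40)
        d, idx = tree.query(pts, k=k)
        count = 0
        for row in idx:
            outside = row[owner[row] != i]
            if len(outside) and owner[outside[0]] == j:
                count += 1
        return count

    from .config import MarkerConfig

    head_d = 2.0 * MarkerConfig().head_radius
    merged_away: set[int] = set()
    out: list[ElectrodeCluster] = []
    # a shadow split often leaves one balanced piece and one skewed one,
    # so a pair qualifies when either member is a candidate
    for i, j in combinations(range(len(clusters)), 2):
        if i not in cand and j not in cand:
            continue
        if i in merged_away or j in merged_away:
            continue
        # pieces of one clip head sit within a head diameter of each other;
        # genuinely distinct neighbouring markers are a grid pitch apart
        ci = clusters[i].cloud.points.mean(axis=0)
        cj = clusters[j].cloud.points.mean(axis=0)
        if np.linalg.norm(ci - cj) > head_d:
            continue
        if votes(i, j) >= cfg.min_split_neighbors and votes(j, i) >= cfg.min_split_neighbors:
            big, small = (i, j) if len(clusters[i].cloud) >= len(clusters[j].cloud) else (j, i)
            union = MarkerPointCloud.concatenate(
                [clusters[i].cloud, clusters[j].cloud]
            )
            out.append(
                ElectrodeCluster(
                    cloud=union, merged=True, fit_cloud=clusters[big].cloud
                )
            )
            merged_away.update((i, j))
    for i, cl in enumerate(clusters):
        if i not in merged_away:
            out.append(cl)
    return out


def _mean_knn_distance(centers: np.ndarray, k: int) -> np.ndarray:
    kk = min(k + 1, len(centers))
    d, _ = cKDTree(centers).query(centers, k=kk)
    return d[:, 1:].mean(axis=1)


def _ball_pivot_triangles(centers: np.ndarray, radii: list[float]) -> np.ndarray:
    """Empty-ball triangulation of a centre set.

    A triple forms a triangle when its circumradius fits one of the
    pivoting-ball radii and the ball of that radius resting on the three
    points (on at least one side) contains no other centre — the surface a
    pivoting ball of that radius would reach.
    """
    n = len(centers)
    tree = cKDTree(centers)
    tris: set[tuple[int, int, int]] = set()
    rho_max = max(radii)
    pairs = tree.query_pairs(2.0 * rho_max, output_type="ndarray")
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in pairs:
        neigh[int(a)].add(int(b))
        neigh[int(b)].add(int(a))
    for i in range(n):
        for j, k in combinations(sorted(neigh[i] & set(range(i + 1, n))), 2):
            if k not in neigh[j]:
                continue
            tri = (i, j, k)
            a, b, c = centers[i], centers[j], centers[k]
            ab, ac, bc = b - a, c - a, c - b
            cross = np.cross(ab, ac)
            area2 = np.linalg.norm(cross)
            if area2 < 1e-9:
                continue
            la, lb, lc_ = np.linalg.norm(bc), np.linalg.norm(ac), np.linalg.norm(ab)
            circum_r = la * lb * lc_ / (2.0 * area2)
            # circumcentre via barycentric weights
            alpha = la**2 * np.dot(ab, ac)
            beta = lb**2 * np.dot(-ab, bc)
            gamma = lc_**2 * np.dot(-ac, -bc)
            ssum = alpha + beta + gamma
            if abs(ssum) < 1e-12:
                continue
            cc = (alpha * a + beta * b + gamma * c) / ssum
            n_hat = cross / area2
            for rho in radii:
                if circum_r > rho:
                    continue
                h = np.sqrt(max(rho**2 - circum_r**2, 0.0))
                accepted = False
                for sgn in (1.0, -1.0):
                    ball_c = cc + sgn * h * n_hat
                    idx = tree.query_ball_point(ball_c, rho * (1.0 - 1e-9))
                    if all(m in tri for m in idx):
                        accepted = True
                        break
                if accepted:
                    tris.add(tri)
                    break
    if not tris:
        return np.empty((0, 3), dtype=np.int64)
    return np.array(sorted(tris), dtype=np.int64)


def _normalize_grid_edges(centers: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Swap vertical edges that cross the horizontal connector of their quad."""
    tris = tris.copy()
    changed = True
    guard = 0
    while changed and guard < 10:
        changed = False
        guard += 1
        edge_map: dict[tuple[int, int], list[int]] = {}
        for ti, tri in enumerate(tris):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = tuple(sorted((tri[a], tri[b])))
                edge_map.setdefault(key, []).append(ti)
        for (a, b), owners in edge_map.items():
            if len(owners) != 2:
                continue
            t1, t2 = owners
            others = [v for v in tris[t1] if v not in (a, b)] + [
                v for v in tris[t2] if v not in (a, b)
            ]
            if len(others) != 2 or others[0] == others[1]:
                continue
            c, d = others
            pa, pb, pc, pd = centers[[a, b, c, d]]
            ab = pb - pa
            cd = pd - pc
            if abs(ab[2]) <= abs(ab[0]):
                continue  # not a vertical edge
            # do segments ab and cd intersect in the x-z plane?
            def side(p, q, r):
                return (q[0] - p[0]) * (r[2] - p[2]) - (q[2] - p[2]) * (r[0] - p[0])

            if side(pa, pb, pc) * side(pa, pb, pd) < 0 and side(pc, pd, pa) * side(
                pc, pd, pb
            ) < 0:
                tris[t1] = [c, d, a]
                tris[t2] = [c, d, b]
                changed = True
                break
    return tris


@dataclass
class GridResult:
    centers: np.ndarray
    cluster_sizes: np.ndarray
    triangles: np.ndarray
    patch_of: np.ndarray       # per-centre component label, -1 = single
    frontal: np.ndarray        # centre indices
    dorsal: np.ndarray
    singles: np.ndarray
    kept: np.ndarray           # indices into the input cluster list


def build_grid(
    clusters: list[ElectrodeCluster],
    cfg: GridConfig | None = None,
    markers_cfg: MarkerConfig | None = None,
) -> GridResult:
    """Triangulate fitted centres into frontal/dorsal patches plus singles.

    Outlier centres (mean 9-NN distance beyond mean + 2 sd) are removed,
    the rest triangulated by ball pivoting with radii x̄/2 and x̄ from the
    mean 9-NN spacing; centres closer than the merge distance collapse
    onto the larger cluster, iteratively.  The two largest connected
    meshes become the frontal (smaller mean y) and dorsal patches; the
    grid is normalized by diagonal edge swaps.
    """
    cfg = cfg or GridConfig()
    markers_cfg = markers_cfg or MarkerConfig()
    fitted = [
        (i, cl) for i, cl in enumerate(clusters) if cl.center is not None
    ]
    if len(fitted) < 4:
        raise ValueError("need at least 4 fitted centres")
    kept = np.array([i for i, _ in fitted])
    centers = np.array([cl.center for _, cl in fitted])
    sizes = np.array([len(cl.cloud) for _, cl in fitted])

    merge_dist = cfg.merge_factor * markers_cfg.head_radius
    while True:
        # outliers (far-off centres) are excluded from the spacing estimate
        # only; they stay in the set and end up as single electrodes
        d9 = _mean_knn_distance(centers, cfg.neighbors)
        inlier = d9 <= d9.mean() + cfg.outlier_sigma * d9.std()
        xbar = float(d9[inlier].mean()) if inlier.any() else float(d9.mean())
        tris = _ball_pivot_triangles(centers, [xbar / 2.0, xbar])
        close = cKDTree(centers).query_pairs(merge_dist, output_type="ndarray")
        if len(close) == 0:
            break
        a, b = close[0]
        drop = a if sizes[a] < sizes[b] else b
        keep_mask = np.ones(len(centers), dtype=bool)
        keep_mask[drop] = False
        centers, sizes, kept = centers[keep_mask], sizes[keep_mask], kept[keep_mask]

    # connected components over triangulation
    patch_of = -np.ones(len(centers), dtype=np.int64)
    parent = np.arange(len(centers))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for tri in tris:
        r = find(tri[0])
        for v in tri[1:]:
            rv = find(v)
            if rv != r:
                parent[rv] = r
    in_mesh = np.zeros(len(centers), dtype=bool)
    in_mesh[np.unique(tris)] = True
    roots = np.array([find(i) if in_mesh[i] else -1 for i in range(len(centers))])
    comp_ids, counts = np.unique(roots[roots >= 0], return_counts=True)
    order = np.argsort(-counts)
    frontal = dorsal = np.empty(0, dtype=np.int64)
    if len(comp_ids) >= 2:
        c1, c2 = comp_ids[order[0]], comp_ids[order[1]]
        g1 = np.flatnonzero(roots == c1)
        g2 = np.flatnonzero(roots == c2)
        if centers[g1][:, 1].mean() <= centers[g2][:, 1].mean():
            frontal, dorsal = g1, g2
        else:
            frontal, dorsal = g2, g1
        patch_of[frontal] = 0
        patch_of[dorsal] = 1
    elif len(comp_ids) == 1:
        log.warning("build_grid: only one connected patch found")
        frontal = np.flatnonzero(roots == comp_ids[0])
        patch_of[frontal] = 0
    singles = np.flatnonzero(patch_of < 0)

    tris = _normalize_grid_edges(centers, tris)
    return GridResult(
        centers=centers,
        cluster_sizes=sizes,
        triangles=tris,
        patch_of=patch_of,
        frontal=frontal,
        dorsal=dorsal,
        singles=singles,
        kept=kept,
    )


def _rows_from_edges(
    centers: np.ndarray, members: np.ndarray, tris: np.ndarray
) -> list[list[int]]:
    """Group patch members into rows connected by consecutive horizontal edges."""
    member_set = set(int(m) for m in members)
    parent = {int(m): int(m) for m in members}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # vertical grid pitch from the vertical-ish triangulation edges; a row
    # edge must stay within half a pitch in z so diagonals never merge rows
    dz_vert = []
    edges = set()
    for tri in tris:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            u, v = int(tri[a]), int(tri[b])
            if u in member_set and v in member_set:
                edges.add((u, v))
                dvec = centers[v] - centers[u]
                if abs(dvec[2]) >= abs(dvec[0]):
                    dz_vert.append(abs(dvec[2]))
    pitch = float(np.median(dz_vert)) if dz_vert else np.inf
    for u, v in edges:
        dvec = centers[v] - centers[u]
        horizontal = abs(dvec[2]) < abs(dvec[0]) and (
            not np.isfinite(pitch) or abs(dvec[2]) <= 0.5 * pitch
        )
        if horizontal:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru
    rows: dict[int, list[int]] = {}
    for m in member_set:
        rows.setdefault(find(m), []).append(m)
    out = [sorted(r, key=lambda i: centers[i, 0]) for r in rows.values()]
    out.sort(key=lambda r: float(np.mean(centers[r, 2])))
    return out


def assign_labels(
    grid: GridResult,
    normals: np.ndarray | None = None,
) -> ElectrodeMap:
    """Assign ECG channel labels to the gridded electrode centres.

    Frontal rows run bottom→top and right→left with ascending channel
    numbers; dorsal numbering continues, starting at the top right and
    ending at the bottom left.  Singles become the Einthoven leads (right
    shoulder RA, left shoulder LA, left hip LL) and the two right-side
    auxiliary electrodes (front/back by their y-coordinate).
    """
    centers = grid.centers
    if normals is None:
        normals = np.tile(np.array([0.0, -1.0, 0.0]), (len(centers), 1))
    labels: list[str] = [""] * len(centers)
    patches: list[str] = ["single"] * len(centers)
    channel = 1
    unlabeled = 0

    rows_f = _rows_from_edges(centers, grid.frontal, grid.triangles)
    for row in rows_f:  # bottom→top, right→left (x ascending)
        for i in row:
            labels[i] = str(channel)
            patches[i] = "frontal"
            channel += 1
    rows_d = _rows_from_edges(centers, grid.dorsal, grid.triangles)
    for row in reversed(rows_d):  # top→bottom
        for i in row:
            labels[i] = str(channel)
            patches[i] = "dorsal"
            channel += 1

    singles = list(grid.singles)
    if singles:
        z = centers[:, 2]
        z_mid = (z.min() + z.max()) / 2.0
        remaining = set(singles)

        def take(key, pool):
            if not pool:
                return None
            best = min(pool, key=key)
            remaining.discard(best)
            return best

        x_mid = float(np.median(centers[:, 0]))
        ll = take(lambda i: centers[i, 2], list(remaining))
        upper = [i for i in remaining if centers[i, 2] > z_mid and centers[i, 0] < x_mid]
        ra = take(lambda i: centers[i, 0], upper)
        upper = [i for i in remaining if centers[i, 2] > z_mid and centers[i, 0] > x_mid]
        la = take(lambda i: -centers[i, 0], upper)
        for idx, name in ((ra, "RA"), (la, "LA"), (ll, "LL")):
            if idx is not None:
                labels[idx] = name
        rest = sorted(remaining, key=lambda i: centers[i, 1])
        if len(rest) >= 1:
            labels[rest[0]] = "AUX_R_FRONT"
        if len(rest) >= 2:
            labels[rest[1]] = "AUX_R_BACK"
        for i in rest[2:]:
            labels[i] = f"UNKNOWN_{i}"
            unlabeled += 1

    edges = set()
    for tri in grid.triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edges.add(tuple(sorted((int(tri[a]), int(tri[b])))))
    return ElectrodeMap(
        labels=labels,
        positions=centers,
        normals=np.asarray(normals),
        patches=patches,
        grid_edges=np.array(sorted(edges), dtype=np.int64)
        if edges
        else np.empty((0, 2), int),
        unlabeled=unlabeled,
    )
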