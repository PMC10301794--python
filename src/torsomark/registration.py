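"""Pairwise symmetric point-to-plane ICP and global chaining of views.

Each recorded view is registered onto its predecessor.  One *run* of the
symmetric scheme performs a forward point-to-plane ICP (source onto
target), then a reverse one (target onto source, initialized with the
inverse of the forward result), and accepts whichever candidate lowers
both the alignment error and the correspondence distance; the accepted
correspondence distance ``l_c ← l̄ + 2σ_l`` shrinks from run to run, from
several centimetres down to about a millimetre.  The initial guess comes
from the relative shoulder-axis rotation about z and the centroid shift
inside the overlap of the two bounding boxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import RegistrationConfig
from .meshing import TexturedSurface, shoulder_medians

log = logging.getLogger(__name__)

__all__ = [
    "RegistrationFailure",
    "RegistrationResult",
    "PairInit",
    "init_pair",
    "symmetric_icp",
    "register_pair",
    "chain_global",
]


class RegistrationFailure(RuntimeError):
    """The surface pair could not be registered (e.g. no overlap)."""


@dataclass
class RegistrationResult:
    transform: np.ndarray      # 4x4, maps source into the target frame
    lc: float                  # final correspondence distance (mm)
    rmse: float                # rms Euclidean correspondence distance (mm)
    runs: int                  # symmetric runs used
    iterations: int            # total inner ICP iterations
    lc_initial: float = 0.0
    converged: bool = True


@dataclass
class PairInit:
    transform: np.ndarray
    lc_max: float
    lc_min: float
    sigma_l0: float


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    t = np.eye(4)
    t[:2, :2] = [[c, -s], [s, c]]
    return t


def transform_points(t: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return pts @ t[:3, :3].T + t[:3, 3]


def _cloud(surface, max_points: int, rng: np.random.Generator):
    """Subsampled (points, normals) from a surface or a (points, normals) pair."""
    if isinstance(surface, TexturedSurface):
        pts, nrm = _trimmed_vertices(surface)
    else:
        pts, nrm = surface
    if len(pts) > max_points:
        sel = rng.choice(len(pts), size=max_points, replace=False)
        pts, nrm = pts[sel], nrm[sel]
    return np.ascontiguousarray(pts, dtype=np.float64), np.ascontiguousarray(
        nrm, dtype=np.float64
    )


def init_pair(
    target,
    source,
    cfg: RegistrationConfig | None = None,
) -> PairInit:
    """Initial transform and correspondence-distance schedule for a pair.

    The relative rotation about z comes from the angle between the
    shoulder axes (right-to-left median-point vectors) of the two
    surfaces; the translation aligns the centroids of the points inside
    the intersection of the axis-aligned bounding boxes.  ``lc_max`` is
    ``l̄ + 2σ`` over normal-compatible forward/backward nearest-neighbour
    distances inside that overlap, ``lc_min`` the mean nearest-neighbour
    spacing, and ``σ_l0`` the spread of the initial correspondences.
    """
    cfg = cfg or RegistrationConfig()
    # independent deterministic subsamples (identical surfaces subsample
    # identically, so self-registration is exact)
    pt, nt = _cloud(target, cfg.max_points, np.random.default_rng(0))
    ps, ns = _cloud(source, cfg.max_points, np.random.default_rng(0))

    # relative shoulder-axis rotation about z
    mt = shoulder_medians(pt)
    ms = shoulder_medians(ps)
    t0 = np.eye(4)
    if mt is not None and ms is not None:
        ht = (mt[1] - mt[0])[:2]
        hs = (ms[1] - ms[0])[:2]
        denom = np.linalg.norm(ht) * np.linalg.norm(hs)
        if denom > 0:
            cosang = np.clip(np.dot(hs, ht) / denom, -1.0, 1.0)
            dphi = np.arccos(cosang)
            if hs[0] * ht[1] - hs[1] * ht[0] < 0:
                dphi = -dphi
            t0 = _rot_z(dphi)

    ps_r = transform_points(t0, ps)
    lo = np.maximum(pt.min(axis=0), ps_r.min(axis=0))
    hi = np.minimum(pt.max(axis=0), ps_r.max(axis=0))
    in_t = np.all((pt >= lo) & (pt <= hi), axis=1)
    in_s = np.all((ps_r >= lo) & (ps_r <= hi), axis=1)
    if not (in_t.any() and in_s.any()):
        raise RegistrationFailure("bounding boxes of the pair do not overlap")
    shift = pt[in_t].mean(axis=0) - ps_r[in_s].mean(axis=0)
    t0 = np.block(
        [[np.eye(3), shift[:, None]], [np.zeros((1, 3)), np.ones((1, 1))]]
    ) @ t0

    ps_r = transform_points(t0, ps)
    ns_r = ns @ t0[:3, :3].T
    cos_lim = np.cos(np.radians(cfg.normal_max_angle_deg))

    def compatible_dists(a, na, b, nb, sel_a):
        tree = cKDTree(b)
        d, j = tree.query(a[sel_a], k=1)
        dots = (na[sel_a] * nb[j]).sum(axis=1)
        return d[dots >= cos_lim]

    df = compatible_dists(pt, nt, ps_r, ns_r, in_t)
    db = compatible_dists(ps_r, ns_r, pt, nt, in_s)
    dists = np.concatenate([df, db])
    if dists.size == 0:
        raise RegistrationFailure("no normal-compatible correspondences")
    sigma_l0 = float(dists.std())

    nn_t = cKDTree(pt).query(pt, k=2)[0][:, 1]
    nn_s = cKDTree(ps).query(ps, k=2)[0][:, 1]
    lc_min = float(np.concatenate([nn_t, nn_s]).mean())
    # already-aligned pairs would yield a vanishing schedule start
    lc_max = max(float(dists.mean() + 2.0 * dists.std()), lc_min, cfg.l_min)
    return PairInit(transform=t0, lc_max=lc_max, lc_min=lc_min, sigma_l0=sigma_l0)


def _trimmed_vertices(surface: TexturedSurface, rings: int = 3,
                      min_axis_cos: float = 0.26):
    """Vertices away from the mesh border and not seen at grazing angles.

    Border vertices of a depth-camera mesh carry ragged geometry and
    one-sided normals; on partially overlapping scans, points beyond the
    other view's coverage would snap to that rim and drag the fit
    sideways.  The border ring is eroded ``rings`` triangle-neighbourhood
    steps; vertices whose normal is nearly perpendicular to the viewing
    axis (canonical +y) are dropped as well.
    """
    tris = surface.triangles
    n_v = len(surface.vertices)
    edges = np.sort(
        np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    excl = np.zeros(n_v, dtype=bool)
    excl[uniq[counts == 1].ravel()] = True
    for _ in range(rings):
        tri_excl = excl[tris].any(axis=1)
        excl[np.unique(tris[tri_excl])] = True
    normals = surface.vertex_normals()
    grazing = np.abs(normals[:, 1]) < min_axis_cos
    keep = ~excl & ~grazing
    if keep.sum() < 100:  # degenerate mesh: fall back to everything
        keep = np.ones(n_v, dtype=bool)
    return surface.vertices[keep], normals[keep]


def _point_to_plane_run(
    tree: cKDTree,
    pt: np.ndarray,
    nt: np.ndarray,
    ps: np.ndarray,
    t_init: np.ndarray,
    lc: float,
    cfg: RegistrationConfig,
):
    """One unidirectional point-to-plane ICP run (Gauss–Newton).

    Returns ``(transform, mean_sq_plane_error, l_mean, l_std, rmse,
    iterations)``; correspondence statistics come from the final iteration.
    """
    t = np.array(t_init, copy=True)
    prev_err = np.inf
    stats = (np.inf, np.inf, np.inf, np.inf)
    iterations = 0
    for iterations in range(1, cfg.max_inner_iterations + 1):
        p = transform_points(t, ps)
        d, j = tree.query(p, k=1, distance_upper_bound=lc)
        ok = np.isfinite(d)
        if ok.sum() < 6:
            return t, np.inf, np.inf, np.inf, np.inf, iterations
        p_ok = p[ok]
        q = pt[j[ok]]
        n = nt[j[ok]]
        r = ((p_ok - q) * n).sum(axis=1)
        err = float((r**2).mean())
        l = np.linalg.norm(p_ok - q, axis=1)
        stats = (err, float(l.mean()), float(l.std()), float(np.sqrt((l**2).mean())))
        if np.isfinite(prev_err) and abs(prev_err - err) <= cfg.fitness_tol * max(
            prev_err, 1e-12
        ):
            break
        prev_err = err
        jac = np.hstack([np.cross(p_ok, n), n])  # d r / d (omega, t)
        h = jac.T @ jac
        g = jac.T @ r
        try:
            delta = np.linalg.solve(h + 1e-9 * np.eye(6), -g)
        except np.linalg.LinAlgError:
            break
        omega, trans = delta[:3], delta[3:]
        angle = np.linalg.norm(omega)
        if angle > 0:
            axis = omega / angle
            k = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        else:
            rot = np.eye(3)
        upd = np.eye(4)
        upd[:3, :3] = rot
        upd[:3, 3] = trans
        t = upd @ t
    return t, stats[0], stats[1], stats[2], stats[3], iterations


def _invert(t: np.ndarray) -> np.ndarray:
    out = np.eye(4)
    r = t[:3, :3].T
    out[:3, :3] = r
    out[:3, 3] = -r @ t[:3, 3]
    return out


def symmetric_icp(
    target,
    source,
    init: PairInit | None = None,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Symmetric point-to-plane registration of ``source`` onto ``target``.

    Repeats forward/reverse run pairs, accepting a candidate only when it
    lowers both the point-to-plane error and the shrinking correspondence
    distance; when the acceptance test first fails while the distance is
    still above ``l_min`` but was recently improving by more than the
    initial correspondence spread, one last run at ``l_min ≈ 1 mm`` is
    attempted.  Three consecutive error increases abort with the best
    result so far.
    """
    cfg = cfg or RegistrationConfig()
    if init is None:
        init = init_pair(target, source, cfg)
    pt, nt = _cloud(target, cfg.max_points, np.random.default_rng(0))
    ps, ns = _cloud(source, cfg.max_points, np.random.default_rng(0))
    tree_t = cKDTree(pt)
    tree_s = cKDTree(ps)

    t_cur = init.transform
    lc = init.lc_max
    e_cur = np.inf
    rmse = np.inf
    total_iters = 0
    runs = 0
    increases = 0
    converged = True
    final_attempted = False
    last_reduction = np.inf
    while runs < cfg.max_runs:
        runs += 1
        t_f, e_f, lm_f, ls_f, rmse_f, it_f = _point_to_plane_run(
            tree_t, pt, nt, ps, t_cur, lc, cfg
        )
        lc_f = lm_f + 2.0 * ls_f
        t_r_raw, e_r, lm_r, ls_r, rmse_r, it_r = _point_to_plane_run(
            tree_s, ps, ns, pt, _invert(t_f), lc, cfg
        )
        lc_r = lm_r + 2.0 * ls_r
        t_r = _invert(t_r_raw)
        total_iters += it_f + it_r

        # Candidates must shrink the correspondence distance; among those,
        # the lower point-to-plane error wins (errors at different lc are
        # not comparable across runs, so lc carries the progress test).
        feasible = []
        if np.isfinite(e_r) and lc_r < lc:
            feasible.append((e_r, lc_r, t_r, rmse_r))
        if np.isfinite(e_f) and lc_f < lc:
            feasible.append((e_f, lc_f, t_f, rmse_f))
        if feasible:
            e_new, lc_new, t_new, rmse_new = min(feasible, key=lambda c: (c[0], c[1]))
            if e_cur < np.inf and e_new > e_cur:
                increases += 1
                if increases >= 3:
                    log.warning(
                        "symmetric_icp: error increased 3 times; best so far kept"
                    )
                    converged = False
                    if not final_attempted and lc > cfg.l_min:
                        final_attempted = True
                        lc = cfg.l_min
                        increases = 0
                        continue
                    break
            else:
                increases = 0
            t_cur, e_cur, rmse = t_new, e_new, rmse_new
            last_reduction = lc - lc_new
            lc = lc_new
        else:
            if (
                not final_attempted
                and lc > cfg.l_min
                and init.lc_max - lc > init.sigma_l0
            ):
                # the schedule stalled above l_min after real progress:
                # one last run at the optimal correspondence distance
                final_attempted = True
                lc = cfg.l_min
                continue
            break
        if lc <= cfg.l_min:
            break
    # score the final alignment at the final correspondence distance
    p = transform_points(t_cur, ps)
    d, _ = tree_t.query(p, k=1, distance_upper_bound=max(lc, cfg.l_min))
    d = d[np.isfinite(d)]
    if d.size:
        rmse = float(np.sqrt((d**2).mean()))
    return RegistrationResult(
        transform=t_cur,
        lc=float(lc),
        rmse=float(rmse),
        runs=runs,
        iterations=total_iters,
        lc_initial=float(init.lc_max),
        converged=converged,
    )


def register_pair(target, source, cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Initialize and run the symmetric ICP for one surface pair.

    The shoulder-axis rotation estimate is coarse (median points of
    partial arcs are biased), and electrode clips form a near-regular
    bump lattice on the skin, so a single bad seed can lock onto a
    lattice-shifted false minimum.  A small fan of yaw offsets around the
    estimate is therefore scored with one short coarse run each, and the
    full symmetric schedule starts from the best seed.
    """
    cfg = cfg or RegistrationConfig()
    init = init_pair(target, source, cfg)
    pt, nt = _cloud(target, cfg.max_points, np.random.default_rng(0))
    ps, _ = _cloud(source, cfg.max_points, np.random.default_rng(0))
    tree_t = cKDTree(pt)
    coarse = RegistrationConfig(**{**cfg.__dict__, "max_inner_iterations": 15})
    best = None
    for yaw_deg in (0.0, -8.0, 8.0, -16.0, 16.0, -24.0, 24.0):
        t0 = _rot_z(np.radians(yaw_deg)) @ init.transform
        _, e, lm, ls, _, _ = _point_to_plane_run(
            tree_t, pt, nt, ps, t0, init.lc_max, coarse
        )
        if np.isfinite(e) and (best is None or e < best[0]):
            best = (e, t0)
    if best is not None:
        init = PairInit(best[1], init.lc_max, init.lc_min, init.sigma_l0)
    return symmetric_icp(target, source, init, cfg)


def chain_global(results: list[RegistrationResult | None]) -> list[np.ndarray | None]:
    """Cumulative global transforms from consecutive pairwise results.

    ``results[i]`` registers view ``i+1`` onto view ``i``; the first view
    gets the identity.  A failed pair (``None``) breaks the chain: all
    downstream views are flagged unaligned (``None``).
    """
    transforms: list[np.ndarray | None] = [np.eye(4)]
    broken = False
    for res in results:
        if broken or res is None:
            transforms.append(None)
            broken = True
            continue
        transforms.append(transforms[-1] @ res.transform)
    return transforms
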