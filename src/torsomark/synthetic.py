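"""Ground-truth torso scenes for exercising the pipeline without hardware.

The torso is an elliptic cylinder (semi-axes ``rx`` across the chest,
``ry`` front-to-back) standing on z ∈ [0, height], carrying circular
electrode markers — a red disk inside a blue rim on a clip head that
protrudes a few millimetres from the skin.  A surrounding circular room
wall provides the neutral gray background the white-balance controller
relies on.  Views are ray-cast analytically: a 16-bit depth image from
the depth sensor position and an 8-bit gamma-compressed color image from
a laterally offset color sensor (so occlusion removal has something to
chew on), with per-view illumination color casts applied through the
sensor gain model, Gaussian depth noise, and millimetre quantization.

The default scene mirrors the recording conditions the pipeline targets:
14 views spanning about 270° around the torso, 67 electrodes (a 32-pad
frontal patch, a 30-pad dorsal patch, three Einthoven leads and two
right-side auxiliaries), 1 mm depth noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import color as color_mod
from .config import MarkerConfig, PipelineConfig
from .meshing import CameraIntrinsics
from .white_balance import apply_cast

log = logging.getLogger(__name__)

__all__ = [
    "MarkerSite",
    "TorsoModel",
    "ViewFrame",
    "Scene",
    "make_torso",
    "default_poses",
    "render_view",
    "render_views",
    "simulate_scene",
]

# Linear RGB albedos; chromaticities chosen to sit inside (markers) or
# outside (skin) the calibration ellipses after neutral correction.
SKIN_ALBEDO = (0.45, 0.30, 0.25)
RED_ALBEDO = (0.52, 0.075, 0.10)
BLUE_ALBEDO = (0.028, 0.07, 0.46)
WALL_CHROMA = (0.363, 0.338, 0.299)   # neutral gamut point at 5500 K
WALL_INTENSITY = 1.35                 # of max 3
WALL_CHROMA_NOISE = 0.005             # per-pixel gray-surface variation
GRAZING_COS = 0.18                    # rays flatter than ~80° return no depth


@dataclass
class MarkerSite:
    """One electrode marker on the torso surface."""

    label: str
    theta: float        # azimuth on the elliptic cross-section (rad, 0 = front)
    z: float            # height (mm)
    patch: str          # 'frontal' | 'dorsal' | 'single'


#: Smooth anatomical relief: radial offsets (mm) as Gaussian blobs in
#: (azimuth, height) — spine groove, scapulae, pectorals, belly, waist.
#: A real torso is far from a smooth cylinder; this relief is also what
#: makes pairwise surface registration well-posed, exactly as anatomy does
#: on a real patient.
def _anatomy_relief() -> tuple[tuple[float, float, float, float, float], ...]:
    """Radial relief of the standard synthetic subject.

    Large named features (spine groove, scapulae, pectorals, belly, waist)
    plus a fixed pseudo-random field of centimetre-scale blobs standing in
    for ribs and musculature.  The fine field matters beyond looks: smooth
    convex side surfaces would let consecutive views slide tangentially
    within the depth noise, which real anatomy prevents.
    """
    blobs = [
        # (amplitude mm, theta0 deg, z0 mm, sigma_theta deg, sigma_z mm)
        (-7.0, 180.0, 350.0, 12.0, 250.0),   # spine groove
        (9.0, 150.0, 460.0, 20.0, 70.0),     # left scapula
        (9.0, 210.0, 460.0, 20.0, 70.0),     # right scapula
        (7.0, 25.0, 440.0, 18.0, 80.0),      # left pectoral
        (7.0, -25.0, 440.0, 18.0, 80.0),     # right pectoral
        (10.0, 0.0, 180.0, 45.0, 110.0),     # belly
        (-6.0, 90.0, 260.0, 25.0, 90.0),     # left waist
        (-6.0, -90.0, 260.0, 25.0, 90.0),    # right waist
    ]
    rng = np.random.default_rng(42)  # the subject's fixed anatomy
    for _ in range(24):
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0)
        blobs.append(
            (
                float(amp),
                float(rng.uniform(-180.0, 180.0)),
                float(rng.uniform(60.0, 540.0)),
                float(rng.uniform(8.0, 15.0)),
                float(rng.uniform(30.0, 60.0)),
            )
        )
    return tuple(blobs)


DEFAULT_RELIEF = _anatomy_relief()


@dataclass
class TorsoModel:
    rx: float = 160.0           # mm, half-width (x)
    ry: float = 110.0           # mm, half-depth (y)
    height: float = 600.0       # mm
    bump: float = 3.0           # mm, clip-head protrusion
    markers: list[MarkerSite] = field(default_factory=list)
    marker_cfg: MarkerConfig = field(default_factory=MarkerConfig)
    relief: tuple = DEFAULT_RELIEF

    def relief_height(self, theta, z):
        """Radial surface offset (mm) at azimuth/height, periodic in theta."""
        theta = np.asarray(theta, dtype=np.float64)
        z = np.asarray(z, dtype=np.float64)
        shape = np.broadcast(theta, z).shape
        theta = np.broadcast_to(theta, shape).reshape(-1, 1)
        z = np.broadcast_to(z, shape).reshape(-1, 1)
        params = np.asarray(self.relief, dtype=np.float64)
        amp = params[:, 0]
        t0 = np.radians(params[:, 1])
        z0 = params[:, 2]
        inv2st2 = 1.0 / (2.0 * np.radians(params[:, 3]) ** 2)
        inv2sz2 = 1.0 / (2.0 * params[:, 4] ** 2)
        dt = theta - t0
        dt = (dt + np.pi) % (2 * np.pi) - np.pi
        h = np.exp(-(dt**2) * inv2st2 - (z - z0) ** 2 * inv2sz2) @ amp
        return h.reshape(shape)

    def _base_radius(self, theta):
        return np.sqrt(
            (self.rx * np.sin(theta)) ** 2 + (self.ry * np.cos(theta)) ** 2
        )

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """Signed surface function: 0 on the torso skin, <0 inside.

        The skin is the elliptic cross-section radially offset by the
        relief height; the offset is expressed on the normalized elliptic
        radius so it is measured in millimetres along the radial ray.
        """
        x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
        e = np.sqrt((x / self.rx) ** 2 + (y / self.ry) ** 2)
        theta = np.arctan2(x / self.rx, -y / self.ry)
        return e - 1.0 - self.relief_height(theta, z) / self._base_radius(theta)

    def surface_point(self, theta, z) -> np.ndarray:
        base = np.array([self.rx * np.sin(theta), -self.ry * np.cos(theta), float(z)])
        scale = 1.0 + self.relief_height(theta, z) / self._base_radius(theta)
        return np.array([base[0] * scale, base[1] * scale, float(z)])

    def surface_normal(self, theta, z=None) -> np.ndarray:
        """Outward unit normal from the implicit-function gradient."""
        z = 0.0 if z is None else float(z)
        p = self.surface_point(theta, z)
        return self._gradient(p[None, :])[0]

    def _gradient(self, pts: np.ndarray, eps: float = 0.5) -> np.ndarray:
        g = np.empty_like(pts)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            g[..., k] = (self.implicit(pts + dp) - self.implicit(pts - dp)) / (2 * eps)
        norm = np.linalg.norm(g, axis=-1, keepdims=True)
        return g / np.where(norm > 0, norm, 1.0)

    def marker_centers(self) -> np.ndarray:
        """Ground-truth electrode centres: clip-head plane, bump included."""
        out = []
        for m in self.markers:
            out.append(
                self.surface_point(m.theta, m.z)
                + self.bump * self.surface_normal(m.theta, m.z)
            )
        return np.array(out)

    def marker_normals(self) -> np.ndarray:
        return np.array([self.surface_normal(m.theta, m.z) for m in self.markers])


def _frontal_layout(rows=8, cols=4, z0=230.0, dz=40.0, thetas_deg=(-30, -10, 10, 30)):
    """Frontal patch, channels ascending bottom-right → top-left."""
    sites = []
    ch = 1
    for r in range(rows):
        for th in thetas_deg[:cols]:
            sites.append(MarkerSite(str(ch), np.radians(th), z0 + r * dz, "frontal"))
            ch += 1
    return sites, ch


def _dorsal_layout(start_ch, rows=6, cols=5, z0=250.0, dz=40.0,
                   thetas_deg=(150, 165, 180, 195, 210)):
    """Dorsal patch, channels continuing top-right → bottom-left."""
    sites = []
    ch = start_ch
    for r in range(rows - 1, -1, -1):
        for th in sorted(thetas_deg[:cols], key=lambda t: np.sin(np.radians(t))):
            sites.append(MarkerSite(str(ch), np.radians(th), z0 + r * dz, "dorsal"))
            ch += 1
    return sites


_SINGLES = [
    ("RA", -70.0, 555.0),
    ("LA", 70.0, 555.0),
    ("LL", 40.0, 100.0),
    ("AUX_R_FRONT", -60.0, 160.0),
    ("AUX_R_BACK", -130.0, 170.0),
]


def make_torso(
    n_electrodes: int = 67,
    rx: float = 160.0,
    ry: float = 110.0,
    height: float = 600.0,
    marker_cfg: MarkerConfig | None = None,
) -> TorsoModel:
    """Torso model with a planted, labeled electrode layout.

    ``n_electrodes`` may be 67 (full layout: 32 frontal + 30 dorsal +
    5 singles), 32 (frontal patch only) or 8 (mini 2x4 frontal patch);
    markers closer than one clip-head diameter raise an error.
    """
    marker_cfg = marker_cfg or MarkerConfig()
    if n_electrodes == 67:
        sites, ch = _frontal_layout()
        sites += _dorsal_layout(ch)
        sites += [MarkerSite(lbl, np.radians(th), z, "single") for lbl, th, z in _SINGLES]
    elif n_electrodes == 32:
        sites, _ = _frontal_layout()
    elif n_electrodes == 8:
        sites, _ = _frontal_layout(rows=2, cols=4, z0=330.0)
    else:
        raise ValueError("supported layouts: 8, 32, 67 electrodes")
    model = TorsoModel(rx=rx, ry=ry, height=height, markers=sites, marker_cfg=marker_cfg)
    centers = model.marker_centers()
    if len(centers) > 1:
        from scipy.spatial import cKDTree

        d = cKDTree(centers).query(centers, k=2)[0][:, 1]
        if d.min() < 2.0 * marker_cfg.head_radius:
            raise ValueError("marker spacing below one clip-head diameter")
    return model


@dataclass
class CameraPose:
    """Camera position/orientation looking horizontally at the torso axis."""

    azimuth: float          # rad; 0 = in front of the torso
    distance: float = 520.0  # mm from the torso axis
    look_z: float = 330.0    # mm, height of the viewed axis point

    @property
    def position(self) -> np.ndarray:
        return np.array(
            [
                self.distance * np.sin(self.azimuth),
                -self.distance * np.cos(self.azimuth),
                self.look_z,
            ]
        )

    @property
    def rotation(self) -> np.ndarray:
        """World→camera axes as rows (X right, Y down, Z forward)."""
        z = np.array([-np.sin(self.azimuth), np.cos(self.azimuth), 0.0])
        y = np.array([0.0, 0.0, -1.0])
        x = np.cross(y, z)
        return np.stack([x, y, z])

    def world_to_camera(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.position) @ self.rotation.T


def default_poses(n_views: int = 14, span_deg: float = 270.0, distance: float = 520.0,
                  look_z: float = 330.0) -> list[CameraPose]:
    """Poses sweeping the torso from the right-frontal to the right-dorsal side."""
    start = np.radians(-45.0)
    azimuths = start + np.radians(np.linspace(0.0, span_deg, n_views))
    return [CameraPose(a, distance, look_z) for a in azimuths]


DEPTH_INTRINSICS = CameraIntrinsics(fx=208.0, fy=208.0, cx=89.5, cy=119.5, width=180, height=240)
COLOR_INTRINSICS = CameraIntrinsics(fx=416.0, fy=416.0, cx=179.5, cy=239.5, width=360, height=480)
COLOR_BASELINE = 25.0   # mm, color sensor offset along the camera x-axis
ROOM_RADIUS = 900.0     # mm, gray wall around the torso axis
DEPTH_RANGE = (200.0, 1500.0)  # mm, valid sensor band


@dataclass
class ViewFrame:
    """One recorded view: raw sensor frames plus ground-truth metadata."""

    depth: np.ndarray          # (H, W) uint16 mm, 0 = undefined
    color: np.ndarray          # (Hc, Wc, 3) uint8 gamma RGB
    kw_recorded: float         # color-temperature setting stored by the camera
    k_illuminant: float        # true illuminant temperature
    pose: CameraPose
    view_id: int = 0


@dataclass
class Scene:
    model: TorsoModel
    frames: list[ViewFrame]
    truth_labels: list[str]
    truth_positions: np.ndarray
    truth_normals: np.ndarray
    truth_patches: list[str]


def _ray_cast(model: TorsoModel, pose: CameraPose, intr: CameraIntrinsics,
              origin: np.ndarray):
    """Intersect all pixel rays with the torso and the room wall.

    Returns ``(points, normals, depth_axis, hit_torso, hit_any)``:
    world-space hit points, outward surface normals, depth along the
    camera's optical axis, and hit masks.  Rays use a unit z-component in
    the camera frame so the ray parameter *is* the axis depth.
    """
    h, w = intr.height, intr.width
    py, px = np.mgrid[0:h, 0:w].astype(np.float64)
    d_cam = np.stack(
        [(px - intr.cx) / intr.fx, (py - intr.cy) / intr.fy, np.ones_like(px)], axis=-1
    )
    d_w = d_cam @ pose.rotation  # rows are camera axes -> d_cam @ R
    o = origin

    # torso: base elliptic hit, then Newton refinement onto the relief
    # surface (the implicit function is smooth and the relief shallow, so
    # a handful of iterations lands on the skin to sub-0.01 mm)
    inv = np.array([1.0 / model.rx, 1.0 / model.ry])
    dxy = d_w[..., :2] * inv
    oxy = o[:2] * inv
    a = (dxy**2).sum(-1)
    b = 2.0 * (dxy @ oxy)
    c = (oxy**2).sum() - 1.0
    disc = b**2 - 4 * a * c
    hit_t = np.full((h, w), np.inf)
    ok = disc > 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - sq) / (2 * a)
    pre = ok & (t1 > 0)
    if pre.any():
        t_ref = t1[pre]
        rays = d_w[pre]
        eps = 0.5
        for _ in range(10):
            p = o + t_ref[:, None] * rays
            f = model.implicit(p)
            fp = (
                model.implicit(o + (t_ref + eps)[:, None] * rays)
                - model.implicit(o + (t_ref - eps)[:, None] * rays)
            ) / (2 * eps)
            step = np.where(np.abs(fp) > 1e-9, f / np.where(fp == 0, 1.0, fp), 0.0)
            t_ref = t_ref - np.clip(step, -30.0, 30.0)
        p = o + t_ref[:, None] * rays
        converged = np.abs(model.implicit(p)) < 1e-4
        zok = (p[:, 2] >= 0) & (p[:, 2] <= model.height) & (t_ref > 0)
        t1_full = np.full((h, w), np.inf)
        sel = np.zeros((h, w), dtype=bool)
        sel[pre] = converged & zok
        tmp = np.full(pre.sum(), np.inf)
        good = converged & zok
        tmp[good] = t_ref[good]
        t1_full[pre] = tmp
        torso = sel
        hit_t[torso] = t1_full[torso]
    else:
        torso = np.zeros((h, w), dtype=bool)

    # room wall (circular cylinder, hit from inside => larger root)
    a2 = (d_w[..., :2] ** 2).sum(-1)
    b2 = 2.0 * (d_w[..., :2] @ o[:2])
    c2 = (o[:2] ** 2).sum() - ROOM_RADIUS**2
    disc2 = b2**2 - 4 * a2 * c2
    t2 = (-b2 + np.sqrt(np.maximum(disc2, 0.0))) / (2 * a2)
    wall = ~torso & (t2 > 0)
    hit_t[wall] = t2[wall]

    pts = o + hit_t[..., None] * d_w
    normals = np.zeros_like(pts)
    if torso.any():
        normals[torso] = model._gradient(pts[torso])
    nw = pts[wall][:, :2]
    normals[wall, :2] = -nw / np.linalg.norm(nw, axis=1, keepdims=True)
    nrm = np.linalg.norm(normals, axis=-1, keepdims=True)
    normals = normals / np.where(nrm > 0, nrm, 1.0)
    hit_any = torso | wall
    return pts, normals, hit_t, torso, hit_any, d_w


def _marker_distances(model: TorsoModel, pts: np.ndarray, torso: np.ndarray):
    """Distance of each torso hit point to the nearest marker surface centre."""
    centers = np.array([model.surface_point(m.theta, m.z) for m in model.markers])
    p = pts[torso]
    if len(centers) == 0 or len(p) == 0:
        return np.full(len(p), np.inf), np.zeros(len(p), dtype=np.int64)
    d = np.linalg.norm(p[:, None, :] - centers[None, :, :], axis=-1)
    idx = d.argmin(axis=1)
    return d[np.arange(len(p)), idx], idx


def _apply_clip_heads(
    model: TorsoModel,
    origin: np.ndarray,
    d_w: np.ndarray,
    hit_t: np.ndarray,
    torso: np.ndarray,
    pts: np.ndarray,
    normals: np.ndarray,
):
    """Raise the clip heads by exact ray/disk-plane intersection.

    Each clip head is a flat disk of the head radius, parallel to the
    skin, at the bump height above the marker centre.  Rays whose torso
    hit lands near a marker are re-intersected with that marker's disk
    plane; disk hits replace the skin hit.  Exact intersection keeps the
    reconstructed clip geometry identical from every viewpoint (an
    approximate depth offset would warp the bump field view-dependently
    and bias the surface registration).

    Returns ``marker_zone`` (int image: -1 none, else marker index) and
    ``disk_rho`` (in-plane distance to the marker centre for zone pixels).
    """
    h, w = hit_t.shape
    zone = np.full((h, w), -1, dtype=np.int64)
    rho = np.full((h, w), np.inf)
    if model.bump < 0 or not len(model.markers) or not torso.any():
        return zone, rho
    head_r = model.marker_cfg.head_radius
    md, midx = _marker_distances(model, pts, torso)
    cand = md <= 3.0 * head_r
    if not cand.any():
        return zone, rho
    t_idx = np.argwhere(torso)[cand]
    marker_of = midx[cand]
    centers = np.array(
        [model.surface_point(m.theta, m.z) for m in model.markers]
    )
    m_normals = np.array(
        [model.surface_normal(m.theta, m.z) for m in model.markers]
    )
    tops = centers + model.bump * m_normals
    n = m_normals[marker_of]
    top = tops[marker_of]
    rays = d_w[t_idx[:, 0], t_idx[:, 1]]
    denom = (rays * n).sum(1)
    ok = np.abs(denom) > 1e-9
    t_disk = np.where(ok, ((top - origin) * n).sum(1) / np.where(ok, denom, 1.0), np.inf)
    p_disk = origin + t_disk[:, None] * rays
    planar = np.linalg.norm(p_disk - top, axis=1)
    hit = ok & (t_disk > 0) & (planar <= head_r)
    rr, cc = t_idx[hit, 0], t_idx[hit, 1]
    hit_t[rr, cc] = t_disk[hit]
    pts[rr, cc] = p_disk[hit]
    normals[rr, cc] = n[hit]
    zone[rr, cc] = marker_of[hit]
    rho[rr, cc] = planar[hit]
    return zone, rho


def render_view(
    model: TorsoModel,
    pose: CameraPose,
    k_illuminant: float,
    depth_noise: float = 1.0,
    intensity_jitter: float = 0.0,
    channel_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    view_id: int = 0,
    cfg: PipelineConfig | None = None,
) -> ViewFrame:
    """Render one depth/color frame pair of the scene.

    The clip heads raise the depth surface by the bump height; rays
    grazing the torso (incidence beyond ~80°) return undefined depth,
    emulating infrared dropout at the silhouette.  The color image is
    rendered from the laterally offset color sensor, shaded by incidence,
    cast by the illuminant through the gain model (recorded at the sensor
    clamp of the illuminant temperature), gamma-compressed and quantized.
    """
    rng = rng or np.random.default_rng(0)
    cfg = cfg or PipelineConfig()
    nearest = pose.distance - max(model.rx, model.ry)
    if not (DEPTH_RANGE[0] < nearest and pose.distance < DEPTH_RANGE[1]):
        raise ValueError("camera pose outside the valid depth range")

    disk_r = model.marker_cfg.disk_radius

    # ---- depth sensor ----
    pts, normals, t_axis, torso, hit_any, d_w = _ray_cast(
        model, pose, DEPTH_INTRINSICS, pose.position
    )
    _apply_clip_heads(model, pose.position, d_w, t_axis, torso, pts, normals)
    view_dir = pts - pose.position
    vd = view_dir / np.maximum(np.linalg.norm(view_dir, axis=-1, keepdims=True), 1e-9)
    cos_inc = -(vd * normals).sum(-1)

    depth = t_axis.copy()
    undefined = ~hit_any | (torso & (cos_inc < GRAZING_COS))
    undefined |= (depth < DEPTH_RANGE[0]) | (depth > DEPTH_RANGE[1])
    if depth_noise > 0:
        depth = depth + rng.normal(0.0, depth_noise, size=depth.shape)
    depth16 = np.where(undefined, 0, np.round(depth)).astype(np.uint16)

    # ---- color sensor ----
    c_origin = pose.position + pose.rotation[0] * COLOR_BASELINE
    cpts, cnormals, c_t, ctorso, chit, cd_w = _ray_cast(
        model, pose, COLOR_INTRINSICS, c_origin
    )
    czone, crho = _apply_clip_heads(model, c_origin, cd_w, c_t, ctorso, cpts, cnormals)
    cview = cpts - c_origin
    cvd = cview / np.maximum(np.linalg.norm(cview, axis=-1, keepdims=True), 1e-9)
    ccos = np.clip(-(cvd * cnormals).sum(-1), 0.0, 1.0)

    albedo = np.zeros(cpts.shape)
    wall_mask = chit & ~ctorso
    nwall = int(wall_mask.sum())
    wall_chroma = np.array(WALL_CHROMA) + rng.normal(
        0.0, WALL_CHROMA_NOISE, size=(nwall, 3)
    )
    wall_chroma = np.clip(wall_chroma, 0.01, None)
    wall_chroma /= wall_chroma.sum(axis=1, keepdims=True)
    albedo[wall_mask] = wall_chroma * WALL_INTENSITY
    albedo[ctorso] = SKIN_ALBEDO
    albedo[(czone >= 0) & (crho <= disk_r)] = RED_ALBEDO
    albedo[(czone >= 0) & (crho > disk_r)] = BLUE_ALBEDO

    shade = np.ones(cpts.shape[:2])
    shade[ctorso] = 0.75 + 0.25 * ccos[ctorso]
    linear = albedo * shade[..., None]
    if intensity_jitter > 0:
        linear = linear * rng.uniform(1 - intensity_jitter, 1 + intensity_jitter)
    if channel_jitter > 0:
        linear = linear * rng.uniform(1 - channel_jitter, 1 + channel_jitter, size=3)

    wb = cfg.white_balance
    kw_recorded = float(np.clip(k_illuminant, wb.kw_min + 1.0, wb.kw_max))
    cast = apply_cast(
        linear, k_illuminant, kw_recorded, wb.virtual_kw_min, wb.virtual_kw_max
    )
    np.clip(cast, 0.0, 1.0, out=cast)
    color8 = color_mod.compress(cast)

    return ViewFrame(
        depth=depth16,
        color=color8,
        kw_recorded=kw_recorded,
        k_illuminant=k_illuminant,
        pose=pose,
        view_id=view_id,
    )


def render_views(
    model: TorsoModel,
    poses: list[CameraPose],
    illuminants: list[float] | None = None,
    depth_noise: float = 1.0,
    intensity_jitter: float = 0.0,
    channel_jitter: float = 0.0,
    seed: int = 1234,
    cfg: PipelineConfig | None = None,
) -> list[ViewFrame]:
    """Render all views with per-view illuminants and seeded noise."""
    rng = np.random.default_rng(seed)
    if illuminants is None:
        illuminants = list(rng.uniform(2800.0, 8500.0, size=len(poses)))
    frames = []
    for i, (pose, k) in enumerate(zip(poses, illuminants)):
        frames.append(
            render_view(
                model,
                pose,
                k,
                depth_noise=depth_noise,
                intensity_jitter=intensity_jitter,
                channel_jitter=channel_jitter,
                rng=rng,
                view_id=i,
                cfg=cfg,
            )
        )
    return frames


def simulate_scene(
    seed: int = 1234,
    n_views: int = 14,
    n_electrodes: int = 67,
    depth_noise: float = 1.0,
    intensity_jitter: float = 0.0,
    channel_jitter: float = 0.0,
    span_deg: float = 270.0,
    cfg: PipelineConfig | None = None,
) -> Scene:
    """Full study-condition scene: torso, poses, rendered frames, truth."""
    model = make_torso(n_electrodes)
    poses = default_poses(n_views, span_deg=span_deg)
    frames = render_views(
        model,
        poses,
        depth_noise=depth_noise,
        intensity_jitter=intensity_jitter,
        channel_jitter=channel_jitter,
        seed=seed,
        cfg=cfg,
    )
    return Scene(
        model=model,
        frames=frames,
        truth_labels=[m.label for m in model.markers],
        truth_positions=model.marker_centers(),
        truth_normals=model.marker_normals(),
        truth_patches=[m.patch for m in model.markers],
    )
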