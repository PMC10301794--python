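"""Marker pixel classification, 3D lifting, filtering, clustering."""

import numpy as np
import pytest

from torsomark import color, markers, meshing
from torsomark.config import MarkerColorCalibration, MarkerConfig

CALIB = MarkerColorCalibration()
MCFG = MarkerConfig()


def brute_force_classify(r, g, calib):
    def inside(cr, cg, sr, sg, phi):
        dr, dg = r - cr, g - cg
        u = dr * np.cos(phi) - dg * np.sin(phi)
        w = dr * np.sin(phi) + dg * np.cos(phi)
        return u**2 / sr**2 + w**2 / sg**2 <= 1.0

    red = inside(calib.red_r, calib.red_g, calib.red_sigma_r, calib.red_sigma_g, calib.red_phi)
    blue = inside(
        calib.blue_r, calib.blue_g, calib.blue_sigma_r, calib.blue_sigma_g, calib.blue_phi
    ) and not red
    return red, blue


def _chrom_image(rg_pairs):
    rg = np.asarray(rg_pairs, dtype=float)
    b = 1.0 - rg.sum(axis=1)
    chrom = np.concatenate([rg, b[:, None]], axis=1).reshape(1, -1, 3)
    return color.to_chromaticity(chrom * 0.9)


class TestClassification:
    def test_red_center_is_red(self):
        red, blue = markers.classify_pixels(_chrom_image([[0.75, 0.08]]), CALIB)
        assert red[0, 0] and not blue[0, 0]

    def test_neutral_gray_is_neither(self):
        red, blue = markers.classify_pixels(_chrom_image([[1 / 3, 1 / 3]]), CALIB)
        assert not red[0, 0] and not blue[0, 0]

    def test_blue_center_is_blue(self):
        red, blue = markers.classify_pixels(_chrom_image([[0.05, 0.13]]), CALIB)
        assert blue[0, 0] and not red[0, 0]

    def test_matches_brute_force_on_random_chromaticities(self, rng):
        calib = MarkerColorCalibration(red_phi=0.4, blue_phi=-0.3)
        rg = rng.uniform(0.0, 0.85, size=(10000, 2))
        rg = rg[rg.sum(axis=1) < 0.98][:5000]
        chrom = _chrom_image(rg)
        red, blue = markers.classify_pixels(chrom, calib)
        for k in range(0, len(rg), 37):
            want_r, want_b = brute_force_classify(rg[k, 0], rg[k, 1], calib)
            assert red[0, k] == want_r
            assert blue[0, k] == want_b

    def test_zero_rotation_reduces_to_axis_aligned(self, rng):
        rg = rng.uniform(0.0, 0.8, size=(500, 2))
        rg = rg[rg.sum(axis=1) < 0.98]
        chrom = _chrom_image(rg)
        red0, blue0 = markers.classify_pixels(chrom, CALIB)
        r, g = chrom.chromaticity[..., 0], chrom.chromaticity[..., 1]
        axis_red = ((r - CALIB.red_r) / CALIB.red_sigma_r) ** 2 + (
            (g - CALIB.red_g) / CALIB.red_sigma_g
        ) ** 2 <= 1
        assert np.array_equal(red0, axis_red & chrom.defined)


@pytest.fixture()
def flat_surface():
    """Planar textured surface: uv == (x, y) of the vertices."""
    g = np.mgrid[0:12, 0:12].astype(float)
    verts = np.stack([g[1].ravel() * 2, g[0].ravel() * 2, np.full(144, 300.0)], axis=1)
    tris = []
    for i in range(11):
        for j in range(11):
            a = i * 12 + j
            tris.append([a, a + 12, a + 13])
            tris.append([a, a + 13, a + 1])
    uv = verts[:, :2] * 4.0  # texture pixels
    return meshing.TexturedSurface(
        vertices=verts,
        triangles=np.asarray(tris),
        uv=uv,
        texture=np.zeros((100, 100, 3), np.uint8),
    )


class TestLifting:
    def test_pixel_at_vertex_maps_to_vertex(self, flat_surface):
        pix = flat_surface.uv[40][None, :]
        cloud = markers.lift_to_surface(pix, np.array([False]), flat_surface)
        assert len(cloud) == 1
        assert np.allclose(cloud.points[0], flat_surface.vertices[40], atol=1e-9)

    def test_pixel_at_triangle_centroid(self, flat_surface):
        t = flat_surface.triangles[10]
        pix = flat_surface.uv[t].mean(axis=0)[None, :]
        cloud = markers.lift_to_surface(pix, np.array([True]), flat_surface)
        assert np.allclose(
            cloud.points[0], flat_surface.vertices[t].mean(axis=0), atol=1e-9
        )
        assert cloud.is_blue[0]

    def test_roundtrip_reprojection(self, flat_surface, rng):
        pix = rng.uniform(4.0, 84.0, size=(200, 2))
        cloud = markers.lift_to_surface(pix, np.zeros(200, bool), flat_surface)
        assert len(cloud) == 200
        # uv = 4 * (x, y) on this surface, so reprojection is direct
        back = cloud.points[:, :2] * 4.0
        assert np.abs(back - pix).max() < 0.5

    def test_outside_pixels_dropped(self, flat_surface):
        pix = np.array([[95.0, 95.0], [-5.0, 2.0]])
        cloud = markers.lift_to_surface(pix, np.zeros(2, bool), flat_surface)
        assert len(cloud) == 0


def _disk_ring_cloud(center, normal, rng, n_red=80, n_blue=80, disk_r=6.0, ring_w=3.0):
    normal = np.asarray(normal) / np.linalg.norm(normal)
    a = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(normal, [0.0, 1.0, 0.0])
    a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    rr = disk_r * np.sqrt(rng.uniform(0, 1, n_red))
    tr = rng.uniform(0, 2 * np.pi, n_red)
    rb = rng.uniform(disk_r, disk_r + ring_w, n_blue)
    tb = rng.uniform(0, 2 * np.pi, n_blue)
    pts = np.concatenate(
        [
            center + rr[:, None] * (np.cos(tr)[:, None] * a + np.sin(tr)[:, None] * b),
            center + rb[:, None] * (np.cos(tb)[:, None] * a + np.sin(tb)[:, None] * b),
        ]
    )
    is_blue = np.concatenate([np.zeros(n_red, bool), np.ones(n_blue, bool)])
    normals = np.tile(normal, (len(pts), 1))
    return markers.MarkerPointCloud(
        pts, is_blue, normals, np.zeros(len(pts), dtype=np.int64)
    )


class TestOppositeColorFilter:
    def test_ideal_marker_fully_retained(self, rng):
        # dense sampling: every blue point is within the ring width of the
        # disk boundary, every red within the head radius of some blue
        cloud = _disk_ring_cloud([0, 0, 0], [0, 0, 1], rng, n_red=600, n_blue=200)
        out = markers.opposite_color_filter(cloud, MCFG.head_radius, MCFG.ring_width)
        assert len(out) > 0.97 * len(cloud)

    def test_isolated_red_blob_removed(self, rng):
        pts = rng.normal(0, 2.0, size=(50, 3))
        cloud = markers.MarkerPointCloud(
            pts, np.zeros(50, bool), np.tile([0.0, 0, 1], (50, 1)), np.zeros(50, np.int64)
        )
        out = markers.opposite_color_filter(cloud, MCFG.head_radius, MCFG.ring_width)
        assert len(out) == 0

    def test_distant_blue_point_removed(self, rng):
        cloud = _disk_ring_cloud([0, 0, 0], [0, 0, 1], rng)
        stray = markers.MarkerPointCloud(
            np.array([[MCFG.head_radius + MCFG.ring_width + 5.0, 0.0, 0.0]]),
            np.array([True]),
            np.array([[0.0, 0.0, 1.0]]),
            np.array([0]),
        )
        merged = markers.MarkerPointCloud.concatenate([cloud, stray])
        out = markers.opposite_color_filter(merged, MCFG.head_radius, MCFG.ring_width)
        assert len(out) < len(merged)
        assert np.linalg.norm(out.points, axis=1).max() < MCFG.head_radius + 1.0


class TestClustering:
    def test_separated_markers_yield_exact_count(self, rng):
        cfg = MarkerConfig(n_electrodes=12)
        clouds = []
        for i in range(3):
            for j in range(4):
                clouds.append(
                    _disk_ring_cloud([i * 50.0, 0.0, j * 50.0], [0, -1, 0], rng)
                )
        cloud = markers.MarkerPointCloud.concatenate(clouds)
        out = markers.cluster_markers(cloud, cfg)
        assert len(out) == 12

    def test_pure_noise_yields_nothing(self, rng):
        pts = rng.uniform(0, 500, size=(300, 3))
        cloud = markers.MarkerPointCloud(
            pts,
            rng.uniform(size=300) > 0.5,
            np.tile([0.0, -1, 0], (300, 1)),
            np.zeros(300, np.int64),
        )
        assert markers.cluster_markers(cloud, MarkerConfig(n_electrodes=4)) == []


class TestRealignFrontal:
    def _shell(self, rng, yaw_deg=0.0):
        theta = rng.uniform(-np.pi, np.pi, 6000)
        z = rng.uniform(0, 500, 6000)
        pts = np.stack([160 * np.sin(theta), -110 * np.cos(theta), z], axis=1)
        c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
        rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        return pts @ rz.T

    def test_aligned_cloud_gives_identity(self, rng):
        t = markers.realign_frontal(self._shell(rng))
        ang = np.degrees(np.arccos(np.clip((np.trace(t[:3, :3]) - 1) / 2, -1, 1)))
        assert ang < 1.5

    def test_recovers_fifteen_degree_yaw(self, rng):
        t = markers.realign_frontal(self._shell(rng, yaw_deg=15.0))
        rec = np.degrees(np.arctan2(t[1, 0], t[0, 0]))
        assert rec == pytest.approx(-15.0, abs=2.0)

    def test_degenerate_cloud_gives_identity(self):
        t = markers.realign_frontal(np.tile([[1.0, 2.0, 3.0]], (5, 1)))
        assert np.allclose(t, np.eye(4))
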