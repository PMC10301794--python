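"""Depth-to-mesh conversion, occlusion/degeneracy cleanup, canonical pose."""

from dataclasses import replace

import numpy as np
import pytest

from torsomark import meshing
from torsomark.config import MeshConfig

INTR = meshing.CameraIntrinsics(fx=100.0, fy=100.0, cx=9.5, cy=9.5, width=20, height=20)
TEX = np.zeros((40, 40, 3), dtype=np.uint8)
CINTR = meshing.CameraIntrinsics(fx=200.0, fy=200.0, cx=19.5, cy=19.5, width=40, height=40)


def _mesh(depth, mask=None, baseline=25.0):
    mask = np.ones_like(depth, bool) if mask is None else mask
    return meshing.depth_to_mesh(
        depth, mask, INTR, TEX, CINTR, color_offset=np.array([baseline, 0.0, 0.0])
    )


class TestDepthToMesh:
    def test_full_grid_triangle_count(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        assert len(surf.triangles) == 2 * 19 * 19
        assert len(surf.vertices) == 400

    def test_single_undefined_pixel_drops_incident_triangles(self):
        d = np.full((20, 20), 500, dtype=np.uint16)
        d[10, 10] = 0
        surf = _mesh(d)
        dropped = 2 * 19 * 19 - len(surf.triangles)
        assert 1 <= dropped <= 6

    def test_planar_frame_is_coplanar(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        assert np.allclose(surf.vertices[:, 2], 500.0)

    def test_normals_face_camera(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        n = surf.triangle_normals()
        c = surf.vertices[surf.triangles].mean(axis=1)
        assert ((n * c).sum(axis=1) < 0).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            _mesh(np.full((20, 20), 500, dtype=np.uint16), np.zeros((20, 20), bool))


class TestOcclusionRemoval:
    def test_frontal_plane_untouched(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        assert len(meshing.remove_occluded(surf).triangles) == len(surf.triangles)

    def test_mirrored_uv_triangle_removed(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        uv = surf.uv.copy()
        t0 = surf.triangles[0]
        # mirror the first triangle's uv winding by swapping two coordinates
        uv[t0[1]], uv[t0[2]] = uv[t0[2]].copy(), uv[t0[1]].copy()
        flipped = replace(surf, uv=uv)
        out = meshing.remove_occluded(flipped)
        assert len(out.triangles) < len(surf.triangles)

    def test_step_occlusion_removes_bridging_triangles(self):
        # near slab on the same side as the color-sensor offset hides part
        # of the far slab from it; bridging triangles flip their winding
        d = np.full((20, 20), 800, dtype=np.uint16)
        d[:, 10:] = 300
        surf = _mesh(d)
        out = meshing.remove_occluded(surf)
        assert len(out.triangles) < len(surf.triangles)
        # surviving triangles never span the depth step
        z = surf.vertices[:, 2]
        spans = np.ptp(z[out.triangles], axis=1)
        assert spans.max() < 400


class TestDegenerateRemoval:
    def test_uniform_grid_untouched(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        out = meshing.remove_degenerate_and_skinny(surf, MeshConfig(min_patch_triangles=1))
        assert len(out.triangles) == len(surf.triangles)

    def test_tiny_uv_area_removed(self):
        surf = _mesh(np.full((20, 20), 500, dtype=np.uint16))
        uv = surf.uv.copy()
        t0 = surf.triangles[0]
        uv[t0] = uv[t0[0]] + np.array([[0.0, 0.0], [0.4, 0.0], [0.0, 0.4]])
        out = meshing.remove_degenerate_and_skinny(
            replace(surf, uv=uv), MeshConfig(min_patch_triangles=1)
        )
        assert len(out.triangles) < len(surf.triangles)

    def test_needle_triangle_removed(self):
        # equilateral-ish sheet with one needle spike 10x the local scale
        rng = np.random.default_rng(0)
        g = np.mgrid[0:8, 0:8].astype(float)
        verts = np.stack([g[0].ravel() * 10, g[1].ravel() * 10, np.zeros(64)], axis=1)
        tris = []
        for i in range(7):
            for j in range(7):
                a = i * 8 + j
                tris.append([a, a + 8, a + 9])
                tris.append([a, a + 9, a + 1])
        # append a needle: apex far away, base on one grid edge
        verts = np.vstack([verts, [[350.0, 35.0, 1.0]]])
        tris.append([27, 28, 64])
        tris = np.asarray(tris)
        uv = verts[:, :2] * 2
        surf = meshing.TexturedSurface(
            vertices=verts, triangles=tris, uv=uv,
            texture=np.zeros((200, 200, 3), np.uint8),
        )
        out = meshing.remove_degenerate_and_skinny(surf, MeshConfig(min_patch_triangles=1))
        kept = set(map(tuple, out.triangles.tolist()))
        # the needle vertex disappears entirely
        assert not any(64 in t for t in kept)

    def test_no_unreferenced_vertices_after_cleanup(self):
        d = np.full((20, 20), 500, dtype=np.uint16)
        d[5, 5] = 0
        surf = _mesh(d)
        out = meshing.remove_degenerate_and_skinny(surf, MeshConfig(min_patch_triangles=1))
        used = np.unique(out.triangles)
        assert len(used) == len(out.vertices)


class TestCanonicalize:
    def _torso_cloud_surface(self, rng):
        # half-shell of an elliptic cylinder seen from the front
        theta = rng.uniform(-1.2, 1.2, 4000)
        z = rng.uniform(0, 500, 4000)
        pts_world = np.stack(
            [160 * np.sin(theta), -110 * np.cos(theta), z], axis=1
        )
        cam = np.array([0.0, -500.0, 250.0])
        # camera frame: X=world x, Y=-world z, Z=world y
        pc = np.stack(
            [
                pts_world[:, 0] - cam[0],
                -(pts_world[:, 2] - cam[2]),
                pts_world[:, 1] - cam[1],
            ],
            axis=1,
        )
        return meshing.TexturedSurface(
            vertices=pc,
            triangles=np.zeros((0, 3), dtype=np.int64),
            uv=np.zeros((len(pc), 2)),
            texture=np.zeros((4, 4, 3), np.uint8),
        )

    def test_axes_and_origin(self, rng):
        surf = self._torso_cloud_surface(rng)
        out = meshing.canonicalize(surf)
        assert out.frame == "canonical"
        v = out.vertices
        # +z spans the torso height, x spans the width
        assert np.ptp(v[:, 2]) > 400
        assert np.ptp(v[:, 0]) > 250
        # origin y sits at the shoulder median plane: near the front shell
        med = meshing.shoulder_medians(v)
        assert med is not None
        assert abs((med[0][1] + med[1][1]) / 2.0) < 1.0

    def test_idempotent(self, rng):
        surf = self._torso_cloud_surface(rng)
        once = meshing.canonicalize(surf)
        twice = meshing.canonicalize(once)
        assert np.allclose(once.vertices, twice.vertices, atol=1e-9)

    def test_degenerate_fallback_uses_bbox(self):
        pts = np.tile([[1.0, 2.0, 3.0]], (10, 1))
        surf = meshing.TexturedSurface(
            vertices=pts, triangles=np.zeros((0, 3), np.int64),
            uv=np.zeros((10, 2)), texture=np.zeros((2, 2, 3), np.uint8),
        )
        out = meshing.canonicalize(surf)
        assert out.frame == "canonical"
        assert np.isfinite(out.vertices).all()
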