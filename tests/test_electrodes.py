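"""Disk/ring model fitting, split-marker merging, grid building, labels."""

import numpy as np
import pytest

from torsomark import electrodes, markers, synthetic
from torsomark.config import GridConfig, MarkerConfig
from torsomark.markers import MarkerPointCloud

MCFG = MarkerConfig()


def _marker_cloud(center, normal, rng, n_red=120, n_blue=120, arc=None, jitter=0.0,
                  exact_ring=False):
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    a = np.cross(normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(normal, [0.0, 1.0, 0.0])
    a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    rr = MCFG.disk_radius * np.sqrt(rng.uniform(0, 1, n_red))
    tr = rng.uniform(0, 2 * np.pi, n_red)
    if exact_ring:
        rb = np.full(n_blue, MCFG.disk_radius)
    else:
        rb = rng.uniform(MCFG.disk_radius, MCFG.head_radius, n_blue)
    tb = rng.uniform(0, 2 * np.pi, n_blue) if arc is None else rng.uniform(0, arc, n_blue)
    pts = np.concatenate(
        [
            center + rr[:, None] * (np.cos(tr)[:, None] * a + np.sin(tr)[:, None] * b),
            center + rb[:, None] * (np.cos(tb)[:, None] * a + np.sin(tb)[:, None] * b),
        ]
    )
    if jitter:
        pts = pts + rng.normal(0, jitter, pts.shape)
    is_blue = np.concatenate([np.zeros(n_red, bool), np.ones(n_blue, bool)])
    normals = np.tile(normal, (len(pts), 1))
    return MarkerPointCloud(pts, is_blue, normals, np.zeros(len(pts), np.int64))


class TestDominantNormal:
    def test_identical_normals(self):
        n = np.tile([0.0, -1.0, 0.0], (10, 1))
        assert electrodes.dominant_normal(n) == pytest.approx([0.0, -1.0, 0.0])

    def test_perturbed_bundle_within_one_degree(self, rng):
        base = np.array([0.0, -1.0, 0.0])
        tilts = rng.normal(0, np.radians(5.0), size=(200, 3))
        bundle = base + np.cross(tilts, base)
        bundle /= np.linalg.norm(bundle, axis=1, keepdims=True)
        n = electrodes.dominant_normal(bundle)
        assert np.degrees(np.arccos(abs(np.dot(n, base)))) < 1.0

    def test_opposing_bundles_rejected(self):
        n = np.concatenate(
            [np.tile([0.0, -1.0, 0.0], (10, 1)), np.tile([0.0, 1.0, 0.0], (10, 1))]
        )
        with pytest.raises(ValueError):
            electrodes.dominant_normal(n)


class TestFitMarker:
    def test_perfect_marker_recovered_to_tenth_millimetre(self, rng):
        center = np.array([10.0, -50.0, 120.0])
        cl = electrodes.ElectrodeCluster(
            cloud=_marker_cloud(center, [0, -1, 0.2], rng, exact_ring=True)
        )
        out = electrodes.fit_marker(cl, MCFG)
        assert out is not None
        assert np.linalg.norm(out.center - center) < 0.1

    def test_half_occluded_ring_within_one_millimetre(self, rng):
        center = np.array([0.0, 0.0, 0.0])
        cl = electrodes.ElectrodeCluster(
            cloud=_marker_cloud(center, [0, 0, 1], rng, arc=np.pi, exact_ring=True)
        )
        out = electrodes.fit_marker(cl, MCFG)
        assert out is not None
        assert np.linalg.norm(out.center - center) < 1.0

    def test_noisy_marker_stays_close(self, rng):
        center = np.array([0.0, 0.0, 0.0])
        cl = electrodes.ElectrodeCluster(
            cloud=_marker_cloud(center, [0, 0, 1], rng, jitter=1.0)
        )
        out = electrodes.fit_marker(cl, MCFG)
        assert np.linalg.norm(out.center - center) < 1.0

    def test_single_color_cluster_dropped(self, rng):
        cloud = _marker_cloud([0, 0, 0], [0, 0, 1], rng)
        red_only = cloud.select(~cloud.is_blue)
        assert electrodes.fit_marker(electrodes.ElectrodeCluster(cloud=red_only)) is None

    def test_coincident_points_dropped(self):
        pts = np.zeros((12, 3))
        cloud = MarkerPointCloud(
            pts,
            np.arange(12) % 2 == 0,
            np.tile([0.0, 0, 1], (12, 1)),
            np.zeros(12, np.int64),
        )
        assert electrodes.fit_marker(electrodes.ElectrodeCluster(cloud=cloud)) is None


class TestMergeSplit:
    def test_bisected_marker_merged_and_fit(self, rng):
        center = np.array([0.0, 0.0, 0.0])
        full = _marker_cloud(center, [0, 0, 1], rng, n_red=200, n_blue=200,
                             exact_ring=True)
        left = full.select(full.points[:, 0] < -1.0)
        right = full.select(full.points[:, 0] > 1.0)
        clusters = [
            electrodes.ElectrodeCluster(cloud=right),
            electrodes.ElectrodeCluster(cloud=left),
        ]
        # force split-candidate status by stripping blue from one piece
        clusters[1] = electrodes.ElectrodeCluster(
            cloud=left.select(~left.is_blue)
        )
        merged = electrodes.merge_split_clusters(clusters, GridConfig())
        assert len(merged) == 1
        assert merged[0].merged
        out = electrodes.fit_marker(merged[0], MCFG)
        assert out is not None
        assert np.linalg.norm(out.center - center) < 1.5

    def test_healthy_clusters_untouched(self, rng):
        a = electrodes.ElectrodeCluster(cloud=_marker_cloud([0, 0, 0], [0, 0, 1], rng))
        b = electrodes.ElectrodeCluster(cloud=_marker_cloud([40, 0, 0], [0, 0, 1], rng))
        out = electrodes.merge_split_clusters([a, b], GridConfig())
        assert len(out) == 2
        assert not any(c.merged for c in out)

    def test_distinct_markers_at_two_head_diameters_not_merged(self, rng):
        gap = 4.0 * MCFG.head_radius
        a = _marker_cloud([0, 0, 0], [0, 0, 1], rng)
        b = _marker_cloud([gap, 0, 0], [0, 0, 1], rng)
        clusters = [
            electrodes.ElectrodeCluster(cloud=a.select(~a.is_blue)),
            electrodes.ElectrodeCluster(cloud=b.select(~b.is_blue)),
        ]
        out = electrodes.merge_split_clusters(clusters, GridConfig())
        assert len(out) == 2


def _layout_clusters(rng, jitter=0.0):
    """Clusters at the planted 67-electrode layout positions."""
    model = synthetic.make_torso(67)
    centers = model.marker_centers()
    normals = model.marker_normals()
    labels = [m.label for m in model.markers]
    clusters = []
    for c, n in zip(centers, normals):
        cl = electrodes.ElectrodeCluster(cloud=_marker_cloud(c, n, rng, 60, 60))
        cl.center = c + (rng.normal(0, jitter, 3) if jitter else 0.0)
        cl.normal = n
        clusters.append(cl)
    return clusters, labels, centers


class TestGridAndLabels:
    def test_patches_and_singles_recovered(self, rng):
        clusters, labels, _ = _layout_clusters(rng)
        grid = electrodes.build_grid(clusters, GridConfig(), MCFG)
        assert len(grid.frontal) == 32
        assert len(grid.dorsal) == 30
        assert len(grid.singles) == 5

    def test_labels_match_planted_ground_truth(self, rng):
        clusters, labels, centers = _layout_clusters(rng, jitter=0.5)
        grid = electrodes.build_grid(clusters, GridConfig(), MCFG)
        emap = electrodes.assign_labels(grid)
        got = {}
        for lbl, pos in zip(emap.labels, emap.positions):
            got[lbl] = pos
        matched = 0
        for lbl, c in zip(labels, centers):
            assert lbl in got
            if np.linalg.norm(got[lbl] - c) < 3.0:
                matched += 1
        assert matched == 67

    def test_duplicate_center_collapsed(self, rng):
        clusters, _, _ = _layout_clusters(rng)
        dup = electrodes.ElectrodeCluster(
            cloud=clusters[0].cloud.select(np.arange(10))
        )
        dup.center = clusters[0].center + np.array([1.0, 0.0, 0.0])
        dup.normal = clusters[0].normal
        grid = electrodes.build_grid(clusters + [dup], GridConfig(), MCFG)
        assert len(grid.centers) == 67

    def test_cluster_order_invariance(self, rng):
        clusters, _, _ = _layout_clusters(rng)
        grid1 = electrodes.build_grid(clusters, GridConfig(), MCFG)
        m1 = electrodes.assign_labels(grid1)
        perm = list(np.random.default_rng(5).permutation(len(clusters)))
        grid2 = electrodes.build_grid([clusters[i] for i in perm], GridConfig(), MCFG)
        m2 = electrodes.assign_labels(grid2)
        d1 = {l: tuple(np.round(p, 6)) for l, p in zip(m1.labels, m1.positions)}
        d2 = {l: tuple(np.round(p, 6)) for l, p in zip(m2.labels, m2.positions)}
        assert d1 == d2

    def test_too_few_centres_rejected(self, rng):
        clusters, _, _ = _layout_clusters(rng)
        with pytest.raises(ValueError):
            electrodes.build_grid(clusters[:3], GridConfig(), MCFG)
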