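"""End-to-end orchestration: frames → surfaces → registration → electrode map.

Mirrors the offline processing chain of the recording system: each view is
segmented, meshed, color-corrected and placed in its canonical pose; the
views are chained together by pairwise symmetric ICP; marker pixels are
classified per view on the corrected textures, lifted to 3D, merged in the
global frame, clustered, fitted and labeled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import color as color_mod
from . import electrodes, exposure, markers, registration, segmentation
from .config import PipelineConfig
from .electrodes import ElectrodeMap
from .markers import MarkerPointCloud
from .meshing import TexturedSurface, canonicalize, clean_surface, depth_to_mesh
from .synthetic import COLOR_BASELINE, COLOR_INTRINSICS, DEPTH_INTRINSICS, ViewFrame
from .white_balance import color_correct_offline

log = logging.getLogger(__name__)

__all__ = ["ViewResult", "PipelineResult", "process_view", "run_pipeline", "evaluate"]


@dataclass
class ViewResult:
    surface: TexturedSurface           # canonical frame, corrected texture
    chromaticity: color_mod.ChromaticityImage
    kw_corrected: float
    skewness: float                    # exposure-quality score of the view


@dataclass
class PipelineResult:
    electrode_map: ElectrodeMap | None
    views: list[ViewResult]
    registrations: list[registration.RegistrationResult | None]
    global_transforms: list[np.ndarray | None]
    marker_cloud: MarkerPointCloud
    clusters: list[electrodes.ElectrodeCluster]
    frontal_transform: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)


def process_view(frame: ViewFrame, cfg: PipelineConfig | None = None) -> ViewResult:
    """Segment, mesh, color-correct and canonicalize one recorded view."""
    cfg = cfg or PipelineConfig()
    seg = segmentation.select_patient(frame.depth, cfg=cfg.segmentation)
    corr = color_correct_offline(
        frame.color, frame.kw_recorded, cfg.white_balance, cfg.gamut
    )
    surface = depth_to_mesh(
        frame.depth,
        seg.mask,
        DEPTH_INTRINSICS,
        corr.raw,
        COLOR_INTRINSICS,
        color_offset=np.array([COLOR_BASELINE, 0.0, 0.0]),
        kw=corr.kw,
        view_id=frame.view_id,
    )
    surface = clean_surface(surface, cfg.mesh)
    surface = canonicalize(surface)
    chrom = color_mod.to_chromaticity(corr.linear)

    # offline exposure score: histogram skewness over the texture pixels
    # actually covered by the patient surface
    tex_mask = np.zeros(frame.color.shape[:2], dtype=bool)
    uv = np.round(surface.uv).astype(int)
    ok = (
        (uv[:, 0] >= 0)
        & (uv[:, 0] < tex_mask.shape[1])
        & (uv[:, 1] >= 0)
        & (uv[:, 1] < tex_mask.shape[0])
    )
    tex_mask[uv[ok, 1], uv[ok, 0]] = True
    hist = exposure.masked_histogram(chrom, tex_mask, cfg.gamut)
    skew = exposure.skewness(hist)
    return ViewResult(
        surface=surface, chromaticity=chrom, kw_corrected=corr.kw, skewness=skew
    )


def _transform_cloud(cloud: MarkerPointCloud, t: np.ndarray) -> MarkerPointCloud:
    pts = cloud.points @ t[:3, :3].T + t[:3, 3]
    nrm = cloud.normals @ t[:3, :3].T
    return MarkerPointCloud(pts, cloud.is_blue, nrm, cloud.view_ids)


def run_pipeline(
    frames: list[ViewFrame], cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full offline chain on a list of recorded views."""
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    views: list[ViewResult] = []
    for frame in frames:
        try:
            views.append(process_view(frame, cfg))
        except segmentation.SegmentationAbort:
            log.warning("view %d: segmentation aborted, skipped", frame.view_id)
    timings["frames"] = time.perf_counter() - t0
    if not views:
        raise RuntimeError("no view could be processed")

    t0 = time.perf_counter()
    regs: list[registration.RegistrationResult | None] = []
    for a, b in zip(views[:-1], views[1:]):
        try:
            regs.append(registration.register_pair(a.surface, b.surface, cfg.registration))
        except registration.RegistrationFailure as exc:
            log.warning("registration failed: %s", exc)
            regs.append(None)
    transforms = registration.chain_global(regs)
    timings["registration"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    extraction = extract_electrodes(
        [v.surface for v in views],
        [v.chromaticity for v in views],
        transforms,
        cfg,
    )
    timings["markers"] = extraction.timings.get("markers", 0.0)
    timings["grid"] = extraction.timings.get("grid", 0.0)

    return PipelineResult(
        electrode_map=extraction.electrode_map,
        views=views,
        registrations=regs,
        global_transforms=transforms,
        marker_cloud=extraction.marker_cloud,
        clusters=extraction.clusters,
        frontal_transform=extraction.frontal_transform,
        timings=timings,
    )


@dataclass
class ExtractionResult:
    electrode_map: ElectrodeMap | None
    marker_cloud: MarkerPointCloud
    clusters: list[electrodes.ElectrodeCluster]
    frontal_transform: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)


def extract_electrodes(
    surfaces,
    chromaticities,
    transforms,
    cfg: PipelineConfig | None = None,
) -> ExtractionResult:
    """Marker extraction, fitting and labeling on registered views.

    ``surfaces`` are the canonical per-view meshes, ``chromaticities`` the
    matching corrected-texture chromaticity images, and ``transforms`` the
    global per-view transforms (``None`` entries are skipped).
    """
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    clouds = []
    surface_pts = []
    for surface, chrom, t in zip(surfaces, chromaticities, transforms):
        if t is None:
            continue
        red, blue = markers.classify_pixels(chrom, cfg.marker_colors)
        ys, xs = np.nonzero(red | blue)
        if len(ys) == 0:
            continue
        is_blue = blue[ys, xs]
        cloud = markers.lift_to_surface(
            np.stack([xs, ys], axis=1).astype(float), is_blue, surface
        )
        clouds.append(_transform_cloud(cloud, t))
        v = surface.vertices
        sub = v[:: max(1, len(v) // 2000)]
        surface_pts.append(sub @ t[:3, :3].T + t[:3, 3])
    merged = MarkerPointCloud.concatenate(clouds)

    frontal_t = np.eye(4)
    if surface_pts:
        frontal_t = markers.realign_frontal(np.concatenate(surface_pts))
    merged = _transform_cloud(merged, frontal_t)

    filtered = markers.opposite_color_filter(
        merged, cfg.markers.head_radius, cfg.markers.ring_width
    )
    raw_clusters = markers.cluster_markers(filtered, cfg.markers)
    clusters = [electrodes.ElectrodeCluster(cloud=c) for c in raw_clusters]
    clusters = electrodes.merge_split_clusters(clusters, cfg.grid)
    fitted = [c for c in (electrodes.fit_marker(c, cfg.markers) for c in clusters) if c]
    timings["markers"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    electrode_map = None
    if len(fitted) >= 4:
        grid = electrodes.build_grid(fitted, cfg.grid, cfg.markers)
        normals = np.array([fitted[i].normal for i in grid.kept])
        electrode_map = electrodes.assign_labels(grid, normals)
    else:
        log.warning("only %d fitted markers; no electrode map", len(fitted))
    timings["grid"] = time.perf_counter() - t0

    return ExtractionResult(
        electrode_map=electrode_map,
        marker_cloud=filtered,
        clusters=fitted,
        frontal_transform=frontal_t,
        timings=timings,
    )


@dataclass
class Evaluation:
    n_truth: int
    n_detected: int
    n_matched: int
    mean_error: float       # mm, after label-matched rigid alignment
    sd_error: float
    max_error: float
    label_accuracy: float   # matched / truth
    per_electrode: dict[str, float] = field(default_factory=dict)


def evaluate(
    electrode_map: ElectrodeMap,
    truth_labels: list[str],
    truth_positions: np.ndarray,
) -> Evaluation:
    """Compare an electrode map against ground truth.

    The estimated map lives in the pipeline's canonical frame, the truth
    in the scene frame; the arbitrary global pose is removed by a Kabsch
    fit over label-matched pairs before computing residuals.
    """
    est = electrode_map.as_dict()
    pairs = [(lbl, est[lbl], pos) for lbl, pos in zip(truth_labels, truth_positions) if lbl in est]
    if len(pairs) < 3:
        return Evaluation(
            n_truth=len(truth_labels),
            n_detected=len(electrode_map),
            n_matched=len(pairs),
            mean_error=float("inf"),
            sd_error=float("inf"),
            max_error=float("inf"),
            label_accuracy=0.0,
        )
    a = np.array([p[1] for p in pairs])   # estimated
    b = np.array([p[2] for p in pairs])   # truth
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    aligned = rot.apply(a - ca) + cb
    d = np.linalg.norm(aligned - b, axis=1)
    return Evaluation(
        n_truth=len(truth_labels),
        n_detected=len(electrode_map),
        n_matched=len(pairs),
        mean_error=float(d.mean()),
        sd_error=float(d.std()),
        max_error=float(d.max()),
        label_accuracy=len(pairs) / len(truth_labels),
        per_electrode={p[0]: float(e) for p, e in zip(pairs, d)},
    )
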