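"""Central defaults for the electrode-localization pipeline.

Every threshold used anywhere in the pipeline lives here so a run can be
reproduced from a single serialized config.  Units are millimetres for
distances, Kelvin for color temperatures, milliseconds for exposure times,
and chromaticity fractions (dimensionless, summing to one) for colors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Maximum total linear intensity of a pixel (R+G+B, each channel in [0,1]).
MAX_INTENSITY = 3.0

#: sRGB piecewise-linearization breakpoints.
SRGB_LINEAR_THRESHOLD = 0.04045
SRGB_LINEAR_SLOPE = 12.92
SRGB_OFFSET = 0.055
SRGB_GAMMA = 2.4


@dataclass
class GamutTarget:
    """Neutral (gray) chromaticity gamut at 5500 K plus exposure band.

    The ellipse spreads are standard deviations; membership tests use the
    standard ellipse form with squared denominators.  ``i_min``/``i_max`` are
    fractions of :data:`MAX_INTENSITY` in the linear domain.
    """

    r: float = 0.363
    g: float = 0.338
    b: float = 0.299
    sigma_r: float = 0.0723
    sigma_g: float = 0.0097
    sigma_b: float = 0.0749
    # 0.02 and 0.98 gamma-domain per-channel limits, linearized.
    i_min: float = 0.02 / 12.92
    i_max: float = ((0.98 + 0.055) / 1.055) ** 2.4


@dataclass
class WhiteBalanceConfig:
    kw_min: float = 2500.0          # color sensor AWB range (K)
    kw_max: float = 6500.0
    virtual_kw_min: float = 2000.0  # virtual camera AWB range (K)
    virtual_kw_max: float = 9000.0
    error_threshold: float = 1.758e-8   # gamut error gate of the update test
    error_margin: float = 1e-15         # required predicted improvement
    max_iterations: int = 200           # virtual-camera iteration cap
    jitter_repetitions: int = 20        # window for jitter detection
    jitter_band: float = 1.0            # |ΔKW| considered converged (K)
    jitter_close: float = 10.0          # consecutive-update closeness (K)
    underexposed_channel: float = 1e-8  # channel level treated as unexposed


@dataclass
class ExposureConfig:
    tau_min: float = 0.1       # ms
    tau_max: float = 666.0     # ms
    tau_delta: float = 1.0     # hardware exposure step (ms)
    tau_frame: float = 100.0   # optimal per-frame exposure (ms)
    n_tau: int = 5             # steps taken at |S| = 1
    gain_min: float = 1.0
    gain_max: float = 16.0
    bins: int = 256


@dataclass
class SegmentationConfig:
    sigma_spatial: float = 1.5      # px, Gaussian smoothing support sigma
    support: int = 5                # smoothing window edge length (px)
    sigma_depth: float = 10.0       # mm, gradient-magnitude weight scale
    edge_primary: float = 12.0      # mm, upper (primary) edge limit
    edge_minor: float = 3.5         # mm, minor edge limit
    d_near: float = 200.0           # mm, closest valid patient depth
    min_component: int = 200        # px, smallest acceptable patient blob


@dataclass
class MeshConfig:
    min_uv_area: float = 0.25       # px², degenerate-triangle cutoff
    min_uv_edge: float = 0.5        # px, shortest texture edge
    skinny_angle_deg: float = 13.0
    knn_sigma_factor: float = 4.0   # |e| > mean + factor·sd rejection
    min_patch_triangles: int = 100  # small disconnected patches removed


@dataclass
class RegistrationConfig:
    l_min: float = 1.0              # mm, optimal correspondence distance
    normal_max_angle_deg: float = 30.0  # correspondence normal compatibility
    max_inner_iterations: int = 80
    fitness_tol: float = 1e-6
    max_runs: int = 30
    max_points: int = 12000         # per-surface subsample for ICP
    init_first_view: bool = False   # frontal-plane init of view 1


@dataclass
class MarkerColorCalibration:
    """Red-disk / blue-ring ellipse parameters in (r, g) chromaticity."""

    red_r: float = 0.75
    red_g: float = 0.08
    red_sigma_r: float = 0.1
    red_sigma_g: float = 0.06
    red_phi: float = 0.0
    blue_r: float = 0.05
    blue_g: float = 0.13
    blue_sigma_r: float = 0.02
    blue_sigma_g: float = 0.06
    blue_phi: float = 0.0


@dataclass
class MarkerConfig:
    disk_radius: float = 6.0        # mm, red epoxy disk of the clip head
    ring_width: float = 3.0         # mm, blue painted rim
    min_samples: int = 20           # HDBSCAN minimum samples
    n_electrodes: int = 67          # expected clip count (Nclip)

    @property
    def head_radius(self) -> float:
        """Outer radius of the clip head (disk plus rim), mm."""
        return self.disk_radius + self.ring_width


@dataclass
class GridConfig:
    neighbors: int = 9              # k for the mean-spacing estimate
    outlier_sigma: float = 2.0
    merge_factor: float = 2.0 / 3.0  # duplicate-center distance, times head radius
    min_split_neighbors: int = 10    # mutual-NN votes for a split marker pair


@dataclass
class PipelineConfig:
    gamut: GamutTarget = field(default_factory=GamutTarget)
    white_balance: WhiteBalanceConfig = field(default_factory=WhiteBalanceConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    mesh: MeshConfig = field(default_factory=MeshConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    marker_colors: MarkerColorCalibration = field(default_factory=MarkerColorCalibration)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    grid: GridConfig = field(default_factory=GridConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, values in raw.items():
            target = getattr(cfg, section)
            for key, value in (values or {}).items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(target, key, value)
        return cfg
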